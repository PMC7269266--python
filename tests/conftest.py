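"""Shared builders for synthetic fixtures used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from pelletmetrics.flow import PulseProfile


def make_profile(position, fsc, ssc=None, flg=None, flr=None,
                 trigger_mv=200.0, saturation_mv=3000.0, **kw) -> PulseProfile:
    """PulseProfile with zero-filled channels where not given."""
    position = np.asarray(position, float)
    zeros = np.zeros_like(position)
    return PulseProfile(
        position_um=position,
        fsc_mv=np.asarray(fsc, float),
        ssc_mv=zeros if ssc is None else np.asarray(ssc, float),
        flg_mv=zeros if flg is None else np.asarray(flg, float),
        flr_mv=zeros if flr is None else np.asarray(flr, float),
        trigger_mv=trigger_mv, saturation_mv=saturation_mv, **kw)


def plateau_pulse(x, lo, hi, level, edge_level=None):
    """Steep-edged rectangular pulse: ``edge_level`` exactly at lo/hi, ``level``
    strictly inside, 0 outside.  With ``edge_level`` equal to a crossing
    threshold, interpolated crossings land exactly on lo and hi."""
    x = np.asarray(x, float)
    y = np.zeros_like(x)
    inside = (x > lo) & (x < hi)
    y[inside] = level
    if edge_level is not None:
        y[np.isclose(x, lo)] = edge_level
        y[np.isclose(x, hi)] = edge_level
    return y


def triangle_pulse(x, lo, hi, peak):
    """Symmetric triangle rising from 0 at lo to ``peak`` at the midpoint."""
    x = np.asarray(x, float)
    mid = 0.5 * (lo + hi)
    y = np.where(x <= mid, (x - lo) / (mid - lo), (hi - x) / (hi - mid))
    return peak * np.clip(y, 0.0, None)


@pytest.fixture
def rect_profile():
    """FSC extent exactly [10, 110] μm (length 100), SSC rectangular."""
    x = np.arange(0.0, 121.0)
    fsc = plateau_pulse(x, 9.5, 110.5, 3000.0)
    ssc = plateau_pulse(x, 10, 110, 800.0, edge_level=400.0)
    return make_profile(x, fsc, ssc=ssc)
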