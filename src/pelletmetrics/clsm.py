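"""Live/dead quantification of stained pellet slices imaged by CLSM.

An equatorial cryosection of a pellet stained with a green "live" stain
(SYTO9-class) and a red "dead" stain (PI) is imaged in two co-registered
channels.  Each channel is binarized with Otsu's method, closed with a
5-pixel disk and hole-filled; intersecting the two masks decomposes the
section into three regions — solely green (living), solely red (dead) and
both (overlap) — whose areas are reported as shares of the stained union.
The live ratio is

    live_ratio = living area / total area

with "living" the solely-green region and "total" the union of stained
areas.  An alternative convention where the overlap counts as living is
available via ``live_includes_overlap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .image import PelletImage

__all__ = [
    "DualChannelSlice",
    "ViabilityShares",
    "binarize_otsu",
    "close_and_fill",
    "region_shares",
    "analyze_slice",
    "overlay_rgb",
]


@dataclass(frozen=True)
class DualChannelSlice:
    """Co-registered green/red CLSM channels of one pellet slice."""

    green: PelletImage
    red: PelletImage

    def __post_init__(self) -> None:
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must have equal shapes")
        if self.green.pixel_size_um != self.red.pixel_size_um:
            raise ValueError("green and red channels must share calibration")

    @property
    def pixel_size_um(self) -> float:
        return self.green.pixel_size_um


@dataclass(frozen=True)
class ViabilityShares:
    """Area shares of the three stained regions; shares sum to 1."""

    live_share: float
    dead_share: float
    overlap_share: float
    live_ratio: float
    total_area_um2: float

    def __post_init__(self) -> None:
        s = self.live_share + self.dead_share + self.overlap_share
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"shares must sum to 1, got {s!r}")
        for v in (self.live_share, self.dead_share, self.overlap_share):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError("shares must lie in [0, 1]")


def binarize_otsu(channel: PelletImage) -> np.ndarray:
    """Threshold one fluorescence channel by maximizing between-class variance.

    Foreground is everything above the threshold.  Constant images have no
    histogram to split and raise.
    """
    px = np.asarray(channel.pixels)
    if px.min() == px.max():
        raise ValueError("degenerate histogram: constant image")
    t = threshold_otsu(px)
    return px > t


def close_and_fill(mask: np.ndarray, se_diameter_px: int = 5) -> np.ndarray:
    """Morphological closing with a disk footprint, then hole filling.

    The output is always a superset of the input mask.
    """
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if se_diameter_px < 1:
        raise ValueError("se_diameter_px must be >= 1")
    footprint = disk(se_diameter_px // 2)
    closed = closing(mask, footprint).astype(bool)
    filled = ndi.binary_fill_holes(closed)
    return filled | mask


def region_shares(green_mask: np.ndarray, red_mask: np.ndarray,
                  pixel_size_um: float,
                  live_includes_overlap: bool = False) -> ViabilityShares:
    """Decompose two stain masks into live / dead / overlap area shares."""
    green_mask = np.asarray(green_mask, bool)
    red_mask = np.asarray(red_mask, bool)
    if green_mask.shape != red_mask.shape:
        raise ValueError("masks must have equal shapes")
    union = green_mask | red_mask
    total = int(union.sum())
    if total == 0:
        raise ValueError("empty union: no stained area in either channel")
    overlap = int((green_mask & red_mask).sum())
    live = int((green_mask & ~red_mask).sum())
    dead = int((red_mask & ~green_mask).sum())
    live_px = live + overlap if live_includes_overlap else live
    return ViabilityShares(
        live_share=live / total,
        dead_share=dead / total,
        overlap_share=overlap / total,
        live_ratio=live_px / total,
        total_area_um2=total * pixel_size_um ** 2,
    )


def _channel_mask(channel: PelletImage, se_diameter_px: int,
                  min_snr: float) -> np.ndarray:
    """Binarize one channel, guarding against signal-free channels.

    Otsu's threshold always splits a histogram, including one that is pure
    background noise; a slice in which one stain simply did not bind would
    then contribute a speckle mask covering half the frame.  The guard
    declares a channel unstained (empty mask) when the Otsu classes are
    separated by less than ``min_snr`` robust noise standard deviations
    (1.4826·MAD of the lower class).  The rule is applied identically to both
    channels, preserving exact green/red swap symmetry.
    """
    px = np.asarray(channel.pixels, float)
    if px.min() == px.max():
        raise ValueError("degenerate histogram: constant image")
    t = threshold_otsu(px)
    fg = px > t
    if not fg.any() or fg.all():
        return np.zeros_like(fg)
    lower = px[~fg]
    sigma = 1.4826 * np.median(np.abs(lower - np.median(lower)))
    sep = px[fg].mean() - lower.mean()
    if sigma > 0 and sep < min_snr * sigma:
        return np.zeros_like(fg)
    closed = closing(fg, disk(se_diameter_px // 2)).astype(bool)
    return closed | fg


def analyze_slice(slc: DualChannelSlice, se_diameter_px: int = 5,
                  live_includes_overlap: bool = False,
                  min_snr: float = 6.0) -> ViabilityShares:
    """Full per-slice pipeline: Otsu → close/fill per channel → region shares.

    Hole filling is cross-channel aware: an enclosed region stained by
    neither channel is a sectioning artifact (air bubble, staining gap) and
    is filled, but a hole in the green mask occupied by red staining is a
    dead core, not an artifact, and is left alone — blind per-channel
    filling would silently reclassify every enclosed dead core as overlap.
    The rule is applied symmetrically to both channels, so swapping the
    channels swaps live and dead shares exactly.

    Raises when neither channel contains stained area (all-background pair).
    """
    g = _channel_mask(slc.green, se_diameter_px, min_snr)
    r = _channel_mask(slc.red, se_diameter_px, min_snr)
    g_filled = g | (ndi.binary_fill_holes(g) & ~r)
    r_filled = r | (ndi.binary_fill_holes(r) & ~g)
    return region_shares(g_filled, r_filled, slc.pixel_size_um,
                         live_includes_overlap=live_includes_overlap)


def overlay_rgb(green_mask: np.ndarray, red_mask: np.ndarray) -> np.ndarray:
    """QC overlay: green = live, red = dead, yellow = overlap (uint8 RGB)."""
    green_mask = np.asarray(green_mask, bool)
    red_mask = np.asarray(red_mask, bool)
    out = np.zeros(green_mask.shape + (3,), np.uint8)
    out[..., 0] = np.where(red_mask, 255, 0)
    out[..., 1] = np.where(green_mask, 255, 0)
    return out
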