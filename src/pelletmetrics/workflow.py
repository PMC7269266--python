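"""End-to-end demo runs: synthesize → analyze → summarize → compare.

:func:`run_demo` reproduces the *design* of a two-condition cultivation
comparison (an unsupplemented control versus a treatment producing smaller,
rounder, more viable pellets) on fully synthetic data: per cultivation day it
renders brightfield frames, one stained CLSM slice pair and flow-cytometry
pulse populations per condition, runs every analysis stage, and emits

* ``microscopy_daily.csv`` — per image: mean d_a, circularity, Feret ratio,
* ``flow_daily.csv`` — per replicate population: signal length, compactness,
  viability factor (stained) / autofluorescence factor (unstained),
* ``clsm_daily.csv`` — per day: live/dead/overlap shares and live ratio,
* ``kinetics.csv`` — concentration series with q_P per condition,
* ``summary.csv`` — condition × metric overview (mean ± sd),
* ``anova_per_day.csv`` — per-day single-factor ANOVA across conditions,
* ``manifest.json`` — config hash, versions, file list, warnings.

The CLSM live ratio is *excluded* from the ANOVA (one slice per sample has
no replication).  Identical config + seed reproduce identical CSVs byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .clsm import DualChannelSlice, analyze_slice
from .flow import summarize_population
from .kinetics import compare_conditions_per_day, specific_productivity
from .morphology import analyze_image, measurements_frame
from .synthetic import (
    CultivationGenParams,
    ImageGenParams,
    generate_clsm_pair,
    generate_cultivation_series,
    generate_pellet_image,
    generate_pulse_population,
)

__all__ = ["ConditionConfig", "RunConfig", "RunManifest", "run_demo"]


class ConditionConfig(BaseModel):
    """Generator settings that distinguish one cultivation condition."""

    model_config = ConfigDict(extra="forbid")

    mean_diameter_um: float = 170.0
    diameter_sigma: float = 0.35
    eccentricity_max: float = 0.6
    viable_shell_fraction: float = 0.25
    dead_core_fraction: float = 0.45
    autofluorescence_ratio: float = 0.21
    clsm_dead_core_fraction: float = 0.45
    clsm_overlap_band_um: float = 12.0
    P_max: float = 38.0
    production_rate: float = 0.8


class RunConfig(BaseModel):
    """Validated demo configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "demo_out"
    days: list[int] = Field(default_factory=lambda: list(range(1, 11)))
    n_images_per_day: int = 2
    image_size_px: int = 384
    n_pellets_per_image: int = 12
    n_flow_replicates: int = 2
    n_profiles_per_replicate: int = 30
    conditions: dict[str, ConditionConfig] = Field(default_factory=lambda: {
        "control": ConditionConfig(),
        "beads": ConditionConfig(
            mean_diameter_um=105.0, diameter_sigma=0.4,
            eccentricity_max=0.35, viable_shell_fraction=0.35,
            dead_core_fraction=0.35, autofluorescence_ratio=0.32,
            clsm_dead_core_fraction=0.3, clsm_overlap_band_um=8.0,
            P_max=95.0, production_rate=1.2),
    })


class RunManifest(BaseModel):
    package_version: str
    config_hash: str
    seed: int
    outputs: list[str]
    warnings: list[str]


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _stage_seed(base: int, *tags: int) -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    ss = np.random.SeedSequence([base, *tags])
    return int(ss.generate_state(1, np.uint32)[0] >> 1)


def run_demo(config: RunConfig) -> RunManifest:
    """Execute the full synthetic comparison; returns the written manifest."""
    if not config.days:
        raise ValueError("nothing to run: empty day list")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    cond_names = sorted(config.conditions)

    micro_rows, flow_rows, clsm_rows = [], [], []
    for ci, cname in enumerate(cond_names):
        cond = config.conditions[cname]
        for day in config.days:
            for rep in range(config.n_images_per_day):
                params = ImageGenParams(
                    image_width_px=config.image_size_px,
                    image_height_px=config.image_size_px,
                    n_pellets=config.n_pellets_per_image,
                    diameter_lognormal_mu=math.log(cond.mean_diameter_um),
                    diameter_lognormal_sigma=cond.diameter_sigma,
                    eccentricity_max=cond.eccentricity_max,
                    seed=_stage_seed(config.seed, 1, ci, day, rep))
                image, _truth = generate_pellet_image(params)
                meas, _ = analyze_image(image)
                if not meas:
                    warnings.append(
                        f"no pellets survived filtering: {cname} day {day} rep {rep}")
                    continue
                frame = measurements_frame(meas)
                micro_rows.append({
                    "condition": cname, "day": day, "replicate": rep,
                    "n_pellets": len(meas),
                    "d_a_um": frame["equivalent_diameter_um"].mean(),
                    "circularity": frame["circularity"].mean(),
                    "feret_ratio": frame["feret_ratio"].mean()})

            for rep in range(config.n_flow_replicates):
                profiles, _ = generate_pulse_population(
                    n=config.n_profiles_per_replicate,
                    seed=_stage_seed(config.seed, 2, ci, day, rep),
                    diameter_lognormal_mu=math.log(cond.mean_diameter_um),
                    diameter_lognormal_sigma=cond.diameter_sigma,
                    dead_core_fraction=cond.dead_core_fraction,
                    viable_shell_fraction=cond.viable_shell_fraction)
                s = summarize_population(profiles, stained=True,
                                         min_pellets=10)
                unstained, _ = generate_pulse_population(
                    n=config.n_profiles_per_replicate,
                    seed=_stage_seed(config.seed, 3, ci, day, rep),
                    diameter_lognormal_mu=math.log(cond.mean_diameter_um),
                    diameter_lognormal_sigma=cond.diameter_sigma,
                    stained=False,
                    autofluorescence_ratio=cond.autofluorescence_ratio)
                u = summarize_population(unstained, stained=False,
                                         min_pellets=10)
                flow_rows.append({
                    "condition": cname, "day": day, "replicate": rep,
                    "n_pellets": s["n_pellets"],
                    "signal_length_um": s["signal_length_um"][0],
                    "compactness": s["compactness"][0],
                    "viability_factor": s["viability_factor"][0],
                    "autofluorescence_factor": u["autofluorescence_factor"][0]})

            d = cond.mean_diameter_um
            g, r, _truth_shares = generate_clsm_pair(
                outer_diameter_um=d,
                dead_core_diameter_um=cond.clsm_dead_core_fraction * d,
                overlap_band_um=cond.clsm_overlap_band_um,
                noise_sd=8.0,
                seed=_stage_seed(config.seed, 4, ci, day))
            shares = analyze_slice(DualChannelSlice(g, r))
            clsm_rows.append({
                "condition": cname, "day": day,
                "live_share": shares.live_share,
                "dead_share": shares.dead_share,
                "overlap_share": shares.overlap_share,
                "live_ratio": shares.live_ratio})

    micro = pd.DataFrame(micro_rows)
    flow = pd.DataFrame(flow_rows)
    clsm = pd.DataFrame(clsm_rows)

    kin_rows = []
    qp_onset: dict[str, float] = {}
    for ci, cname in enumerate(cond_names):
        cond = config.conditions[cname]
        params = CultivationGenParams(
            t_grid=tuple(float(t) for t in [0] + list(config.days)),
            P_max=cond.P_max, production_rate=cond.production_rate,
            noise_sd_X=0.05, noise_sd_P=1.0, noise_sd_S=0.05,
            seed=_stage_seed(config.seed, 5, ci))
        series = generate_cultivation_series(params, condition=cname)
        qp = specific_productivity(series)
        frame = series.to_frame()
        frame["qP_mg_per_g_per_d"] = qp
        frame["condition"] = cname
        kin_rows.append(frame)
        after = series.t_days > params.production_onset_day
        qp_onset[cname] = float(qp[after][0]) if after.any() else float("nan")
    kinetics = pd.concat(kin_rows, ignore_index=True)

    summary_rows = []
    for cname in cond_names:
        m = micro[micro.condition == cname]
        f = flow[flow.condition == cname]
        c = clsm[clsm.condition == cname]
        summary_rows.append({
            "condition": cname,
            "d_a_um_mean": m["d_a_um"].mean(), "d_a_um_sd": m["d_a_um"].std(),
            "circularity_mean": m["circularity"].mean(),
            "circularity_sd": m["circularity"].std(),
            "feret_ratio_mean": m["feret_ratio"].mean(),
            "feret_ratio_sd": m["feret_ratio"].std(),
            "signal_length_um_mean": f["signal_length_um"].mean(),
            "signal_length_um_sd": f["signal_length_um"].std(),
            "compactness_mean": f["compactness"].mean(),
            "compactness_sd": f["compactness"].std(),
            "viability_factor_mean": f["viability_factor"].mean(),
            "viability_factor_sd": f["viability_factor"].std(),
            "autofluorescence_factor_mean": f["autofluorescence_factor"].mean(),
            "autofluorescence_factor_sd": f["autofluorescence_factor"].std(),
            "live_ratio_mean": c["live_ratio"].mean(),
            "live_ratio_sd": c["live_ratio"].std(),
            "qP_at_onset_mg_per_g_per_d": qp_onset[cname]})
    summary = pd.DataFrame(summary_rows)

    anova_parts = []
    metric_tables = {
        "d_a_um": micro, "circularity": micro, "feret_ratio": micro,
        "signal_length_um": flow, "compactness": flow,
        "viability_factor": flow, "autofluorescence_factor": flow}
    for metric, table in metric_tables.items():
        long = table.rename(columns={metric: "value"})[
            ["day", "condition", "value"]]
        res = compare_conditions_per_day(long)
        res.insert(0, "metric", metric)
        anova_parts.append(res)
    anova = pd.concat(anova_parts, ignore_index=True)

    outputs = []
    for name, frame in [("microscopy_daily.csv", micro),
                        ("flow_daily.csv", flow),
                        ("clsm_daily.csv", clsm),
                        ("kinetics.csv", kinetics),
                        ("summary.csv", summary),
                        ("anova_per_day.csv", anova)]:
        path = out / name
        frame.to_csv(path, index=False)
        outputs.append(name)

    manifest = RunManifest(
        package_version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
        outputs=outputs,
        warnings=warnings)
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest.model_dump(), indent=2, sort_keys=True))
    os.replace(tmp, out / "manifest.json")
    return manifest
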