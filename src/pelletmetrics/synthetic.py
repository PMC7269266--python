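"""Synthetic inputs with known ground truth for every analysis stage.

Real cultivation data for this kind of study (brightfield frames, stained
cryosection CLSM channels, large-particle flow-cytometer pulse traces and
daily concentration series) are rarely public, so each generator here
emulates the relevant measurement:

* :func:`generate_pellet_image` — dark elliptical pellet cores with a fuzzy
  hyphal corona on a bright background, log-normal size distribution,
  non-overlapping placement, Gaussian sensor noise; ground truth carries the
  analytic geometry of every core.
* :func:`generate_clsm_pair` — concentric live-shell / dead-core staining
  geometry as two co-registered fluorescence channels with analytic area
  shares.
* :func:`generate_pulse_profile` — projected-sphere pulse traces: FSC/SSC
  proportional to the chord 2·sqrt(R²−x²) through the equatorial disk (FSC
  clipped at the saturation level), FLG proportional to the projected viable
  shell (outer chord minus unstained-core chord), FLR to the projected dead
  core; baseline offset plus Gaussian noise.
* :func:`generate_cultivation_series` — logistic biomass growth, delayed
  sigmoidal product formation and yield-coupled glucose consumption.

All generators are bit-deterministic for a fixed parameter set and seed.
Ground-truth areas refer to the core ellipse only; where a pellet "ends" is
otherwise ill-defined, and the corona is rendered as texture that the
segmentation stage is expected to reject.  Glass beads are not rendered by
default; ``n_beads`` adds bright circular objects for robustness testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ellipe

from .clsm import ViabilityShares
from .flow import PulseProfile
from .image import PelletImage
from .kinetics import CultivationSeries

__all__ = [
    "ImageGenParams",
    "PulseGenParams",
    "CultivationGenParams",
    "PlacementError",
    "generate_pellet_image",
    "generate_clsm_pair",
    "generate_pulse_profile",
    "generate_pulse_population",
    "generate_cultivation_series",
]

_SUPERSAMPLE = 8  # edge anti-aliasing: 8x8 sub-pixel coverage samples


class PlacementError(RuntimeError):
    """Rejection sampling could not place all pellets (density too high)."""


@dataclass(frozen=True)
class ImageGenParams:
    """Brightfield frame generator settings.

    Diameters are drawn log-normally (log-space ``mu``/``sigma``, μm); each
    core is an ellipse of the drawn area-equivalent diameter with random
    orientation and eccentricity up to ``eccentricity_max``.  The corona is
    a multiplicative radial intensity falloff with speckle outside the core,
    of width ``corona_fraction`` times the core radius and peak darkening
    ``corona_strength`` times the core contrast.  Defaults emulate shake-
    flask pellet populations at the study's calibration of 4.5 μm/px.
    """

    image_width_px: int = 512
    image_height_px: int = 512
    pixel_size_um: float = 4.5
    n_pellets: int = 40
    diameter_lognormal_mu: float = math.log(160.0)
    diameter_lognormal_sigma: float = 0.35
    corona_fraction: float = 0.3
    corona_strength: float = 0.22
    speckle_sd: float = 0.25
    eccentricity_max: float = 0.6
    background_level: float = 200.0
    foreground_level: float = 60.0
    noise_sd: float = 4.0
    n_beads: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px < 8 or self.image_height_px < 8:
            raise ValueError("image must be at least 8x8 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_pellets < 0:
            raise ValueError("n_pellets must be >= 0")
        if not 0 <= self.corona_fraction <= 1:
            raise ValueError("corona_fraction must lie in [0, 1]")
        if not 0 <= self.eccentricity_max < 1:
            raise ValueError("eccentricity_max must lie in [0, 1)")
        if self.background_level <= self.foreground_level:
            raise ValueError("background must be brighter than foreground")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ellipse_coverage(shape: tuple[int, int], center: tuple[float, float],
                      a_px: float, b_px: float, theta: float) -> tuple[slice, slice, np.ndarray]:
    """Per-pixel area coverage of an ellipse, anti-aliased by supersampling.

    Returns the bounding-box slices and the coverage array (0..1) within
    them.  Interior/exterior pixels are decided from the implicit form at
    the pixel center; only the boundary band is supersampled.
    """
    h, w = shape
    cy, cx = center
    ext = max(a_px, b_px) + 1.5
    r0 = max(0, int(math.floor(cy - ext)))
    r1 = min(h, int(math.ceil(cy + ext)) + 1)
    c0 = max(0, int(math.floor(cx - ext)))
    c1 = min(w, int(math.ceil(cx + ext)) + 1)
    if r0 >= r1 or c0 >= c1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a_px
    v = (-dx * st + dy * ct) / b_px
    rho2 = u * u + v * v
    # pixels within half a pixel diagonal of the boundary get supersampled
    band = 0.75 * (1.0 / a_px + 1.0 / b_px) + 0.02
    inner = rho2 <= (1.0 - band) ** 2 if band < 1 else np.zeros_like(rho2, bool)
    outer = rho2 >= (1.0 + band) ** 2
    cov = np.where(inner, 1.0, 0.0)
    edge = ~(inner | outer)
    if edge.any():
        er, ec = np.nonzero(edge)
        n = _SUPERSAMPLE
        offs = (np.arange(n) + 0.5) / n - 0.5
        oy, ox = np.meshgrid(offs, offs, indexing="ij")
        sy = (yy[er, ec][:, None] + oy.ravel()[None, :]) - cy
        sx = (xx[er, ec][:, None] + ox.ravel()[None, :]) - cx
        su = (sx * ct + sy * st) / a_px
        sv = (-sx * st + sy * ct) / b_px
        inside = (su * su + sv * sv) <= 1.0
        cov[er, ec] = inside.mean(axis=1)
    return slice(r0, r1), slice(c0, c1), cov


def _ellipse_axes(diameter_um: float, ecc: float, pixel_size_um: float) -> tuple[float, float]:
    """Semi-axes (a >= b, px) of the area-equivalent ellipse of ``diameter_um``."""
    r_px = diameter_um / (2.0 * pixel_size_um)
    ratio = math.sqrt(1.0 - ecc * ecc)  # b/a
    a = r_px / math.sqrt(ratio)
    return a, a * ratio


def _ellipse_perimeter_um(a_um: float, b_um: float) -> float:
    m = 1.0 - (b_um / a_um) ** 2
    return 4.0 * a_um * float(ellipe(m))


def generate_pellet_image(params: ImageGenParams) -> tuple[PelletImage, pd.DataFrame]:
    """Render one brightfield frame and its per-object ground-truth table.

    Cores are placed by rejection sampling with minimum center distance equal
    to the sum of the semi-major radii plus 2 px, fully inside the frame;
    1000 consecutive rejections raise :class:`PlacementError`.  The truth
    table holds one row per object with the analytic core geometry (area,
    equivalent diameter, circularity, Feret extremes) and pixel center.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px
    px_um = params.pixel_size_um
    contrast = params.background_level - params.foreground_level

    diameters = np.exp(rng.normal(params.diameter_lognormal_mu,
                                  params.diameter_lognormal_sigma,
                                  params.n_pellets))
    eccs = rng.uniform(0.0, params.eccentricity_max, params.n_pellets)
    thetas = rng.uniform(0.0, math.pi, params.n_pellets)

    placed: list[dict] = []
    for i in range(params.n_pellets):
        a_px, b_px = _ellipse_axes(diameters[i], eccs[i], px_um)
        rejections = 0
        while True:
            cy = rng.uniform(a_px + 1.0, h - a_px - 1.0) if h > 2 * (a_px + 1) else None
            cx = rng.uniform(a_px + 1.0, w - a_px - 1.0) if w > 2 * (a_px + 1) else None
            if cy is None or cx is None:
                raise PlacementError(
                    f"pellet of semi-major {a_px:.1f} px does not fit a "
                    f"{w}x{h} px frame (n_pellets={params.n_pellets})")
            ok = all((cy - q["cy"]) ** 2 + (cx - q["cx"]) ** 2
                     >= (a_px + q["a_px"] + 2.0) ** 2 for q in placed)
            if ok:
                placed.append({"id": i, "cy": cy, "cx": cx, "a_px": a_px,
                               "b_px": b_px, "theta": thetas[i],
                               "d_um": diameters[i], "ecc": eccs[i]})
                break
            rejections += 1
            if rejections >= 1000:
                raise PlacementError(
                    f"could not place pellet {i + 1}/{params.n_pellets} in a "
                    f"{w}x{h} px frame after 1000 rejections; "
                    "reduce n_pellets or enlarge the image")

    darkening = np.zeros((h, w))
    coverage_sum = []
    for q in placed:
        rs, cs, cov = _ellipse_coverage((h, w), (q["cy"], q["cx"]),
                                        q["a_px"], q["b_px"], q["theta"])
        core_dark = cov * contrast
        # corona: multiplicative radial falloff with speckle outside the core
        if params.corona_fraction > 0 and params.corona_strength > 0:
            yy, xx = np.mgrid[rs, cs]
            dy, dx = yy - q["cy"], xx - q["cx"]
            ct, st = math.cos(q["theta"]), math.sin(q["theta"])
            u = (dx * ct + dy * st) / q["a_px"]
            v = (-dx * st + dy * ct) / q["b_px"]
            rho = np.sqrt(u * u + v * v)
            halo = np.exp(-np.clip(rho - 1.0, 0.0, None) / params.corona_fraction)
            speckle = 1.0 + params.speckle_sd * rng.standard_normal(halo.shape)
            halo_dark = (params.corona_strength * contrast * halo
                         * np.clip(speckle, 0.0, None) * (1.0 - cov))
            core_dark = np.maximum(core_dark, halo_dark)
        darkening[rs, cs] = np.maximum(darkening[rs, cs], core_dark)
        coverage_sum.append(float(cov.sum()))

    img = params.background_level - darkening
    if params.n_beads:
        for _ in range(params.n_beads):
            br = rng.uniform(3.0, 8.0)
            bc = (rng.uniform(br, h - br), rng.uniform(br, w - br))
            rs, cs, cov = _ellipse_coverage((h, w), bc, br, br, 0.0)
            img[rs, cs] = np.maximum(
                img[rs, cs],
                params.background_level + 0.2 * contrast * cov)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, None).astype(np.float32)

    rows = []
    for q, cov_area_px in zip(placed, coverage_sum):
        a_um = q["a_px"] * px_um
        b_um = q["b_px"] * px_um
        area = math.pi * a_um * b_um
        perim = _ellipse_perimeter_um(a_um, b_um)
        rows.append({
            "id": q["id"],
            "center_row_px": q["cy"],
            "center_col_px": q["cx"],
            "true_area_um2": area,
            "true_equivalent_diameter_um": math.sqrt(4.0 * area / math.pi),
            "true_circularity": 4.0 * math.pi * area / perim ** 2,
            "true_feret_min_um": 2.0 * b_um,
            "true_feret_max_um": 2.0 * a_um,
            "rendered_coverage_area_um2": cov_area_px * px_um ** 2,
            "touches_edge": False,
        })
    truth = pd.DataFrame(rows, columns=[
        "id", "center_row_px", "center_col_px", "true_area_um2",
        "true_equivalent_diameter_um", "true_circularity",
        "true_feret_min_um", "true_feret_max_um",
        "rendered_coverage_area_um2", "touches_edge"])
    return PelletImage(img, px_um), truth


def _disk_coverage(shape, center, r_px):
    return _ellipse_coverage(shape, center, r_px, r_px, 0.0)


def generate_clsm_pair(outer_diameter_um: float, dead_core_diameter_um: float,
                       overlap_band_um: float, pixel_size_um: float = 4.5,
                       noise_sd: float = 0.0, seed: int = 0,
                       background_level: float = 10.0,
                       foreground_level: float = 200.0,
                       ) -> tuple[PelletImage, PelletImage, ViabilityShares]:
    """Concentric staining geometry as a green/red channel pair plus truth.

    Green fluorescence covers the full section disk minus the solely-red
    dead core; red covers the core plus the overlap band.  Truth shares come
    from the analytic circle areas of the same geometry.
    """
    if outer_diameter_um <= 0:
        raise ValueError("outer_diameter_um must be positive")
    if dead_core_diameter_um < 0 or overlap_band_um < 0:
        raise ValueError("core diameter and overlap band must be >= 0")
    if dead_core_diameter_um + 2.0 * overlap_band_um > outer_diameter_um + 1e-9:
        raise ValueError(
            "non-physical geometry: dead core + 2*overlap exceeds the section")
    rng = np.random.default_rng(seed)
    R = outer_diameter_um / 2.0
    rc = dead_core_diameter_um / 2.0
    rr = rc + overlap_band_um  # outer radius of the red (PI-positive) region
    R_px = R / pixel_size_um
    side = int(math.ceil(2 * R_px * 1.2)) + 4
    center = (side / 2.0, side / 2.0)
    shape = (side, side)

    def render(cov_outer_r_px: float, cov_inner_r_px: float) -> np.ndarray:
        img = np.zeros(shape)
        if cov_outer_r_px > 0:
            rs, cs, cov = _disk_coverage(shape, center, cov_outer_r_px)
            img[rs, cs] += cov
        if cov_inner_r_px > 0:
            rs, cs, cov = _disk_coverage(shape, center, cov_inner_r_px)
            img[rs, cs] -= cov
        return np.clip(img, 0.0, 1.0)

    amp = foreground_level - background_level
    green = background_level + amp * render(R_px, rc / pixel_size_um)
    red = background_level + amp * render(rr / pixel_size_um, 0.0)
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, shape)
        red = red + rng.normal(0.0, noise_sd, shape)
    green = np.clip(green, 0.0, None).astype(np.float32)
    red = np.clip(red, 0.0, None).astype(np.float32)

    total = R * R
    truth = ViabilityShares(
        live_share=(R * R - rr * rr) / total,
        dead_share=rc * rc / total,
        overlap_share=(rr * rr - rc * rc) / total,
        live_ratio=(R * R - rr * rr) / total,
        total_area_um2=math.pi * R * R,
    )
    return (PelletImage(green, pixel_size_um), PelletImage(red, pixel_size_um),
            truth)


@dataclass(frozen=True)
class PulseGenParams:
    """Projected-sphere pulse trace settings (gains in mV per μm of chord)."""

    pellet_diameter_um: float = 160.0
    viable_shell_um: float = 25.0
    dead_core_diameter_um: float = 60.0
    fsc_gain: float = 30.0
    ssc_gain: float = 12.0
    flg_gain: float = 15.0
    flr_gain: float = 15.0
    saturation_mv: float = 2000.0
    baseline_mv: float = 50.0
    trigger_mv: float = 200.0
    edge_floor_mv: float = 400.0
    noise_sd_mv: float = 5.0
    sample_spacing_um: float = 2.5
    margin_samples: int = 5
    stained: bool = True
    autofluorescence_ratio: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pellet_diameter_um <= 0:
            raise ValueError("pellet_diameter_um must be positive")
        if not 0 <= self.viable_shell_um <= self.pellet_diameter_um / 2:
            raise ValueError("viable_shell_um must lie in [0, diameter/2]")
        if not 0 <= self.dead_core_diameter_um <= self.pellet_diameter_um:
            raise ValueError("dead_core_diameter_um must lie in [0, diameter]")
        if self.sample_spacing_um <= 0:
            raise ValueError("sample_spacing_um must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")


def _chord(x: np.ndarray, r: float) -> np.ndarray:
    """Projected chord length 2·sqrt(r²−x²) of a disk of radius r, else 0."""
    return 2.0 * np.sqrt(np.clip(r * r - x * x, 0.0, None))


def generate_pulse_profile(params: PulseGenParams,
                           particle_id: str = "synthetic",
                           ) -> tuple[PulseProfile, dict]:
    """One synthetic particle trace plus its ground-truth record.

    FSC and SSC follow the chord through the equatorial disk; the FSC trace
    is additionally floored at ``edge_floor_mv`` everywhere inside the
    particle (the acquisition trigger is set below any biomass signal, so
    even the particle rim scatters above it — this is what makes the
    recorded signal length represent the full diameter) and clipped at the
    saturation level.  FLG follows the projected viable shell (outer chord
    minus the chord of the unstained inner sphere of radius
    R − viable_shell), FLR the projected dead core.  Unstained runs replace
    FLG with ``autofluorescence_ratio`` times the recorded FSC signal and
    leave FLR at baseline.
    """
    rng = np.random.default_rng(params.seed)
    R = params.pellet_diameter_um / 2.0
    dx = params.sample_spacing_um
    half = R + params.margin_samples * dx
    n = int(math.floor(half / dx))
    x = np.arange(-n, n + 1) * dx

    inside = np.abs(x) < R
    fsc = params.fsc_gain * _chord(x, R)
    fsc = np.where(inside, np.maximum(fsc, params.edge_floor_mv), fsc)
    fsc = np.minimum(fsc, params.saturation_mv - params.baseline_mv)
    ssc = params.ssc_gain * _chord(x, R)
    if params.stained:
        inner = R - params.viable_shell_um
        flg = params.flg_gain * (_chord(x, R) - _chord(x, inner))
        flr = params.flr_gain * _chord(x, params.dead_core_diameter_um / 2.0)
    else:
        flg = params.autofluorescence_ratio * fsc
        flr = np.zeros_like(x)

    def finalize(y: np.ndarray) -> np.ndarray:
        y = y + params.baseline_mv
        if params.noise_sd_mv > 0:
            y = y + rng.normal(0.0, params.noise_sd_mv, y.shape)
        return np.clip(y, 0.0, None)

    profile = PulseProfile(
        position_um=x - x[0],  # start at 0 like an instrument trace
        fsc_mv=finalize(fsc),
        ssc_mv=finalize(ssc),
        flg_mv=finalize(flg),
        flr_mv=finalize(flr),
        particle_id=particle_id,
        saturation_mv=params.saturation_mv,
        trigger_mv=params.trigger_mv,
        stained=params.stained,
    )
    truth = {
        "diameter_um": params.pellet_diameter_um,
        "viable_shell_um": params.viable_shell_um,
        "dead_core_diameter_um": params.dead_core_diameter_um,
    }
    return profile, truth


def generate_pulse_population(n: int = 200, seed: int = 0,
                              diameter_lognormal_mu: float = math.log(150.0),
                              diameter_lognormal_sigma: float = 0.25,
                              diameter_range_um: tuple[float, float] = (80.0, 280.0),
                              dead_core_fraction: float = 0.3,
                              viable_shell_fraction: float = 0.3,
                              stained: bool = True,
                              **overrides) -> tuple[list[PulseProfile], pd.DataFrame]:
    """A seeded population of pulse traces with per-particle ground truth.

    Diameters are log-normal, truncated to ``diameter_range_um`` — the upper
    end reflects the instrument's sampling-bore hindrance for very large
    particles.  Dead core and viable shell scale with the diameter.
    """
    rng = np.random.default_rng(seed)
    profiles, rows = [], []
    for i in range(n):
        while True:
            d = float(np.exp(rng.normal(diameter_lognormal_mu,
                                        diameter_lognormal_sigma)))
            if diameter_range_um[0] <= d <= diameter_range_um[1]:
                break
        params = PulseGenParams(
            pellet_diameter_um=d,
            viable_shell_um=viable_shell_fraction * d / 2.0,
            dead_core_diameter_um=dead_core_fraction * d,
            stained=stained,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            **overrides)
        prof, truth = generate_pulse_profile(params, particle_id=f"p{i:04d}")
        profiles.append(prof)
        rows.append({"particle_id": prof.particle_id, **truth})
    return profiles, pd.DataFrame(rows)


@dataclass(frozen=True)
class CultivationGenParams:
    """Shake-flask trajectory settings: logistic growth, delayed production.

    Defaults emulate a 10-day cultivation in which biomass growth levels off
    around day 2, product formation starts between day 3 and 4 and glucose
    is consumed in proportion to grown biomass.
    """

    t_grid: tuple[float, ...] = tuple(float(t) for t in range(11))
    X_max: float = 5.0
    X_init: float = 0.15
    growth_rate: float = 2.2
    production_onset_day: float = 3.5
    P_max: float = 95.0
    production_rate: float = 1.0
    production_midpoint_days: float = 3.0
    glucose_init: float = 4.0
    yield_coefficient: float = 1.3
    noise_sd_X: float = 0.0
    noise_sd_P: float = 0.0
    noise_sd_S: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing, length >= 2")
        if not 0 < self.X_init < self.X_max:
            raise ValueError("need 0 < X_init < X_max")
        for name in ("growth_rate", "P_max", "production_rate",
                     "glucose_init", "yield_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def cultivation_model(params: CultivationGenParams,
                      t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free (X, P, S) trajectories of the generator model."""
    t = np.asarray(t, float)
    A = (params.X_max - params.X_init) / params.X_init
    X = params.X_max / (1.0 + A * np.exp(-params.growth_rate * t))
    tau = t - params.production_onset_day
    k, t0 = params.production_rate, params.production_midpoint_days
    c0 = 1.0 / (1.0 + math.exp(k * t0))
    raw = 1.0 / (1.0 + np.exp(-k * (tau - t0)))
    P = np.where(tau > 0, params.P_max * (raw - c0) / (1.0 - c0), 0.0)
    P = np.clip(P, 0.0, None)
    S = np.clip(params.glucose_init - (X - X[0]) / params.yield_coefficient,
                0.0, None)
    return X, P, S


def generate_cultivation_series(params: CultivationGenParams,
                                condition: str = "synthetic",
                                ) -> CultivationSeries:
    """Sample the cultivation model on ``t_grid`` with seeded channel noise."""
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.t_grid, float)
    X, P, S = cultivation_model(params, t)
    if params.noise_sd_X > 0:
        X = X + rng.normal(0.0, params.noise_sd_X, X.shape)
    if params.noise_sd_P > 0:
        P = P + rng.normal(0.0, params.noise_sd_P, P.shape)
    if params.noise_sd_S > 0:
        S = S + rng.normal(0.0, params.noise_sd_S, S.shape)
    return CultivationSeries(
        t_days=t,
        P_mg_per_L=np.clip(P, 0.0, None),
        X_g_per_L=np.clip(X, 0.0, None),
        S_g_per_L=np.clip(S, 0.0, None),
        condition=condition,
    )
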