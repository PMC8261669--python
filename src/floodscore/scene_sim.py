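"""Synthetic UAV scene generator for soybean flooding-injury plots.

Builds per-plot five-band reflectance stacks, thermal rasters (°C) and
ground-truth canopy masks for a field of single-row breeding plots scored
on a five-level flooding injury scale (FIS, 1 = no apparent injury,
5 = most plants severely injured or dead).  Flooding injury expresses
itself in the imagery the way it does in the field: injured plots are
hotter (reduced transpiration), less green (lower NDVI) and smaller
(canopy dieback).  Flights at 50 and 80 m above ground are emulated as a
ground-sampling-distance (GSD) change — exact area-average downsampling
with mixed pixels at canopy edges — plus atmospheric attenuation of the
thermal signal toward ambient air temperature.

Raster convention: row-major, origin top-left, image rows run along the
planted row (the "length" direction); 0-based indices.  Band order is
blue, green, red, red-edge, NIR throughout.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

BAND_NAMES: tuple[str, ...] = ("blue", "green", "red", "red_edge", "nir")
BLUE, GREEN, RED, RED_EDGE, NIR = range(5)
HEIGHTS_M: tuple[int, ...] = (20, 50, 80)

#: superellipse exponent of the canopy outline
_SHAPE_EXPONENT = 2.5
#: length/width aspect ratio of the canopy blob (single-row plots)
_CANOPY_ASPECT = 3.6
#: reflectance sum NIR + red inside the canopy; NDVI fixes their split
_CANOPY_BAND_SUM = 0.50
#: soil reflectance sum NIR + red
_SOIL_BAND_SUM = 0.556
#: base soil spectrum (blue, green, red*, red-edge, nir*); * rederived from NDVI
_SOIL_SPECTRUM = np.array([0.17, 0.22, 0.250, 0.28, 0.306])
#: dark plant residue spectrum
_RESIDUE_SPECTRUM = np.array([0.060, 0.070, 0.085, 0.095, 0.105])
#: shadow = soil spectrum scaled down by this factor
_SHADOW_FACTOR = 0.15
#: background composition (soil, shadow, residue) among non-canopy pixels
_BACKGROUND_MIX = (0.82, 0.10, 0.08)
#: canopy blue / green / red-edge reflectance means
_CANOPY_BLUE, _CANOPY_GREEN, _CANOPY_RED_EDGE = 0.05, 0.16, 0.26


def _default_noise() -> dict[str, float]:
    """Per-source noise standard deviations (reflectance units / °C)."""
    return {
        "ndvi_px": 0.04,       # per-pixel canopy NDVI
        "ndvi_plot": 0.02,     # per-plot canopy NDVI random effect
        "band": 0.012,         # additive, blue/green/red-edge
        "thermal": 0.7,        # per-pixel canopy temperature, °C
        "thermal_bg": 1.0,     # per-pixel background temperature, °C
        "temp_plot": 0.5,      # per-plot canopy temperature random effect
        "bg_plot": 0.6,        # per-plot background temperature random effect
        "area_plot": 0.07,     # multiplicative canopy-area random effect
        "soil_brightness": 0.06,  # multiplicative per-pixel soil brightness
        "soil_region": 0.5,    # per-region bare-soil temperature, °C
        "panel_dn": 0.0,       # calibration-panel DN noise
    }


@dataclass
class SimConfig:
    """Field-level simulation parameters.

    Defaults reproduce the 20 m flight conditions of the study design:
    724 scored single-row plots, grand-mean canopy temperature 39.0 °C,
    grand-mean canopy NDVI 0.51, bare soil at 52.3 °C, in-plot background
    at 49.4 °C, ambient air 33.4 °C.  The FIS→parameter maps are linear in
    FIS and centred so the class-proportion-weighted mixture hits those
    grand means.
    """

    n_plots: int = 724
    fis_probs: tuple[float, ...] = (0.18, 0.27, 0.27, 0.18, 0.10)
    plot_px_20m: tuple[int, int] = (160, 56)  # (rows, cols) at 20 m multispectral
    gsd_mm: Mapping[int, float] = field(
        default_factory=lambda: {20: 13.2, 50: 34.7, 80: 55.6})
    gsd_mm_thermal: Mapping[int, float] = field(
        default_factory=lambda: {20: 23.4, 50: 68.0, 80: 108.8})
    canopy_temp_mean_c: Mapping[int, float] = field(
        default_factory=lambda: {1: 37.075, 2: 38.175, 3: 39.275,
                                 4: 40.375, 5: 41.475})
    soil_temp_mean_c: float = 52.3
    background_temp_mean_c: float = 49.4
    canopy_ndvi_mean: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.60625, 2: 0.55125, 3: 0.49625,
                                 4: 0.44125, 5: 0.38625})
    soil_ndvi_mean: float = 0.10
    canopy_area_frac: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.58, 2: 0.50, 3: 0.42, 4: 0.33, 5: 0.22})
    noise_sd: float | Mapping[str, float] = field(default_factory=_default_noise)
    band_gains: tuple[float, ...] = (1.05, 0.98, 1.02, 1.00, 0.96)
    band_exposures: tuple[float, ...] = (0.85, 0.90, 0.80, 0.90, 0.95)
    band_illumination: tuple[float, ...] = (0.80, 0.85, 0.90, 0.85, 0.80)
    panel_reflectance: tuple[float, ...] = (0.52, 0.51, 0.50, 0.49, 0.48)
    attenuation_tau: Mapping[int, float] = field(
        default_factory=lambda: {20: 1.0, 50: 0.9259, 80: 0.7989})
    ambient_temp_c: float = 33.4
    # thermal sensor point-spread sigma, in output pixels, applied when
    # degrading to 50/80 m: microbolometer optics smear hot background
    # into canopy interiors once the canopy is only a few pixels wide
    thermal_psf_px: float = 1.3
    corner_light_drop: float | None = None  # optional exposure drop factor
    corner_frac: float = 0.05               # fraction of plots affected
    seed: int = 0

    def noise(self, key: str) -> float:
        if np.isscalar(self.noise_sd):
            return float(self.noise_sd)
        return float(self.noise_sd[key])  # type: ignore[index]

    def validate(self) -> None:
        probs = np.asarray(self.fis_probs, dtype=float)
        if probs.size != 5 or np.any(probs < 0):
            raise ValueError("fis_probs must be 5 nonnegative proportions")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("fis_probs must sum to 1")
        if self.n_plots < 5:
            raise ValueError("n_plots must be at least 5 (one per FIS level)")
        temps = [self.canopy_temp_mean_c[f] for f in range(1, 6)]
        if not np.all(np.isfinite(temps + [self.soil_temp_mean_c,
                                           self.background_temp_mean_c])):
            raise ValueError("temperature means must be finite")
        if any(t >= self.soil_temp_mean_c for t in temps):
            raise ValueError("canopy must be cooler than soil at every FIS")
        if any(self.canopy_ndvi_mean[f] <= self.soil_ndvi_mean
               for f in range(1, 6)):
            raise ValueError("canopy NDVI must exceed soil NDVI at every FIS")
        for gsd in (self.gsd_mm, self.gsd_mm_thermal):
            vals = [gsd[h] for h in HEIGHTS_M]
            if not np.all(np.diff(vals) > 0):
                raise ValueError("GSD must increase strictly with height")
        for name, vec in (("band_gains", self.band_gains),
                          ("band_exposures", self.band_exposures),
                          ("band_illumination", self.band_illumination)):
            if len(vec) != 5 or any(v <= 0 for v in vec):
                raise ValueError(f"{name} must be 5 positive scalars")
        if any(not 0 < r < 1 for r in self.panel_reflectance):
            raise ValueError("panel reflectance must lie in (0, 1)")
        for h in HEIGHTS_M:
            if not 0 < self.attenuation_tau[h] <= 1:
                raise ValueError("attenuation tau must lie in (0, 1]")


@dataclass
class PlotScene:
    """Ground truth for one plot at one flight height."""

    plot_id: str
    fis: int
    height_m: int
    reflectance: np.ndarray          # (rows, cols, 5) float32 in [0, 1]
    thermal: np.ndarray              # (rows_t, cols_t) float32 °C
    truth_mask: np.ndarray           # bool, multispectral grid
    truth_mask_thermal: np.ndarray   # bool, thermal grid
    gsd_mm: float = 13.2
    gsd_mm_thermal: float = 23.4
    row_direction: str = "rows"      # image axis running along the planted row
    degenerate: bool = False         # empty-canopy plot


@dataclass
class RawCapture:
    """Uncalibrated 16-bit digital numbers plus the panel capture."""

    plot_id: str
    dn_bands: np.ndarray        # (rows, cols, 5) uint16
    panel_dn: np.ndarray        # (panel_rows, panel_cols, 5) uint16
    gains: tuple[float, ...]
    exposures: tuple[float, ...]
    panel_reflectance: tuple[float, ...]


# ---------------------------------------------------------------------------
# canopy geometry
# ---------------------------------------------------------------------------

def _superellipse_area_factor(exponent: float) -> float:
    from scipy.special import gamma
    return 4 * gamma(1 + 1 / exponent) ** 2 / gamma(1 + 2 / exponent)


_AREA_FACTOR = _superellipse_area_factor(_SHAPE_EXPONENT)


def _canopy_mask(shape: tuple[int, int], gsd_m: float, extent_m: tuple[float, float],
                 area_m2: float, fourier: np.ndarray) -> np.ndarray:
    """Boolean canopy mask on a pixel grid, from a noisy superellipse.

    The outline is defined in physical (metre) coordinates so the
    multispectral and thermal grids see the same plant.
    """
    if area_m2 <= 0:
        return np.zeros(shape, dtype=bool)
    len_r, len_c = extent_m
    b = np.sqrt(area_m2 / (_AREA_FACTOR * _CANOPY_ASPECT))
    a = _CANOPY_ASPECT * b
    a = min(a, 0.49 * len_r)
    b = min(b, 0.49 * len_c)
    rows = (np.arange(shape[0]) + 0.5) * gsd_m
    cols = (np.arange(shape[1]) + 0.5) * gsd_m
    u = (rows - len_r / 2)[:, None] / a
    v = (cols - len_c / 2)[None, :] / b
    rho = (np.abs(u) ** _SHAPE_EXPONENT
           + np.abs(v) ** _SHAPE_EXPONENT) ** (1 / _SHAPE_EXPONENT)
    theta = np.arctan2(v, u)
    wobble = np.zeros_like(rho)
    for k in range(fourier.shape[1]):
        wobble += (fourier[0, k] * np.cos((k + 1) * theta)
                   + fourier[1, k] * np.sin((k + 1) * theta))
    return rho <= 1.0 + wobble


# ---------------------------------------------------------------------------
# field generation (20 m ground truth)
# ---------------------------------------------------------------------------

def _thermal_shape(config: SimConfig, ms_shape: tuple[int, int]) -> tuple[int, int]:
    ratio = config.gsd_mm[20] / config.gsd_mm_thermal[20]
    return (max(1, round(ms_shape[0] * ratio)), max(1, round(ms_shape[1] * ratio)))


def _render_plot(fis: int, config: SimConfig, rng: np.random.Generator,
                 plot_id: str) -> PlotScene:
    ms_shape = tuple(config.plot_px_20m)
    th_shape = _thermal_shape(config, ms_shape)
    gsd_ms = config.gsd_mm[20] / 1000.0
    gsd_th = config.gsd_mm_thermal[20] / 1000.0
    extent = (ms_shape[0] * gsd_ms, ms_shape[1] * gsd_ms)

    area_jit = 1.0 + rng.normal(0.0, config.noise("area_plot"))
    area_m2 = max(0.0, config.canopy_area_frac[fis] * area_jit) * extent[0] * extent[1]
    fourier = rng.normal(0.0, 0.04, size=(2, 4))
    mask = _canopy_mask(ms_shape, gsd_ms, extent, area_m2, fourier)
    mask_th = _canopy_mask(th_shape, gsd_th, extent, area_m2, fourier)
    degenerate = not mask.any()

    # --- multispectral reflectance ------------------------------------
    n_plot = config.canopy_ndvi_mean[fis] + rng.normal(0.0, config.noise("ndvi_plot"))
    refl = np.empty(ms_shape + (5,), dtype=np.float64)

    bg = ~mask
    n_bg = int(bg.sum())
    kind = rng.choice(3, size=n_bg, p=_BACKGROUND_MIX)  # 0 soil, 1 shadow, 2 residue
    bg_px = np.empty((n_bg, 5))
    soil = kind == 0
    w = 1.0 + rng.normal(0.0, config.noise("soil_brightness"), size=int(soil.sum()))
    n_soil = config.soil_ndvi_mean + rng.normal(
        0.0, 0.5 * config.noise("ndvi_px"), size=int(soil.sum()))
    soil_px = np.tile(_SOIL_SPECTRUM, (int(soil.sum()), 1)) * w[:, None]
    soil_px[:, RED] = (1 - n_soil) * _SOIL_BAND_SUM * w / 2
    soil_px[:, NIR] = (1 + n_soil) * _SOIL_BAND_SUM * w / 2
    bg_px[soil] = soil_px
    shadow = kind == 1
    bg_px[shadow] = _SOIL_SPECTRUM * _SHADOW_FACTOR + rng.normal(
        0.0, 0.004, size=(int(shadow.sum()), 5))
    residue = kind == 2
    wr = 1.0 + rng.normal(0.0, 0.08, size=(int(residue.sum()), 1))
    bg_px[residue] = _RESIDUE_SPECTRUM * wr
    refl[bg] = bg_px

    n_can = int(mask.sum())
    n_px = np.clip(n_plot + rng.normal(0.0, config.noise("ndvi_px"), size=n_can),
                   -0.2, 0.95)
    can_px = np.empty((n_can, 5))
    can_px[:, BLUE] = _CANOPY_BLUE + rng.normal(0, config.noise("band"), n_can)
    can_px[:, GREEN] = _CANOPY_GREEN + rng.normal(0, config.noise("band"), n_can)
    can_px[:, RED_EDGE] = _CANOPY_RED_EDGE + rng.normal(0, config.noise("band"), n_can)
    can_px[:, RED] = (1 - n_px) * _CANOPY_BAND_SUM / 2
    can_px[:, NIR] = (1 + n_px) * _CANOPY_BAND_SUM / 2
    refl[mask] = can_px
    np.clip(refl, 0.0, 1.0, out=refl)

    # --- thermal -------------------------------------------------------
    t_plot = config.canopy_temp_mean_c[fis] + rng.normal(0.0, config.noise("temp_plot"))
    t_bg = config.background_temp_mean_c + rng.normal(0.0, config.noise("bg_plot"))
    thermal = np.where(
        mask_th,
        t_plot + rng.normal(0.0, config.noise("thermal"), th_shape),
        t_bg + rng.normal(0.0, config.noise("thermal_bg"), th_shape),
    )

    return PlotScene(
        plot_id=plot_id, fis=int(fis), height_m=20,
        reflectance=refl.astype(np.float32),
        thermal=thermal.astype(np.float32),
        truth_mask=mask, truth_mask_thermal=mask_th,
        gsd_mm=config.gsd_mm[20], gsd_mm_thermal=config.gsd_mm_thermal[20],
        degenerate=degenerate,
    )


def _class_counts_to_labels(probs: np.ndarray, n: int) -> np.ndarray:
    """FIS labels with fixed class counts (largest-remainder rounding).

    A scored field has one definite injury-score histogram; emulating it
    with fixed counts (rather than per-plot multinomial draws) keeps the
    class composition at the configured proportions for every seed, while
    the seed still randomizes which plot gets which score.
    """
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return np.repeat(np.arange(1, 6), counts)


def generate_field(config: SimConfig) -> tuple[list[PlotScene], pd.DataFrame]:
    """Generate the full field of scored plots at the 20 m flight height.

    Returns the list of scenes plus a manifest table (plot_id, fis,
    height_m, GSDs).  Identical config (including seed) gives
    bit-identical output.
    """
    config.validate()
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1E1D]))
    fis_labels = master.permutation(_class_counts_to_labels(
        np.asarray(config.fis_probs, dtype=float), config.n_plots))
    scenes = []
    for i, fis in enumerate(fis_labels):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, i]))
        scenes.append(_render_plot(int(fis), config, rng, f"plot_{i:04d}"))
    n_deg = sum(s.degenerate for s in scenes)
    if n_deg:
        logger.warning("%d plots have an empty canopy (degenerate)", n_deg)
    manifest = pd.DataFrame({
        "plot_id": [s.plot_id for s in scenes],
        "fis": [s.fis for s in scenes],
        "height_m": [s.height_m for s in scenes],
        "gsd_mm": [s.gsd_mm for s in scenes],
        "gsd_mm_thermal": [s.gsd_mm_thermal for s in scenes],
        "degenerate": [s.degenerate for s in scenes],
    })
    return scenes, manifest


def generate_soil_regions(config: SimConfig, height_m: int = 20, n_regions: int = 10,
                          shape: tuple[int, int] = (40, 40),
                          seed: int | None = None) -> list[np.ndarray]:
    """Thermal rasters of bare-soil sample locations (no canopy at all).

    Emulates hand-picked bare-soil patches used to track how apparent soil
    temperature changes with flight height.  Attenuation toward ambient is
    the only height effect (a uniform target has no mixed-pixel bias).
    """
    if height_m not in HEIGHTS_M:
        raise ValueError(f"unknown flight height {height_m}")
    seed = config.seed if seed is None else seed
    tau = config.attenuation_tau[height_m]
    regions = []
    for i in range(n_regions):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, i]))
        mean = config.soil_temp_mean_c + rng.normal(0.0, config.noise("soil_region"))
        raster = mean + rng.normal(0.0, config.noise("thermal_bg"), shape)
        regions.append(tau * raster + (1 - tau) * config.ambient_temp_c)
    return regions


# ---------------------------------------------------------------------------
# flight-height degradation
# ---------------------------------------------------------------------------

def area_downsample(arr: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Exact area-average downsampling to ``out_shape``.

    Each output pixel is the mean of the source image over its (generally
    fractional) footprint, computed from the integral image — the integral
    of a piecewise-constant image is piecewise bilinear, so sampling it
    with linear interpolation at fractional box corners is exact.
    """
    arr = np.asarray(arr, dtype=np.float64)
    h, w = arr.shape[:2]
    oh, ow = out_shape
    if (oh, ow) == (h, w):
        return arr.copy()
    flat = arr.reshape(h, w, -1)
    integral = np.zeros((h + 1, w + 1, flat.shape[2]))
    integral[1:, 1:] = flat.cumsum(0).cumsum(1)

    def sample_axis(grid: np.ndarray, coords: np.ndarray, axis: int) -> np.ndarray:
        idx = np.clip(np.floor(coords).astype(int), 0, grid.shape[axis] - 2)
        frac = coords - idx
        lo = np.take(grid, idx, axis=axis)
        hi = np.take(grid, idx + 1, axis=axis)
        shape = [1] * lo.ndim
        shape[axis] = len(coords)
        return lo + (hi - lo) * frac.reshape(shape)

    ys = np.linspace(0.0, h, oh + 1)
    xs = np.linspace(0.0, w, ow + 1)
    corner = sample_axis(sample_axis(integral, ys, 0), xs, 1)
    box = (corner[1:, 1:] - corner[:-1, 1:] - corner[1:, :-1] + corner[:-1, :-1])
    box /= (h / oh) * (w / ow)
    return box.reshape((oh, ow) + arr.shape[2:])


def _down_shape(shape: tuple[int, int], ratio: float) -> tuple[int, int]:
    return (max(1, int(shape[0] / ratio)), max(1, int(shape[1] / ratio)))


def degrade_to_height(scene: PlotScene, height_m: int, config: SimConfig) -> PlotScene:
    """Emulate a higher flight: coarser GSD plus thermal attenuation.

    All rasters are area-average downsampled by the GSD ratio (mixed
    pixels appear at canopy edges); the thermal raster is additionally
    mapped T_obs = tau·T + (1 − tau)·T_ambient; truth masks are
    downsampled by majority vote.
    """
    if scene.height_m != 20:
        raise ValueError("degrade_to_height expects a 20 m ground-truth scene")
    if height_m == 20:
        return scene
    if height_m not in HEIGHTS_M:
        raise ValueError(f"unknown flight height {height_m}")
    r_ms = config.gsd_mm[height_m] / config.gsd_mm[20]
    r_th = config.gsd_mm_thermal[height_m] / config.gsd_mm_thermal[20]
    ms_shape = _down_shape(scene.reflectance.shape[:2], r_ms)
    th_shape = _down_shape(scene.thermal.shape, r_th)
    refl = area_downsample(scene.reflectance, ms_shape)
    tau = config.attenuation_tau[height_m]
    thermal_ds = area_downsample(scene.thermal, th_shape)
    if config.thermal_psf_px > 0:
        from scipy.ndimage import gaussian_filter
        thermal_ds = gaussian_filter(thermal_ds, config.thermal_psf_px,
                                     mode="nearest")
    thermal = tau * thermal_ds + (1 - tau) * config.ambient_temp_c
    mask = area_downsample(scene.truth_mask.astype(np.float64), ms_shape) > 0.5
    mask_th = area_downsample(scene.truth_mask_thermal.astype(np.float64),
                              th_shape) > 0.5
    return PlotScene(
        plot_id=scene.plot_id, fis=scene.fis, height_m=height_m,
        reflectance=refl.astype(np.float32), thermal=thermal.astype(np.float32),
        truth_mask=mask, truth_mask_thermal=mask_th,
        gsd_mm=config.gsd_mm[height_m],
        gsd_mm_thermal=config.gsd_mm_thermal[height_m],
        degenerate=not mask.any(),
    )


# ---------------------------------------------------------------------------
# raw-capture rendering (inverse of radiometric calibration)
# ---------------------------------------------------------------------------

def band_scale(config: SimConfig) -> np.ndarray:
    """Per-band DN scale: illumination · gain · exposure · 65535."""
    return (np.asarray(config.band_illumination)
            * np.asarray(config.band_gains)
            * np.asarray(config.band_exposures) * 65535.0)


def render_raw_capture(scene: PlotScene, config: SimConfig,
                       panel_shape: tuple[int, int] = (32, 32),
                       exposure_scale: float = 1.0,
                       rng: np.random.Generator | None = None) -> RawCapture:
    """Render 16-bit raw digital numbers (DN) for a scene plus a panel capture.

    Forward model per band b:  DN = round(clip(R · I_b · g_b · x_b · 65535)),
    with I the scene illumination, g the sensor gain and x the exposure.
    The calibration-reflectance-panel capture uses the same model, so
    panel-based calibration recovers reflectance to quantization accuracy.
    ``exposure_scale`` emulates auto-exposure compensation (all bands).
    """
    if any(g <= 0 for g in config.band_gains) or \
            any(x <= 0 for x in config.band_exposures) or exposure_scale <= 0:
        raise ValueError("gains and exposures must be positive")
    scale = band_scale(config) * exposure_scale
    dn = np.clip(np.rint(scene.reflectance.astype(np.float64) * scale),
                 0, 65535).astype(np.uint16)
    panel = np.broadcast_to(np.asarray(config.panel_reflectance) * scale,
                            panel_shape + (5,)).copy()
    sd = config.noise("panel_dn")
    if sd > 0:
        rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        panel += rng.normal(0.0, sd, panel.shape)
    panel_dn = np.clip(np.rint(panel), 0, 65535).astype(np.uint16)
    exposures = tuple(x * exposure_scale for x in config.band_exposures)
    return RawCapture(plot_id=scene.plot_id, dn_bands=dn, panel_dn=panel_dn,
                      gains=tuple(config.band_gains), exposures=exposures,
                      panel_reflectance=tuple(config.panel_reflectance))


def render_field_captures(scenes: list[PlotScene], config: SimConfig
                          ) -> list[RawCapture]:
    """Raw captures for a whole field; applies the optional corner light drop.

    When ``corner_light_drop`` is set, the last ``corner_frac`` of the
    plots are rendered under a global exposure drop, emulating a sudden
    light change over one corner of the field during the mission.
    """
    n_corner = 0
    if config.corner_light_drop is not None:
        n_corner = int(round(config.corner_frac * len(scenes)))
    captures = []
    for i, scene in enumerate(scenes):
        drop = (config.corner_light_drop
                if n_corner and i >= len(scenes) - n_corner else 1.0)
        captures.append(render_raw_capture(scene, config, exposure_scale=drop))
    return captures


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_field(scenes: list[PlotScene], captures: list[RawCapture],
                manifest: pd.DataFrame, config: SimConfig, outdir: str | Path
                ) -> Path:
    """Write DN band TIFFs, thermal TIFFs, panel TIFFs, manifest and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scene, cap in zip(scenes, captures):
        entry = {"plot_id": scene.plot_id, "fis": scene.fis,
                 "height_m": scene.height_m, "gsd_mm": scene.gsd_mm,
                 "gsd_mm_thermal": scene.gsd_mm_thermal}
        for b, name in enumerate(BAND_NAMES):
            path = outdir / f"{scene.plot_id}_{name}.tif"
            tifffile.imwrite(path, cap.dn_bands[:, :, b])
            entry[f"file_{name}"] = path.name
        tpath = outdir / f"{scene.plot_id}_thermal.tif"
        tifffile.imwrite(tpath, scene.thermal.astype(np.float32))
        entry["file_thermal"] = tpath.name
        rows.append(entry)
    panel = captures[0].panel_dn
    for b, name in enumerate(BAND_NAMES):
        tifffile.imwrite(outdir / f"panel_{name}.tif", panel[:, :, b])
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    cfg = dataclasses.asdict(config)
    cfg["band_order"] = list(BAND_NAMES)
    for key, val in cfg.items():
        if isinstance(val, Mapping):
            cfg[key] = {k: v for k, v in val.items()}
    with open(outdir / "simconfig.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=False)
    return outdir


def config_from_dict(d: dict) -> SimConfig:
    """Rebuild a SimConfig from its YAML echo (restores key/value types)."""
    d = dict(d)
    d.pop("band_order", None)
    for key in ("gsd_mm", "gsd_mm_thermal", "canopy_temp_mean_c",
                "canopy_ndvi_mean", "canopy_area_frac", "attenuation_tau"):
        if key in d and isinstance(d[key], dict):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
    for key in ("fis_probs", "plot_px_20m", "band_gains", "band_exposures",
                "band_illumination", "panel_reflectance"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)


def read_field(outdir: str | Path) -> tuple[pd.DataFrame, SimConfig]:
    """Read back a written field's manifest and configuration."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    with open(outdir / "simconfig.yaml") as fh:
        cfg = config_from_dict(yaml.safe_load(fh))
    return manifest, cfg


def read_capture(outdir: str | Path, manifest_row: pd.Series,
                 config: SimConfig) -> tuple[RawCapture, np.ndarray]:
    """Reconstruct one plot's raw capture and thermal raster from disk."""
    outdir = Path(outdir)
    dn = np.stack([tifffile.imread(outdir / manifest_row[f"file_{name}"])
                   for name in BAND_NAMES], axis=-1)
    panel = np.stack([tifffile.imread(outdir / f"panel_{name}.tif")
                      for name in BAND_NAMES], axis=-1)
    thermal = tifffile.imread(outdir / manifest_row["file_thermal"])
    capture = RawCapture(plot_id=manifest_row["plot_id"], dn_bands=dn,
                         panel_dn=panel, gains=tuple(config.band_gains),
                         exposures=tuple(config.band_exposures),
                         panel_reflectance=tuple(config.panel_reflectance))
    return capture, thermal
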