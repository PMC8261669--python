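"""Radiometric calibration: raw digital numbers to reflectance.

Two conversions are supported.  The unified-factor method divides the
radiance of a calibration reflectance panel (CRP) by its known per-band
reflectance to obtain one radiance→reflectance scale factor per band; it
assumes constant illumination over the mission.  The max-min method
simply rescales 16-bit DN by the full range 0–65535, which is robust when
the camera auto-adjusts exposure between frames (a global light change
is compensated in the DN themselves) but carries no absolute scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .scene_sim import BAND_NAMES, RawCapture

logger = logging.getLogger(__name__)

DN_MAX = 65535.0


@dataclass
class PanelReading:
    """Per-band mean panel radiance (model units) + known panel reflectance."""

    radiance: np.ndarray          # shape (5,), > 0
    known_reflectance: np.ndarray  # shape (5,), in (0, 1)

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        self.known_reflectance = np.asarray(self.known_reflectance, dtype=float)
        if np.any(self.radiance <= 0):
            raise ValueError("panel radiance must be positive (unusable capture)")
        if np.any((self.known_reflectance <= 0) | (self.known_reflectance >= 1)):
            raise ValueError("known panel reflectance must lie in (0, 1)")


@dataclass
class ReflectanceStack:
    """Calibrated 5-band reflectance in [0, 1] plus the method tag."""

    data: np.ndarray   # (rows, cols, 5)
    method: str        # "unified_factor" | "max_min"
    band_names: tuple[str, ...] = BAND_NAMES
    n_clipped: int = 0


def dn_to_radiance(dn_band: np.ndarray, gain: float, exposure: float) -> np.ndarray:
    """Convert one band of raw DN to radiance in model units.

    radiance = DN / (gain · exposure · 65535); the sensor model has a flat
    vignette, so the conversion is a single per-band scale.
    """
    if gain <= 0 or exposure <= 0:
        raise ValueError("gain and exposure must be positive")
    return np.asarray(dn_band, dtype=np.float64) / (gain * exposure * DN_MAX)


def read_panel(capture: RawCapture, crop_frac: float = 0.5) -> PanelReading:
    """Summarize a panel capture as per-band mean radiance over a central crop.

    The central ``crop_frac`` box (by side length) stands in for the
    interactive crop of the panel in the calibration dialog.
    """
    panel = np.asarray(capture.panel_dn, dtype=np.float64)
    h, w = panel.shape[:2]
    dr, dc = int(h * (1 - crop_frac) / 2), int(w * (1 - crop_frac) / 2)
    crop = panel[dr:h - dr or None, dc:w - dc or None]
    radiance = np.array([
        dn_to_radiance(crop[:, :, b], capture.gains[b], capture.exposures[b]).mean()
        for b in range(5)])
    return PanelReading(radiance=radiance,
                        known_reflectance=np.asarray(capture.panel_reflectance))


def unified_factor_reflectance(radiance_bands: np.ndarray,
                               panel: PanelReading) -> ReflectanceStack:
    """Panel-based calibration: reflectance = radiance · (ρ_panel / L_panel).

    The per-band factor is the known panel reflectance divided by the
    measured panel radiance; applying it to the panel image itself returns
    the known reflectance.  Out-of-range results are clipped to [0, 1]
    with a logged count.
    """
    radiance = np.asarray(radiance_bands, dtype=np.float64)
    factor = panel.known_reflectance / panel.radiance
    refl = radiance * factor
    n_clipped = int(np.sum((refl < 0) | (refl > 1)))
    if n_clipped:
        logger.info("unified-factor: clipped %d out-of-range pixels", n_clipped)
    return ReflectanceStack(data=np.clip(refl, 0.0, 1.0),
                            method="unified_factor", n_clipped=n_clipped)


def calibrate_capture(capture: RawCapture,
                      panel: PanelReading | None = None) -> ReflectanceStack:
    """Unified-factor calibration of a full 5-band raw capture."""
    if panel is None:
        panel = read_panel(capture)
    radiance = np.stack([
        dn_to_radiance(capture.dn_bands[:, :, b], capture.gains[b],
                       capture.exposures[b])
        for b in range(5)], axis=-1)
    return unified_factor_reflectance(radiance, panel)


def maxmin_reflectance(dn_bands: np.ndarray) -> ReflectanceStack:
    """Rescale raw DN by the 16-bit full range: value = DN / 65535."""
    dn = np.asarray(dn_bands, dtype=np.float64)
    if dn.min() < 0 or dn.max() > DN_MAX:
        raise ValueError("DN values must lie in [0, 65535]")
    return ReflectanceStack(data=dn / DN_MAX, method="max_min")


def write_reflectance(stack: ReflectanceStack, path: str | Path) -> None:
    """Write a stack as multi-page float32 TIFF plus a sidecar method tag."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(stack.data.astype(np.float32), -1, 0),
                     photometric="minisblack")
    sidecar = {"method": stack.method, "band_order": list(stack.band_names),
               "n_clipped": stack.n_clipped}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_reflectance(path: str | Path) -> ReflectanceStack:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, -1).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ReflectanceStack(data=data, method=meta["method"],
                            band_names=tuple(meta["band_order"]),
                            n_clipped=meta.get("n_clipped", 0))
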