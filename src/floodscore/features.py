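"""Plot-level image features.

Five features per plot: canopy temperature (mean °C over the thermal
mask), mean NDVI over the multispectral mask, canopy area (pixel count),
canopy width (occupied image columns) and length (occupied image rows).
The two sensors have different ground sampling distances, so thermal and
multispectral features are computed on their own grids with no
cross-sensor resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .radiometric import ReflectanceStack
from .scene_sim import NIR, RED
from .segmentation import CanopyMask

FEATURE_COLUMNS = ("canopy_temp_c", "ndvi_mean", "area_px", "width_px", "length_px")


@dataclass
class FeatureRecord:
    plot_id: str
    fis: int
    height_m: int
    canopy_temp_c: float
    ndvi_mean: float
    area_px: int
    width_px: int
    length_px: int
    valid: bool = True


def compute_ndvi(stack: ReflectanceStack,
                 mask: CanopyMask | None = None) -> tuple[np.ndarray, float]:
    """Per-pixel NDVI = (NIR − R)/(NIR + R) and its mean over the mask.

    Pixels with NIR + R = 0 are undefined (NaN) and excluded from the
    mean.  With an empty (or None) mask the mean is NaN.
    """
    data = np.asarray(stack.data, dtype=np.float64)
    nir, red = data[:, :, NIR], data[:, :, RED]
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0),
                        np.nan)
    if mask is None or mask.empty:
        return ndvi, float("nan")
    vals = ndvi[mask.mask]
    vals = vals[np.isfinite(vals)]
    return ndvi, (float(vals.mean()) if vals.size else float("nan"))


def canopy_geometry(mask: CanopyMask | np.ndarray) -> tuple[int, int, int]:
    """(area, width, length) of a canopy mask.

    Area is the count of true pixels; length the number of image rows
    containing at least one true pixel (rows run along the planted row);
    width the number of occupied image columns.  Empty mask → (0, 0, 0).
    """
    m = mask.mask if isinstance(mask, CanopyMask) else np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area == 0:
        return 0, 0, 0
    length = int(m.any(axis=1).sum())
    width = int(m.any(axis=0).sum())
    return area, width, length


def canopy_temperature(thermal: np.ndarray, mask: CanopyMask) -> float:
    """Mean temperature (°C) over the thermal canopy mask; NaN if empty."""
    if mask.empty:
        return float("nan")
    thermal = np.asarray(thermal, dtype=np.float64)
    if thermal.shape != mask.mask.shape:
        raise ValueError("thermal raster and mask shapes differ")
    return float(thermal[mask.mask].mean())


def extract_features(plot_id: str, fis: int, height_m: int,
                     stack: ReflectanceStack, thermal: np.ndarray,
                     ms_mask: CanopyMask, thermal_mask: CanopyMask
                     ) -> FeatureRecord:
    """Assemble the five features for one plot at one height."""
    area, width, length = canopy_geometry(ms_mask)
    _, ndvi_mean = compute_ndvi(stack, ms_mask)
    temp = canopy_temperature(thermal, thermal_mask)
    valid = area > 0 and not thermal_mask.empty and np.isfinite(ndvi_mean) \
        and np.isfinite(temp)
    return FeatureRecord(plot_id=plot_id, fis=int(fis), height_m=int(height_m),
                         canopy_temp_c=temp, ndvi_mean=ndvi_mean,
                         area_px=area, width_px=width, length_px=length,
                         valid=bool(valid))


def features_table(records: list[FeatureRecord]) -> pd.DataFrame:
    """One row per plot × height, in the features.csv column layout."""
    return pd.DataFrame([{
        "plot_id": r.plot_id, "fis": r.fis, "height_m": r.height_m,
        "canopy_temp_c": r.canopy_temp_c, "ndvi_mean": r.ndvi_mean,
        "area_px": r.area_px, "width_px": r.width_px, "length_px": r.length_px,
        "valid": r.valid} for r in records])


def px_to_cm(value_px: float, gsd_mm: float) -> float:
    """Optional physical-unit conversion (pixels → cm) via the GSD."""
    return value_px * gsd_mm / 10.0
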