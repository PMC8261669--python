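"""Canopy/background segmentation.

Multispectral plot images are segmented by a stepwise colour-space
procedure: (1) a YCbCr box on the red/NIR/red-edge false-colour composite
removes the bulk of the soil, (2) a YCbCr box on the true-colour (RGB)
composite removes remaining soil near the canopy, (3) an HSV box removes
dark pixels (shadow, fallen leaves, residue), and (4) connected
components smaller than 1% of the image area are discarded as noise.
Each step can only shrink the mask.  Thermal plot images are segmented by
1-D K-means with k = 2 on temperature; the cooler cluster is the canopy
(transpiring plants are cooler than sun-exposed soil).

The numeric threshold boxes below were fixed once on a frozen synthetic
fixture field (default configuration, seed 0) and shipped as defaults;
they describe *background* colour regions, i.e. a pixel inside a box is
removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import measure
from sklearn.cluster import KMeans

from .radiometric import ReflectanceStack
from .scene_sim import BLUE, GREEN, NIR, RED, RED_EDGE

logger = logging.getLogger(__name__)

Box3 = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


@dataclass
class CanopyMask:
    mask: np.ndarray                  # bool raster
    source: str                       # "multispectral" | "thermal"
    n_regions_removed: int = 0
    log: dict = field(default_factory=dict)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return not self.mask.any()


@dataclass
class ThresholdSet:
    """Per-step background boxes; all bounds inclusive, lo <= hi.

    ``step1_ycbcr`` acts on the (red, NIR, red-edge) composite mapped to
    (R, G, B) in that order; ``step2_ycbcr`` on the (red, green, blue)
    true-colour composite; ``step3_hsv`` is an (S, V) box for dark pixels.
    YCbCr uses the ITU-R BT.601 scaling (Y 16–235, Cb/Cr 16–240).
    """

    step1_ycbcr: Box3 = ((40.0, 120.0), (118.0, 136.0), (116.5, 135.0))
    step2_ycbcr: Box3 = ((55.0, 80.0), (118.0, 126.0), (129.0, 136.5))
    step3_hsv_sv: tuple[tuple[float, float], tuple[float, float]] = \
        ((0.0, 1.0), (0.0, 0.10))
    step4_min_area_frac: float = 0.01

    def validate(self) -> None:
        for box in (self.step1_ycbcr, self.step2_ycbcr, self.step3_hsv_sv):
            for lo, hi in box:
                if lo > hi:
                    raise ValueError("threshold bounds must satisfy lo <= hi")
        if not 0 < self.step4_min_area_frac < 1:
            raise ValueError("min area fraction must lie in (0, 1)")


DEFAULT_THRESHOLDS = ThresholdSet()

_SPACES = {"HSV": skcolor.rgb2hsv, "YCbCr": skcolor.rgb2ycbcr,
           "Lab": skcolor.rgb2lab}
_INVERSE = {"HSV": skcolor.hsv2rgb, "YCbCr": skcolor.ycbcr2rgb,
            "Lab": skcolor.lab2rgb}


def to_color_space(raster3: np.ndarray, space: str) -> np.ndarray:
    """Standard colour transform (BT.601 YCbCr, D65 Lab) of an RGB image."""
    raster3 = np.asarray(raster3, dtype=np.float64)
    if raster3.ndim != 3 or raster3.shape[-1] != 3:
        raise ValueError("expected an (rows, cols, 3) image")
    if raster3.min() < 0 or raster3.max() > 1:
        raise ValueError("channel values must lie in [0, 1]")
    try:
        return _SPACES[space](raster3)
    except KeyError:
        raise ValueError(f"unknown colour space {space!r}") from None


def from_color_space(raster3: np.ndarray, space: str) -> np.ndarray:
    """Inverse transform back to RGB (identity round trip on in-gamut values)."""
    try:
        return _INVERSE[space](np.asarray(raster3, dtype=np.float64))
    except KeyError:
        raise ValueError(f"unknown colour space {space!r}") from None


def _in_box(img3: np.ndarray, box) -> np.ndarray:
    keep = np.ones(img3.shape[:2], dtype=bool)
    for c, (lo, hi) in enumerate(box):
        keep &= (img3[:, :, c] >= lo) & (img3[:, :, c] <= hi)
    return keep


def area_noise_filter(mask: np.ndarray, min_fraction: float) -> CanopyMask:
    """Drop 8-connected components smaller than ``min_fraction`` of the image.

    Removal uses a strict "<": a component of exactly the threshold size
    is retained.
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    out = mask.copy()
    threshold = min_fraction * mask.size
    removed = 0
    for region in measure.regionprops(labels):
        if region.area < threshold:
            out[labels == region.label] = False
            removed += 1
    return CanopyMask(mask=out, source="multispectral",
                      n_regions_removed=removed,
                      log={"removed_components": removed})


def remove_background_multispectral(stack: ReflectanceStack,
                                    thresholds: ThresholdSet | None = None,
                                    ) -> CanopyMask:
    """Stepwise background removal on a calibrated 5-band stack.

    Returns the final canopy mask with per-step pixel-removal counts in
    the log.  An empty result after any step is returned as an empty mask
    with a warning (the plot is flagged, mirroring dead plots).
    """
    thr = thresholds or DEFAULT_THRESHOLDS
    thr.validate()
    data = np.asarray(stack.data, dtype=np.float64)
    if data.ndim != 3 or data.shape[-1] != 5:
        raise ValueError("expected an (rows, cols, 5) reflectance stack")
    log: dict = {}
    mask = np.ones(data.shape[:2], dtype=bool)

    # step 1: YCbCr box on the red / NIR / red-edge composite (soil bulk)
    composite = np.clip(data[:, :, [RED, NIR, RED_EDGE]], 0, 1)
    ycbcr = to_color_space(composite, "YCbCr")
    step1 = mask & ~_in_box(ycbcr, thr.step1_ycbcr)
    log["step1_removed"] = int(mask.sum() - step1.sum())
    mask = step1

    # step 2: YCbCr box on the masked true-colour composite (residual soil)
    rgb = np.clip(data[:, :, [RED, GREEN, BLUE]], 0, 1)
    ycbcr2 = to_color_space(rgb, "YCbCr")
    step2 = mask & ~_in_box(ycbcr2, thr.step2_ycbcr)
    log["step2_removed"] = int(mask.sum() - step2.sum())
    mask = step2

    # step 3: HSV dark-pixel removal (shadow, fallen leaves, residue)
    hsv = to_color_space(rgb, "HSV")
    sv = hsv[:, :, 1:3]
    dark = np.ones(sv.shape[:2], dtype=bool)
    for c, (lo, hi) in enumerate(thr.step3_hsv_sv):
        dark &= (sv[:, :, c] >= lo) & (sv[:, :, c] <= hi)
    step3 = mask & ~dark
    log["step3_removed"] = int(mask.sum() - step3.sum())
    mask = step3

    # step 4: area noise filter
    filtered = area_noise_filter(mask, thr.step4_min_area_frac)
    log["step4_removed"] = int(mask.sum() - filtered.mask.sum())
    log["removed_components"] = filtered.n_regions_removed
    mask = filtered.mask

    if not mask.any():
        logger.warning("empty canopy mask after background removal")
    return CanopyMask(mask=mask, source="multispectral",
                      n_regions_removed=filtered.n_regions_removed, log=log)


def kmeans_thermal_mask(thermal: np.ndarray, seed: int = 0) -> CanopyMask:
    """Two-cluster 1-D K-means on temperature; canopy = cooler cluster.

    k-means++ initialisation with a fixed seed, at most 300 iterations,
    tolerance 1e-6.  The output is invariant to cluster label permutation
    because the canopy is chosen by cluster mean, not by label.
    """
    thermal = np.asarray(thermal, dtype=np.float64)
    values = thermal.reshape(-1, 1)
    if np.ptp(values) == 0:
        raise ValueError("constant thermal raster: no canopy/background split")
    km = KMeans(n_clusters=2, init="k-means++", n_init=1, max_iter=300,
                tol=1e-6, random_state=seed).fit(values)
    centers = km.cluster_centers_.ravel()
    cool = int(np.argmin(centers))
    mask = (km.labels_ == cool).reshape(thermal.shape)
    return CanopyMask(mask=mask, source="thermal",
                      log={"cluster_means": sorted(centers.tolist())})
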