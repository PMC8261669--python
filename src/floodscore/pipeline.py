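"""End-to-end plumbing: scene → raw capture → calibration → mask → features.

Composes the stage modules for a whole synthetic field at one flight
height, returning the plot-level feature table the statistics and
classifier stages consume.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import fnn_classifier, radiometric, scene_sim, segmentation
from .features import FeatureRecord, extract_features, features_table
from .scene_sim import PlotScene, SimConfig
from .segmentation import ThresholdSet

logger = logging.getLogger(__name__)


def process_plot(scene: PlotScene, config: SimConfig,
                 thresholds: ThresholdSet | None = None,
                 calibration: str = "unified_factor") -> FeatureRecord:
    """Render, calibrate, segment and featurize a single plot scene."""
    capture = scene_sim.render_raw_capture(scene, config)
    if calibration == "unified_factor":
        stack = radiometric.calibrate_capture(capture)
    elif calibration == "max_min":
        stack = radiometric.maxmin_reflectance(capture.dn_bands)
    else:
        raise ValueError(f"unknown calibration method {calibration!r}")
    ms_mask = segmentation.remove_background_multispectral(stack, thresholds)
    thermal_mask = segmentation.kmeans_thermal_mask(scene.thermal,
                                                    seed=config.seed)
    return extract_features(scene.plot_id, scene.fis, scene.height_m, stack,
                            scene.thermal, ms_mask, thermal_mask)


def field_features(config: SimConfig, height_m: int = 20,
                   thresholds: ThresholdSet | None = None,
                   calibration: str = "unified_factor",
                   scenes: list[PlotScene] | None = None) -> pd.DataFrame:
    """Feature table for the whole field at one flight height."""
    if scenes is None:
        scenes, _ = scene_sim.generate_field(config)
    records = []
    for scene in scenes:
        if height_m != 20:
            scene = scene_sim.degrade_to_height(scene, height_m, config)
        records.append(process_plot(scene, config, thresholds, calibration))
    n_invalid = sum(not r.valid for r in records)
    if n_invalid:
        logger.warning("%d plots produced invalid feature records", n_invalid)
    return features_table(records)


def run_classification(config: SimConfig, height_m: int = 20, seed: int = 0,
                       thresholds: ThresholdSet | None = None,
                       features: pd.DataFrame | None = None) -> dict:
    """Full pipeline through training and test-set evaluation."""
    if features is None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
        features = field_features(config, height_m, thresholds)
    return fnn_classifier.train_fis_classifier(features, seed=seed)
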