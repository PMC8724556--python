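"""End-to-end convenience: simulate/load → segment → features → classify → curves.

Glues the stage modules together the way the assay runs them: one texture
model per plate, segmentation of every (well, day) projection, the
25-feature panel per ROI, live/dead classification with goodness, optional
vital-dye calls from the fluorescence channel, and well-level aggregation
into response curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_PANEL, FeatureConfig, background_median, feature_vector
from .errors import DegenerateROIError
from .segmentation import (
    SegmentationParams,
    SegmentationResult,
    TextureModel,
    segment_organoids,
    train_texture_model,
)
from .simulate import SimulatedPlate, make_texture_annotations
from .viability import ViabilityClassifier
from .vitaldye import VDParams, vd_calls_for_image


def texture_model_from_plate(
    plate: SimulatedPlate,
    params: SegmentationParams | None = None,
    seed: int = 0,
    n_images: int = 3,
) -> TextureModel:
    """Train the texture model from annotation strokes on a few plate images.

    Images are chosen to span phenotypes: the first negative-control well at
    day 0 and the first positive-control well at the last two days (so both
    smooth live and granular dead organoid textures are annotated).
    """
    params = params or SegmentationParams()
    layout = plate.layout.table
    neg = layout[layout["control"] == "negative"]["well"].tolist()
    pos = layout[layout["control"] == "positive"]["well"].tolist()
    days = sorted({d for (_, d) in plate.images})
    keys: list[tuple[str, float]] = []
    if neg:
        keys.append((neg[0], days[0]))
    if pos:
        keys.append((pos[0], days[-1]))
        if len(days) > 1:
            keys.append((pos[0], days[-2]))
    while len(keys) < n_images and len(keys) < len(plate.images):
        for key in plate.images:
            if key not in keys:
                keys.append(key)
                break
    images, strokes = make_texture_annotations(
        plate, keys[:n_images], brush_px=params.annotation_brush_px, seed=seed
    )
    return train_texture_model(images, strokes, params, seed=seed)


@dataclass
class PlateAnalysis:
    """Per-ROI calls and features for a whole plate."""

    calls: pd.DataFrame  # well, day, roi_id, label, goodness, vd_label, centroids
    features: pd.DataFrame
    segmentations: dict = field(default_factory=dict)  # (well, day) -> SegmentationResult


def analyze_plate(
    plate: SimulatedPlate,
    texture_model: TextureModel,
    classifier: ViabilityClassifier,
    seg_params: SegmentationParams | None = None,
    feature_config: FeatureConfig | None = None,
    vd_params: VDParams | None = None,
) -> PlateAnalysis:
    """Run segmentation, feature extraction and classification on every image."""
    seg_params = seg_params or SegmentationParams()
    feature_config = feature_config or FeatureConfig()
    call_rows = []
    feat_rows = []
    segmentations = {}
    for (well, day), image in sorted(plate.images.items()):
        result: SegmentationResult = segment_organoids(image, texture_model, seg_params)
        segmentations[(well, day)] = result
        bg = background_median(image, result.label_map > 0)
        vd_by_roi = {}
        if vd_params is not None:
            fluor = plate.fluorescence[(well, day)]
            for call in vd_calls_for_image(fluor, result.rois, vd_params, result.label_map):
                vd_by_roi[call.roi_id] = call.label
        for roi in result.rois:
            try:
                vals = feature_vector(image, roi, feature_config, bg)
            except DegenerateROIError:
                continue
            goodness = float(classifier.decision_function(vals)[0])
            label = "live" if goodness > 0 else "dead"
            call_rows.append(
                {
                    "well": well,
                    "day": day,
                    "roi_id": roi.roi_id,
                    "label": label,
                    "goodness": goodness,
                    "vd_label": vd_by_roi.get(roi.roi_id),
                    "centroid_y_um": roi.centroid_um[0],
                    "centroid_x_um": roi.centroid_um[1],
                    "area_um2": roi.area_um2,
                }
            )
            feat_rows.append({"well": well, "day": day, "roi_id": roi.roi_id, **vals})
    calls = pd.DataFrame(
        call_rows,
        columns=["well", "day", "roi_id", "label", "goodness", "vd_label",
                 "centroid_y_um", "centroid_x_um", "area_um2"],
    )
    features = pd.DataFrame(feat_rows, columns=["well", "day", "roi_id", *FEATURE_PANEL])
    return PlateAnalysis(calls=calls, features=features, segmentations=segmentations)


def live_fraction_by_well(calls: pd.DataFrame, label_column: str = "label") -> pd.DataFrame:
    """Live fraction per (well, day) from per-ROI calls."""
    rows = []
    for (well, day), grp in calls.groupby(["well", "day"], sort=True):
        labeled = grp[grp[label_column].notna()]
        n = len(labeled)
        rows.append(
            {
                "well": well,
                "day": day,
                "n": n,
                "live_fraction": float((labeled[label_column] == "live").mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
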