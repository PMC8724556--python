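"""Shared fixtures: a small two-condition simulated plate and trained models.

Session-scoped so the (relatively) expensive simulation, texture training
and classifier training run once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from organoidml.features import background_median
from organoidml.pipeline import texture_model_from_plate
from organoidml.segmentation import OrganoidROI
from organoidml.simulate import (
    SimConfig,
    make_training_fixture,
    make_wells,
    patch_features,
    simulate_plate,
)
from organoidml.viability import ViabilityClassifier


@pytest.fixture(scope="session")
def two_condition_config() -> SimConfig:
    wells = make_wells(
        [("media", 0.0, "negative"), ("staurosporine", 5.0, "positive")], n_replicates=1
    )
    return SimConfig(wells=wells, seed=1)


@pytest.fixture(scope="session")
def plate(two_condition_config):
    return simulate_plate(two_condition_config)


@pytest.fixture(scope="session")
def texture_model(plate):
    return texture_model_from_plate(plate, seed=0)


@pytest.fixture(scope="session")
def training_features(two_condition_config, texture_model):
    patches = make_training_fixture(two_condition_config, n_live=60, n_dead=60, seed=5)
    return patch_features(patches, texture_model=texture_model)


@pytest.fixture(scope="session")
def classifier(training_features):
    from organoidml.features import FEATURE_PANEL

    model = ViabilityClassifier(random_state=17)
    model.fit(
        training_features[list(FEATURE_PANEL)], training_features["label"].to_numpy()
    )
    return model


def roi_from_mask(mask: np.ndarray, pixel_size_um: float = 1.0, roi_id: int = 1,
                  well: str = "W1", day: float = 0.0) -> OrganoidROI:
    """Build an OrganoidROI from a full-image boolean mask."""
    rr, cc = np.nonzero(mask)
    bbox = (rr.min(), cc.min(), rr.max() + 1, cc.max() + 1)
    return OrganoidROI(
        roi_id=roi_id,
        well=well,
        field=0,
        timepoint_day=day,
        bbox=bbox,
        mask=mask[bbox[0] : bbox[2], bbox[1] : bbox[3]],
        centroid_um=(rr.mean() * pixel_size_um, cc.mean() * pixel_size_um),
        area_um2=float(mask.sum() * pixel_size_um**2),
        touches_border=False,
        pixel_size_um=pixel_size_um,
    )


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius
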