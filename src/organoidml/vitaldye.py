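"""DRAQ7 vital-dye dead calling per organoid ROI.

A membrane-compromised (dead/dying) organoid takes up the far-red DNA dye
DRAQ7 in its nuclei.  An organoid is called dead when its ROI contains at
least ``min_count`` connected DRAQ7-positive areas each at least the area
of a nucleus (``min_positive_area_um2``); otherwise live.  The positive
threshold is either absolute or robustly estimated from the fluorescence
background (median + k*MAD outside all ROIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ParameterError, RegistrationError
from .imaging import Image2D
from .segmentation import OrganoidROI

LIVE = "live"
DEAD = "dead"


@dataclass
class VDParams:
    """Dead-call rule parameters.

    min_positive_area_um2 defaults to 65 um^2 (~a 9 um nucleus) — an
    analysis default, since the nucleus reference area is configurable per
    cell type.  threshold_mode 'mad' computes background median + mad_k*MAD
    of out-of-ROI fluorescence; 'absolute' uses positive_threshold as-is.
    """

    min_positive_area_um2: float = 65.0
    min_count: int = 1
    threshold_mode: str = "mad"  # or "absolute"
    positive_threshold: float | None = None
    mad_k: float = 5.0

    def __post_init__(self) -> None:
        if self.min_positive_area_um2 <= 0:
            raise ParameterError("min_positive_area_um2 must be > 0")
        if self.min_count < 1:
            raise ParameterError("min_count must be >= 1")
        if self.threshold_mode not in ("mad", "absolute"):
            raise ParameterError("threshold_mode must be 'mad' or 'absolute'")
        if self.threshold_mode == "absolute":
            if self.positive_threshold is None or self.positive_threshold <= 0:
                raise ParameterError("absolute mode requires positive_threshold > 0")


@dataclass
class VDCall:
    """Vital-dye verdict for one ROI."""

    roi_id: int
    label: str
    positive_areas_um2: list[float] = field(default_factory=list)

    @property
    def n_positive_areas(self) -> int:
        return len(self.positive_areas_um2)

    @property
    def max_area_um2(self) -> float:
        return max(self.positive_areas_um2, default=0.0)


def compute_threshold(
    fluor: Image2D, params: VDParams, foreground_mask: np.ndarray | None = None
) -> float:
    """Positive-intensity cut for one fluorescence image."""
    if params.threshold_mode == "absolute":
        return float(params.positive_threshold)
    bg = fluor.pixels if foreground_mask is None else fluor.pixels[~foreground_mask]
    if bg.size == 0:
        bg = fluor.pixels.ravel()
    med = np.median(bg)
    mad = np.median(np.abs(bg - med))
    return float(med + params.mad_k * mad)


def detect_positive_areas(
    fluor: Image2D,
    roi: OrganoidROI,
    params: VDParams | None = None,
    threshold: float | None = None,
) -> list[float]:
    """Areas (um^2) of connected DRAQ7+ components inside the ROI mask.

    The fluorescence image must be co-registered with the brightfield
    projection (same shape and pixel size).  Components are 8-connected;
    only the part intersecting the ROI counts.
    """
    params = params or VDParams()
    if roi.bbox[2] > fluor.shape[0] or roi.bbox[3] > fluor.shape[1]:
        raise RegistrationError(
            f"ROI {roi.roi_id} bbox {roi.bbox} exceeds fluorescence image {fluor.shape}"
        )
    if abs(fluor.pixel_size_um - roi.pixel_size_um) > 1e-9:
        raise RegistrationError("fluorescence pixel size differs from ROI calibration")
    if threshold is None:
        threshold = compute_threshold(fluor, params)
    rmin, cmin, rmax, cmax = roi.bbox
    crop = fluor.pixels[rmin:rmax, cmin:cmax]
    positive = (crop >= threshold) & roi.mask
    labels, n = ndi.label(positive, structure=np.ones((3, 3), bool))
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]
    px2 = fluor.pixel_size_um**2
    return sorted(float(c * px2) for c in counts)


def vd_call(areas: list[float], params: VDParams | None = None, roi_id: int = 0) -> VDCall:
    """Dead iff >= min_count areas reach the nucleus-area floor (boundary inclusive)."""
    params = params or VDParams()
    qualifying = sum(1 for a in areas if a >= params.min_positive_area_um2)
    label = DEAD if qualifying >= params.min_count else LIVE
    return VDCall(roi_id=roi_id, label=label, positive_areas_um2=list(areas))


def vd_calls_for_image(
    fluor: Image2D,
    rois: list[OrganoidROI],
    params: VDParams | None = None,
    label_map: np.ndarray | None = None,
) -> list[VDCall]:
    """Vital-dye calls for all ROIs of one image (shared background threshold)."""
    params = params or VDParams()
    fg = label_map > 0 if label_map is not None else None
    threshold = compute_threshold(fluor, params, fg)
    return [
        vd_call(detect_positive_areas(fluor, roi, params, threshold), params, roi.roi_id)
        for roi in rois
    ]


def calls_to_table(calls: list[VDCall], well: str | None = None, day=None) -> pd.DataFrame:
    rows = [
        {
            "roi_id": c.roi_id,
            "well": well,
            "day": day,
            "vd_label": c.label,
            "n_positive_areas": c.n_positive_areas,
            "max_area_um2": c.max_area_um2,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["roi_id", "well", "day", "vd_label", "n_positive_areas", "max_area_um2"]
    )
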