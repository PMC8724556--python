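"""Texture-based organoid segmentation.

A supervised per-pixel texture classifier separates organoid from background
in the brightfield maximum projection.  The class-score image is smoothed at
the region scale, thresholded at 0.5, hole-filled, and touching organoids are
split by a distance-transform/watershed step.  Components touching the image
border and components outside the area gate are discarded; the survivors are
the per-organoid regions of interest (ROIs) that all downstream feature
extraction and classification operate on.

The per-pixel feature bank deliberately reuses the same Gaussian-derivative
operators as the texture (SER) features: smoothed intensity, gradient
magnitude, both Hessian eigenvalues, and the local intensity standard
deviation in a ``(2*scale+1)**2`` window, all at the texture scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.linear_model import LogisticRegression

from ._filters import gaussian_derivative
from .errors import ParameterError, TrainingError, ValidationError
from .imaging import Image2D

PIXEL_FEATURE_NAMES = (
    "smoothed_intensity",
    "gradient_magnitude",
    "hessian_eig_max",
    "hessian_eig_min",
    "local_sd",
)

ORGANOID = "organoid"
BACKGROUND = "background"


@dataclass
class PixelFeatureMap:
    """Per-pixel feature planes for texture classification."""

    planes: np.ndarray  # (n_features, H, W)
    names: tuple[str, ...]
    texture_scale_px: float

    def as_matrix(self) -> np.ndarray:
        """Flatten to an (n_pixels, n_features) design matrix."""
        return self.planes.reshape(self.planes.shape[0], -1).T


def compute_pixel_features(image: Image2D, texture_scale_px: float = 2.0) -> PixelFeatureMap:
    """Compute the five-plane texture feature bank at ``texture_scale_px``.

    Uses reflection padding at the borders.  Derivative planes are exactly
    zero on constant images and invariant to adding a constant offset.
    """
    if texture_scale_px <= 0:
        raise ParameterError("texture_scale_px must be > 0")
    I = image.pixels
    s = float(texture_scale_px)
    g = gaussian_derivative(I, s, (0, 0))
    gy = gaussian_derivative(I, s, (1, 0))
    gx = gaussian_derivative(I, s, (0, 1))
    hyy = gaussian_derivative(I, s, (2, 0))
    hxx = gaussian_derivative(I, s, (0, 2))
    hxy = gaussian_derivative(I, s, (1, 1))
    grad = np.hypot(gx, gy)
    half_tr = (hxx + hyy) / 2.0
    disc = np.sqrt(((hxx - hyy) / 2.0) ** 2 + hxy**2)
    lam_max = half_tr + disc
    lam_min = half_tr - disc
    w = 2 * int(round(s)) + 1
    mean = ndi.uniform_filter(I, w, mode="reflect")
    mean_sq = ndi.uniform_filter(I * I, w, mode="reflect")
    local_sd = np.sqrt(np.clip(mean_sq - mean**2, 0.0, None))
    planes = np.stack([g, grad, lam_max, lam_min, local_sd])
    if not np.all(np.isfinite(planes)):
        raise ValidationError("pixel feature planes contain non-finite values")
    return PixelFeatureMap(planes=planes, names=PIXEL_FEATURE_NAMES, texture_scale_px=s)


@dataclass
class SegmentationParams:
    """Tunables of the segmentation stage.

    Defaults follow the assay protocol: 15 px annotation brush, texture scale
    2 px, region scale 6 px.  The area gate (700–200,000 μm², roughly 30–500
    μm equivalent diameter) excludes small debris and unsplit clusters.
    """

    texture_scale_px: float = 2.0
    region_scale_px: float = 6.0
    annotation_brush_px: float = 15.0
    min_split_distance_px: float = 20.0
    area_min_um2: float = 700.0
    area_max_um2: float = 200_000.0
    border_margin_px: int = 0

    def __post_init__(self) -> None:
        if min(self.texture_scale_px, self.region_scale_px,
               self.annotation_brush_px, self.min_split_distance_px) <= 0:
            raise ParameterError("scales and distances must be > 0")
        if not self.area_min_um2 < self.area_max_um2:
            raise ParameterError("area_min_um2 must be < area_max_um2")
        if self.border_margin_px < 0:
            raise ParameterError("border_margin_px must be >= 0")


@dataclass
class Stroke:
    """One annotation stroke: pixel coordinates on one image, with a class tag."""

    image_index: int
    rows: np.ndarray
    cols: np.ndarray
    label: str  # ORGANOID or BACKGROUND


@dataclass
class TextureModel:
    """Linear two-class (organoid vs background) pixel classifier."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    mean: np.ndarray
    sd: np.ndarray
    texture_scale_px: float
    region_scale_px: float
    n_annotated: int = 0
    degenerate: bool = False

    def score(self, image: Image2D) -> np.ndarray:
        """Per-pixel organoid probability in [0, 1] (logistic of the linear score)."""
        fmap = compute_pixel_features(image, self.texture_scale_px)
        X = (fmap.as_matrix() - self.mean) / self.sd
        logit = X @ self.weights + self.bias
        prob = 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))
        return prob.reshape(image.shape)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "standardize": {"mean": [float(m) for m in self.mean],
                            "sd": [float(s) for s in self.sd]},
            "texture_scale_px": float(self.texture_scale_px),
            "region_scale_px": float(self.region_scale_px),
            "n_annotated": int(self.n_annotated),
            "degenerate": bool(self.degenerate),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TextureModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=np.asarray(d["weights"], dtype=np.float64),
            bias=float(d["bias"]),
            mean=np.asarray(d["standardize"]["mean"], dtype=np.float64),
            sd=np.asarray(d["standardize"]["sd"], dtype=np.float64),
            texture_scale_px=float(d["texture_scale_px"]),
            region_scale_px=float(d["region_scale_px"]),
            n_annotated=int(d.get("n_annotated", 0)),
            degenerate=bool(d.get("degenerate", False)),
        )


def train_texture_model(
    images: list[Image2D],
    annotations: list[Stroke],
    params: SegmentationParams | None = None,
    seed: int = 0,
) -> TextureModel:
    """Fit the linear pixel classifier from annotated strokes.

    Features are standardized over the annotated pixels; the classifier is a
    logistic regression so the score image is a probability thresholdable at
    0.5.  Deterministic given the seed.
    """
    import warnings

    params = params or SegmentationParams()
    labels_present = {s.label for s in annotations}
    if not {ORGANOID, BACKGROUND} <= labels_present:
        raise TrainingError(
            f"annotations must include both classes, got {sorted(labels_present)}"
        )
    fmaps = [compute_pixel_features(im, params.texture_scale_px) for im in images]
    rows_X, rows_y = [], []
    for stroke in annotations:
        fmap = fmaps[stroke.image_index]
        H, W = images[stroke.image_index].shape
        r = np.asarray(stroke.rows, dtype=int)
        c = np.asarray(stroke.cols, dtype=int)
        if r.size == 0:
            continue
        if r.min() < 0 or r.max() >= H or c.min() < 0 or c.max() >= W:
            raise ValidationError("annotation stroke outside image bounds")
        rows_X.append(fmap.planes[:, r, c].T)
        rows_y.append(np.full(r.size, 1 if stroke.label == ORGANOID else 0))
    X = np.concatenate(rows_X)
    y = np.concatenate(rows_y)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = bool(np.all(sd == 0))
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mean) / sd
    if degenerate:
        warnings.warn("all annotated pixels have identical features; "
                      "returning a degenerate texture model")
        weights = np.zeros(X.shape[1])
        bias = float(np.log((y.mean() + 1e-9) / (1 - y.mean() + 1e-9)))
    else:
        clf = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
        clf.fit(Xs, y)
        weights = clf.coef_[0]
        bias = float(clf.intercept_[0])
    return TextureModel(
        feature_names=PIXEL_FEATURE_NAMES,
        weights=np.asarray(weights, dtype=np.float64),
        bias=bias,
        mean=mean,
        sd=sd,
        texture_scale_px=params.texture_scale_px,
        region_scale_px=params.region_scale_px,
        n_annotated=int(y.size),
        degenerate=degenerate,
    )


@dataclass
class OrganoidROI:
    """One segmented organoid: label-map value, mask (within bbox), calibration."""

    roi_id: int
    well: str | None
    field: int
    timepoint_day: float | None
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax) half-open
    mask: np.ndarray  # bool, shape of bbox
    centroid_um: tuple[float, float]  # (y_um, x_um) = (row, col) * pixel_size
    area_um2: float
    touches_border: bool
    pixel_size_um: float = 1.0

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid_px(self) -> tuple[float, float]:
        return (self.centroid_um[0] / self.pixel_size_um,
                self.centroid_um[1] / self.pixel_size_um)


@dataclass
class SegmentationResult:
    """ROIs plus the label map and per-stage bookkeeping counts."""

    rois: list[OrganoidROI]
    label_map: np.ndarray  # int32, 0 = background, k = ROI with roi_id k
    counts: dict = field(default_factory=dict)


def _touches_border(rmin, cmin, rmax, cmax, shape, margin) -> bool:
    H, W = shape
    return rmin <= margin or cmin <= margin or rmax >= H - margin or cmax >= W - margin


def segment_organoids(
    image: Image2D,
    model: TextureModel,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Segment individual organoids from a brightfield maximum projection.

    Fixed stage order: per-pixel class score → Gaussian smoothing of the
    score at the region scale → threshold at 0.5 → fill enclosed holes →
    split touching organoids by seeded watershed on the interior distance
    transform → drop border-touching components → drop components outside
    the area gate.  Deterministic; an image with no foreground yields an
    empty ROI list.
    """
    params = params or SegmentationParams()
    score = model.score(image)
    smoothed = ndi.gaussian_filter(score, params.region_scale_px, mode="reflect")
    fg = smoothed > 0.5
    counts = {"foreground_px": int(fg.sum())}
    # holes are 4-connected background enclosed by foreground
    filled = ndi.binary_fill_holes(fg)
    eight = np.ones((3, 3), bool)
    comp_labels, n_comp = ndi.label(filled, structure=eight)
    counts["foreground_components"] = int(n_comp)

    label_map = np.zeros(image.shape, dtype=np.int32)
    if n_comp == 0:
        counts.update(after_split=0, border_removed=0, area_removed=0, final=0)
        return SegmentationResult(rois=[], label_map=label_map, counts=counts)

    distance = ndi.distance_transform_edt(filled)
    # light smoothing of the distance map suppresses spurious maxima from
    # ragged (granular) boundaries before seeding
    distance_s = ndi.gaussian_filter(distance, 2.0)
    peaks = peak_local_max(
        distance_s,
        min_distance=max(1, int(round(params.min_split_distance_px))),
        labels=comp_labels,
        exclude_border=False,
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    # guarantee every component owns at least one seed
    seeded = set(np.unique(comp_labels[markers > 0]))
    next_id = len(peaks) + 1
    for comp in range(1, n_comp + 1):
        if comp not in seeded:
            inside = comp_labels == comp
            flat = np.argmax(np.where(inside, distance_s, -1))
            markers.flat[flat] = next_id
            next_id += 1
    split = watershed(-distance_s, markers, mask=filled, connectivity=2)
    counts["after_split"] = int(split.max())

    px2 = image.pixel_size_um**2
    border_removed = area_removed = 0
    rois: list[OrganoidROI] = []
    roi_id = 0
    objects = ndi.find_objects(split)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = split[sl] == k
        rmin, cmin = sl[0].start, sl[1].start
        rmax, cmax = sl[0].stop - 1, sl[1].stop - 1
        if _touches_border(rmin, cmin, rmax, cmax, image.shape, params.border_margin_px):
            border_removed += 1
            continue
        area = mask.sum() * px2
        if not params.area_min_um2 <= area <= params.area_max_um2:
            area_removed += 1
            continue
        rr, cc = np.nonzero(mask)
        cy = (rr.mean() + rmin) * image.pixel_size_um
        cx = (cc.mean() + cmin) * image.pixel_size_um
        roi_id += 1
        label_map[sl][mask] = roi_id
        rois.append(
            OrganoidROI(
                roi_id=roi_id,
                well=image.well,
                field=image.field,
                timepoint_day=image.timepoint_day,
                bbox=(rmin, cmin, rmax + 1, cmax + 1),
                mask=mask,
                centroid_um=(cy, cx),
                area_um2=float(area),
                touches_border=False,
                pixel_size_um=image.pixel_size_um,
            )
        )
    counts["border_removed"] = border_removed
    counts["area_removed"] = area_removed
    counts["final"] = len(rois)
    return SegmentationResult(rois=rois, label_map=label_map, counts=counts)


def rois_to_table(rois: list[OrganoidROI], plate: str = "") -> "pd.DataFrame":
    """Export ROIs as the standard table (centroid x = column, y = row, in μm)."""
    import pandas as pd

    rows = [
        {
            "plate": plate,
            "well": r.well,
            "field": r.field,
            "day": r.timepoint_day,
            "roi_id": r.roi_id,
            "centroid_x_um": r.centroid_um[1],
            "centroid_y_um": r.centroid_um[0],
            "area_um2": r.area_um2,
            "touches_border": r.touches_border,
        }
        for r in rois
    ]
    return pd.DataFrame(
        rows,
        columns=["plate", "well", "field", "day", "roi_id", "centroid_x_um",
                 "centroid_y_um", "area_um2", "touches_border"],
    )
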