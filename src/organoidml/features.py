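"""The 25-feature SER + STAR panel computed per organoid ROI.

Eight SER (Spot–Edge–Ridge family) texture features summarize Gaussian
derivative responses inside the ROI; seventeen STAR features summarize
morphology — Symmetry, Threshold compactness, Axial and Radial properties —
of the region's shape and contrast distribution.

All intensity-derived quantities work on the *contrast image*
``J = clip(background_median - I, 0)`` (brightfield organoids are darker
than the background; the polarity is configurable).  SER features are
normalized by the squared mean ROI intensity of the original image, and the
weight image of the STAR features is J itself, which makes the whole panel
invariant under a global intensity rescaling ``I -> c*I``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter as _sk_perimeter

from ._filters import gaussian_derivative
from .errors import DegenerateROIError, ParameterError
from .imaging import Image2D
from .segmentation import OrganoidROI

FEATURE_PANEL: tuple[str, ...] = (
    "SER Spot",
    "SER Hole",
    "SER Edge",
    "SER Ridge",
    "SER Valley",
    "SER Saddle",
    "SER Bright",
    "SER Dark",
    "Area",
    "Roundness",
    "Width",
    "Length",
    "Ratio Width to Length",
    "Axial Small Length",
    "Axial Length Ratio",
    "Radial Mean",
    "Radial Relative Deviation",
    "Profile 1/2",
    "Profile 2/2",
    "Symmetry 2",
    "Symmetry 3",
    "Symmetry 4",
    "Symmetry 5",
    "Threshold Compactness 50%",
    "Threshold Compactness 60%",
)

SER_NAMES = FEATURE_PANEL[:8]
STAR_NAMES = FEATURE_PANEL[8:]

PROVENANCE_COLUMNS = ("well", "field", "day", "roi_id")


@dataclass
class FeatureConfig:
    """Parameters of the feature panel.

    ser_scale_px is the sigma of the Gaussian derivatives (default 2 px,
    matching the segmentation texture scale); symmetry uses 36 angular bins
    (10 degrees) and harmonics 2–5; compactness thresholds at the 50th and
    60th within-ROI contrast percentiles.
    """

    ser_scale_px: float = 2.0
    n_angular_bins: int = 36
    harmonics: tuple[int, ...] = (2, 3, 4, 5)
    compactness_percentiles: tuple[float, ...] = (50.0, 60.0)
    polarity: str = "dark_objects"  # or "bright_objects"

    def __post_init__(self) -> None:
        if self.ser_scale_px <= 0:
            raise ParameterError("ser_scale_px must be > 0")
        if self.n_angular_bins < 8:
            raise ParameterError("n_angular_bins must be >= 8")
        if self.polarity not in ("dark_objects", "bright_objects"):
            raise ParameterError("polarity must be dark_objects or bright_objects")


def background_median(image: Image2D, foreground_mask: np.ndarray | None) -> float:
    """Median intensity of non-foreground pixels (whole image if no mask)."""
    if foreground_mask is None:
        return float(np.median(image.pixels))
    bg = image.pixels[~foreground_mask]
    if bg.size == 0:
        return float(np.median(image.pixels))
    return float(np.median(bg))


def contrast_image(pixels: np.ndarray, bg_median: float, polarity: str) -> np.ndarray:
    """Non-negative contrast relative to the background level."""
    if polarity == "dark_objects":
        return np.clip(bg_median - pixels, 0.0, None)
    return np.clip(pixels - bg_median, 0.0, None)


def _filter_radius(sigma: float) -> int:
    # matches scipy.ndimage.gaussian_filter truncate=4.0
    return int(4.0 * sigma + 0.5)


def _crop_with_margin(image: Image2D, roi: OrganoidROI, margin: int):
    """Expand the ROI bbox by ``margin`` (clipped to the image).

    Filter outputs at ROI pixels computed on this crop (reflect padding)
    are identical to filtering the full image, because every input pixel
    within the kernel radius of a ROI pixel is inside the crop, and crop
    edges clipped at the image boundary reflect the same content.
    """
    rmin, cmin, rmax, cmax = roi.bbox
    H, W = image.shape
    r0, c0 = max(0, rmin - margin), max(0, cmin - margin)
    r1, c1 = min(H, rmax + margin), min(W, cmax + margin)
    crop = image.pixels[r0:r1, c0:c1]
    rr, cc = np.nonzero(roi.mask)
    return crop, rr + (rmin - r0), cc + (cmin - c0)


def _check_roi(roi: OrganoidROI) -> None:
    if roi.n_pixels < 9:
        raise DegenerateROIError(
            f"ROI {roi.roi_id} has {roi.n_pixels} px (< 9); features undefined"
        )


def ser_features(
    image: Image2D,
    roi: OrganoidROI,
    config: FeatureConfig | None = None,
    bg_median: float | None = None,
) -> dict[str, float]:
    """Eight SER texture features of one ROI.

    Per-pixel operators from the gradient (Jx, Jy) and Hessian eigenvalues
    (l1 >= l2) of the contrast image J at sigma = ser_scale_px:

    - edge   = sqrt(Jx^2 + Jy^2)
    - spot   = sqrt(max(-l1,0) * max(-l2,0))
    - hole   = sqrt(max(l1,0) * max(l2,0))
    - saddle = sqrt(max(l1,0) * max(-l2,0))
    - ridge  = max(-l2,0) * max(1 - |l1|/|l2|, 0)   (0 unless l2 < 0)
    - valley = l1 * max(1 - |l2|/l1, 0)             (0 unless l1 > 0)
    - bright = max(J - mean_roi(J), 0); dark = max(mean_roi(J) - J, 0)

    Each feature is the ROI mean of the squared operator divided by the
    squared mean ROI intensity of the original image.
    """
    config = config or FeatureConfig()
    _check_roi(roi)
    if bg_median is None:
        bg_median = background_median(image, None)
    sigma = config.ser_scale_px
    margin = _filter_radius(sigma)
    crop, rr, cc = _crop_with_margin(image, roi, margin)
    J = contrast_image(crop, bg_median, config.polarity)

    gy = gaussian_derivative(J, sigma, (1, 0))
    gx = gaussian_derivative(J, sigma, (0, 1))
    hyy = gaussian_derivative(J, sigma, (2, 0))
    hxx = gaussian_derivative(J, sigma, (0, 2))
    hxy = gaussian_derivative(J, sigma, (1, 1))

    jx, jy = gx[rr, cc], gy[rr, cc]
    a, b, c = hyy[rr, cc], hxy[rr, cc], hxx[rr, cc]
    half_tr = (a + c) / 2.0
    disc = np.sqrt(((a - c) / 2.0) ** 2 + b**2)
    l1 = half_tr + disc  # l1 >= l2
    l2 = half_tr - disc

    edge_sq = jx**2 + jy**2
    spot_sq = np.maximum(-l1, 0.0) * np.maximum(-l2, 0.0)
    hole_sq = np.maximum(l1, 0.0) * np.maximum(l2, 0.0)
    saddle_sq = np.maximum(l1, 0.0) * np.maximum(-l2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ridge = np.where(
            l2 < 0,
            np.maximum(-l2, 0.0) * np.maximum(1.0 - np.abs(l1) / np.abs(l2), 0.0),
            0.0,
        )
        valley = np.where(
            l1 > 0,
            l1 * np.maximum(1.0 - np.abs(l2) / np.where(l1 > 0, l1, 1.0), 0.0),
            0.0,
        )
    jroi = J[rr, cc]
    jbar = jroi.mean()
    bright = np.maximum(jroi - jbar, 0.0)
    dark = np.maximum(jbar - jroi, 0.0)

    denom = float(crop[rr, cc].mean()) ** 2
    ops_sq = {
        "SER Spot": spot_sq,
        "SER Hole": hole_sq,
        "SER Edge": edge_sq,
        "SER Ridge": ridge**2,
        "SER Valley": valley**2,
        "SER Saddle": saddle_sq,
        "SER Bright": bright**2,
        "SER Dark": dark**2,
    }
    if denom == 0.0:
        return {name: 0.0 for name in ops_sq}
    return {name: float(v.mean() / denom) for name, v in ops_sq.items()}


def _mask_perimeter(mask: np.ndarray) -> float:
    """Weighted boundary-pixel perimeter estimate (Vossepoel–Smeulders-style
    corrections), so the compactness 4*pi*A/P^2 of a rasterized disk is ~1."""
    return float(_sk_perimeter(mask, 4))


def _eig_2x2(srr: float, src: float, scc: float) -> tuple[float, float]:
    half_tr = (srr + scc) / 2.0
    disc = np.sqrt(((srr - scc) / 2.0) ** 2 + src**2)
    return half_tr + disc, max(half_tr - disc, 0.0)


def star_features(
    image: Image2D,
    roi: OrganoidROI,
    config: FeatureConfig | None = None,
    bg_median: float | None = None,
) -> tuple[dict[str, float], dict[str, bool]]:
    """Seventeen STAR morphology features of one ROI; returns (values, flags).

    Shape axes come from the second moments of the mask (Length/Width =
    4*sqrt(eigenvalue) in px, converted to um); the intensity-weighted
    counterparts use the contrast image J as weights.  Profile zones split
    the ROI at half of the normalized interior depth; Symmetry k is one
    minus the relative magnitude of the k-th circular harmonic of the
    angular mass distribution of J about the weighted centroid; Threshold
    Compactness X% is the compactness of the sub-region above the X-th
    within-ROI percentile of J.
    """
    config = config or FeatureConfig()
    _check_roi(roi)
    if bg_median is None:
        bg_median = background_median(image, None)
    px = roi.pixel_size_um
    rmin, cmin, rmax, cmax = roi.bbox
    crop = image.pixels[rmin:rmax, cmin:cmax]
    mask = roi.mask
    rr, cc = np.nonzero(mask)
    n = rr.size
    J = contrast_image(crop, bg_median, config.polarity)
    w = J[rr, cc]
    flags: dict[str, bool] = {}

    area = n * px**2

    # mask second-moment ellipse
    r0, c0 = rr.mean(), cc.mean()
    dr, dc = rr - r0, cc - c0
    srr, scc, src = (dr @ dr) / n, (dc @ dc) / n, (dr @ dc) / n
    lam_max, lam_min = _eig_2x2(srr, src, scc)
    length = 4.0 * np.sqrt(lam_max) * px
    width = 4.0 * np.sqrt(lam_min) * px
    ratio_wl = float(np.sqrt(lam_min / lam_max)) if lam_max > 0 else 1.0

    perim = _mask_perimeter(mask) * px
    roundness = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0

    # intensity-weighted moments (uniform fallback for zero total contrast)
    wsum = w.sum()
    if wsum <= 0:
        wm = np.ones(n)
        wsum_m = float(n)
        flags["zero_contrast"] = True
    else:
        wm = w
        wsum_m = float(wsum)
    rw = (wm @ rr) / wsum_m
    cw = (wm @ cc) / wsum_m
    dwr, dwc = rr - rw, cc - cw
    swrr = (wm @ (dwr * dwr)) / wsum_m
    swcc = (wm @ (dwc * dwc)) / wsum_m
    swrc = (wm @ (dwr * dwc)) / wsum_m
    lam_w_max, lam_w_min = _eig_2x2(swrr, swrc, swcc)
    axial_small = 4.0 * np.sqrt(lam_w_min) * px
    axial_ratio = float(np.sqrt(lam_w_min / lam_w_max)) if lam_w_max > 0 else 1.0

    dist = np.hypot(dwr, dwc) * px
    radial_mean = float(dist.mean())
    radial_rel_dev = float(dist.std() / radial_mean) if radial_mean > 0 else 0.0

    # normalized interior depth: distance to border / max depth
    padded = np.pad(mask, 1)
    depth = ndi.distance_transform_edt(padded)[1:-1, 1:-1][rr, cc]
    d = depth / depth.max()
    inner = d >= 0.5
    mean_j = w.mean()
    if mean_j <= 0:
        profile1 = profile2 = 1.0
        flags["zero_contrast"] = True
    else:
        outer = ~inner
        p_out = float(w[outer].mean() / mean_j) if outer.any() else None
        p_in = float(w[inner].mean() / mean_j) if inner.any() else None
        if p_in is None:
            p_in = p_out
            flags["profile_zone2_empty"] = True
        if p_out is None:
            p_out = p_in
            flags["profile_zone1_empty"] = True
        profile1, profile2 = p_out, p_in

    # circular harmonics of the angular mass distribution
    theta = np.arctan2(rr - rw, cc - cw)
    nb = config.n_angular_bins
    bin_idx = np.clip(((theta + np.pi) / (2 * np.pi) * nb).astype(int), 0, nb - 1)
    mass = np.bincount(bin_idx, weights=wm, minlength=nb)
    centers = (np.arange(nb) + 0.5) * (2 * np.pi / nb) - np.pi
    total_mass = mass.sum()
    symmetry = {}
    for k in config.harmonics:
        hk = np.abs(np.sum(mass * np.exp(1j * k * centers)))
        symmetry[k] = float(1.0 - hk / total_mass) if total_mass > 0 else 1.0

    # threshold compactness
    compactness = {}
    for pct in config.compactness_percentiles:
        t = np.percentile(w, pct)  # linear-interpolated percentile
        sub = np.zeros_like(mask)
        sub[rr, cc] = w >= t
        a_sub = sub.sum() * px**2
        if a_sub == 0:
            compactness[pct] = 0.0
            flags[f"compactness_{pct:g}_empty"] = True
            continue
        p_sub = _mask_perimeter(sub) * px
        compactness[pct] = 4.0 * np.pi * a_sub / p_sub**2 if p_sub > 0 else 1.0

    values = {
        "Area": float(area),
        "Roundness": float(roundness),
        "Width": float(width),
        "Length": float(length),
        "Ratio Width to Length": ratio_wl,
        "Axial Small Length": float(axial_small),
        "Axial Length Ratio": axial_ratio,
        "Radial Mean": radial_mean,
        "Radial Relative Deviation": radial_rel_dev,
        "Profile 1/2": profile1,
        "Profile 2/2": profile2,
        "Symmetry 2": symmetry[2],
        "Symmetry 3": symmetry[3],
        "Symmetry 4": symmetry[4],
        "Symmetry 5": symmetry[5],
        "Threshold Compactness 50%": compactness[50.0],
        "Threshold Compactness 60%": compactness[60.0],
    }
    return values, flags


def feature_vector(
    image: Image2D,
    roi: OrganoidROI,
    config: FeatureConfig | None = None,
    bg_median: float | None = None,
) -> dict[str, float]:
    """All 25 panel features of one ROI, in FEATURE_PANEL order."""
    config = config or FeatureConfig()
    if bg_median is None:
        bg_median = background_median(image, None)
    ser = ser_features(image, roi, config, bg_median)
    star, _ = star_features(image, roi, config, bg_median)
    merged = {**ser, **star}
    return {name: merged[name] for name in FEATURE_PANEL}


def feature_table(
    entries: Iterable[tuple[Image2D, Sequence[OrganoidROI]]],
    config: FeatureConfig | None = None,
    label_maps: Sequence[np.ndarray] | None = None,
) -> tuple[pd.DataFrame, int]:
    """One feature row per ROI across a set of images.

    ``entries`` pairs each image with its ROIs; ``label_maps`` (parallel to
    entries, optional) supply the foreground masks used to estimate the
    per-image background median — otherwise the union of ROI masks is used.
    Rows come out in deterministic (well, field, roi_id) order; degenerate
    ROIs (< 9 px) are excluded and counted.
    """
    config = config or FeatureConfig()
    entries = list(entries)
    rows = []
    n_excluded = 0
    for i, (image, rois) in enumerate(entries):
        if label_maps is not None:
            fg = label_maps[i] > 0
        else:
            fg = np.zeros(image.shape, dtype=bool)
            for roi in rois:
                rmin, cmin, rmax, cmax = roi.bbox
                fg[rmin:rmax, cmin:cmax] |= roi.mask
        bg = background_median(image, fg)
        for roi in rois:
            try:
                vals = feature_vector(image, roi, config, bg)
            except DegenerateROIError:
                n_excluded += 1
                continue
            rows.append(
                {
                    "well": roi.well,
                    "field": roi.field,
                    "day": roi.timepoint_day,
                    "roi_id": roi.roi_id,
                    **vals,
                }
            )
    columns = list(PROVENANCE_COLUMNS) + list(FEATURE_PANEL)
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values(["well", "field", "roi_id"], kind="stable").reset_index(
            drop=True
        )
    return table, n_excluded
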