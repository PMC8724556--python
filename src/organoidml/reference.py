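"""Slow, direct reference implementations used for validation.

These deliberately avoid the optimized code paths of the main modules:
Gaussian-derivative responses are computed by explicit 2D kernel
convolution (no separable pass), moments and perimeter by per-pixel loops.
They exist so the fast implementations can be checked against an
independent rendering of the same definitions on small fixtures.
"""

from __future__ import annotations

import math

import numpy as np

from .features import FeatureConfig, contrast_image
from .imaging import Image2D
from .segmentation import OrganoidROI


def gaussian_kernel_1d(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian (derivative) kernel, truncated at 4 sigma.

    phi(x) is normalized to sum 1 and differentiated analytically
    (order 1: -x/s^2 * phi; order 2: (x^2/s^4 - 1/s^2) * phi).  The order-2
    kernel is DC-corrected so that every derivative kernel has exactly zero
    response to constants.
    """
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    s2 = sigma * sigma
    phi = np.exp(-0.5 * x * x / s2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -x / s2 * phi
    if order == 2:
        k2 = (x * x / (s2 * s2) - 1.0 / s2) * phi
        return k2 - k2.sum() * phi
    raise ValueError("order must be 0, 1 or 2")


def naive_gaussian_derivative(image: np.ndarray, sigma: float, order: tuple[int, int]) -> np.ndarray:
    """Direct 2D convolution with the outer-product Gaussian-derivative kernel.

    ``order = (dy, dx)``; symmetric (reflect) boundary handling.  Each output
    pixel is an explicit dot product with the full 2D kernel — no separable
    shortcut.
    """
    ky = gaussian_kernel_1d(sigma, order[0])
    kx = gaussian_kernel_1d(sigma, order[1])
    K = np.outer(ky, kx)
    R = (K.shape[0] - 1) // 2
    padded = np.pad(image.astype(np.float64), R, mode="symmetric")
    Kf = K[::-1, ::-1]  # convolution = correlation with flipped kernel
    H, W = image.shape
    out = np.empty((H, W), dtype=np.float64)
    for i in range(H):
        for j in range(W):
            out[i, j] = float(np.sum(padded[i : i + 2 * R + 1, j : j + 2 * R + 1] * Kf))
    return out


def naive_ser_features(
    image: Image2D,
    roi: OrganoidROI,
    config: FeatureConfig | None = None,
    bg_median: float | None = None,
) -> dict[str, float]:
    """SER features from first principles, looping per ROI pixel."""
    config = config or FeatureConfig()
    if bg_median is None:
        bg_median = float(np.median(image.pixels))
    J = contrast_image(image.pixels, bg_median, config.polarity)
    s = config.ser_scale_px
    jy = naive_gaussian_derivative(J, s, (1, 0))
    jx = naive_gaussian_derivative(J, s, (0, 1))
    hyy = naive_gaussian_derivative(J, s, (2, 0))
    hxx = naive_gaussian_derivative(J, s, (0, 2))
    hxy = naive_gaussian_derivative(J, s, (1, 1))

    rmin, cmin, _, _ = roi.bbox
    rr, cc = np.nonzero(roi.mask)
    rr, cc = rr + rmin, cc + cmin

    jvals = [J[r, c] for r, c in zip(rr, cc)]
    jbar = sum(jvals) / len(jvals)
    acc = {name: 0.0 for name in ("SER Spot", "SER Hole", "SER Edge", "SER Ridge",
                                  "SER Valley", "SER Saddle", "SER Bright", "SER Dark")}
    for r, c in zip(rr, cc):
        a, b, cxx = hyy[r, c], hxy[r, c], hxx[r, c]
        tr2 = (a + cxx) / 2.0
        disc = math.sqrt(((a - cxx) / 2.0) ** 2 + b * b)
        l1, l2 = tr2 + disc, tr2 - disc
        acc["SER Edge"] += jx[r, c] ** 2 + jy[r, c] ** 2
        acc["SER Spot"] += max(-l1, 0.0) * max(-l2, 0.0)
        acc["SER Hole"] += max(l1, 0.0) * max(l2, 0.0)
        acc["SER Saddle"] += max(l1, 0.0) * max(-l2, 0.0)
        ridge = max(-l2, 0.0) * max(1.0 - abs(l1) / abs(l2), 0.0) if l2 < 0 else 0.0
        valley = l1 * max(1.0 - abs(l2) / l1, 0.0) if l1 > 0 else 0.0
        acc["SER Ridge"] += ridge * ridge
        acc["SER Valley"] += valley * valley
        jv = J[r, c]
        acc["SER Bright"] += max(jv - jbar, 0.0) ** 2
        acc["SER Dark"] += max(jbar - jv, 0.0) ** 2
    n = len(rr)
    mean_int = sum(image.pixels[r, c] for r, c in zip(rr, cc)) / n
    denom = mean_int * mean_int
    if denom == 0.0:
        return {k: 0.0 for k in acc}
    return {k: v / n / denom for k, v in acc.items()}


def naive_perimeter(mask: np.ndarray) -> float:
    """Weighted boundary-pixel perimeter, coded directly from its definition.

    A border pixel is a foreground pixel with at least one 4-neighbor in the
    background (image exterior counts as background).  Each border pixel is
    scored by its border-neighborhood code 1 + 2*(#4-adjacent border px) +
    10*(#diagonal border px) and weighted: codes 5,7,15,17,25,27 -> 1;
    21,33 -> sqrt(2); 13,23 -> (1+sqrt(2))/2.
    """
    H, W = mask.shape

    def is_fg(r: int, c: int) -> bool:
        return 0 <= r < H and 0 <= c < W and bool(mask[r, c])

    def is_border(r: int, c: int) -> bool:
        if not is_fg(r, c):
            return False
        return any(not is_fg(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)))

    weights = {5: 1.0, 7: 1.0, 15: 1.0, 17: 1.0, 25: 1.0, 27: 1.0,
               21: math.sqrt(2.0), 33: math.sqrt(2.0),
               13: (1.0 + math.sqrt(2.0)) / 2.0, 23: (1.0 + math.sqrt(2.0)) / 2.0}
    total = 0.0
    for r in range(H):
        for c in range(W):
            if not is_border(r, c):
                continue
            n4 = sum(is_border(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)))
            nd = sum(is_border(r + dr, c + dc) for dr, dc in ((1, 1), (1, -1), (-1, 1), (-1, -1)))
            code = 1 + 2 * n4 + 10 * nd
            total += weights.get(code, 0.0)
    return total


def naive_star_features(
    image: Image2D,
    roi: OrganoidROI,
    config: FeatureConfig | None = None,
    bg_median: float | None = None,
) -> dict[str, float]:
    """STAR features by explicit loops — independent of the vectorized path."""
    from scipy import ndimage as ndi

    config = config or FeatureConfig()
    if bg_median is None:
        bg_median = float(np.median(image.pixels))
    px = roi.pixel_size_um
    rmin, cmin, rmax, cmax = roi.bbox
    mask = roi.mask
    J = contrast_image(image.pixels[rmin:rmax, cmin:cmax], bg_median, config.polarity)
    pts = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    n = len(pts)
    w = [float(J[r, c]) for r, c in pts]

    area = n * px * px

    r0 = sum(p[0] for p in pts) / n
    c0 = sum(p[1] for p in pts) / n
    srr = sum((p[0] - r0) ** 2 for p in pts) / n
    scc = sum((p[1] - c0) ** 2 for p in pts) / n
    src = sum((p[0] - r0) * (p[1] - c0) for p in pts) / n
    tr2 = (srr + scc) / 2.0
    disc = math.sqrt(((srr - scc) / 2.0) ** 2 + src * src)
    lam_max, lam_min = tr2 + disc, max(tr2 - disc, 0.0)
    length = 4.0 * math.sqrt(lam_max) * px
    width = 4.0 * math.sqrt(lam_min) * px
    ratio_wl = math.sqrt(lam_min / lam_max) if lam_max > 0 else 1.0

    perim = naive_perimeter(mask) * px
    roundness = 4.0 * math.pi * area / perim**2 if perim > 0 else 1.0

    wsum = sum(w)
    wm = w if wsum > 0 else [1.0] * n
    wsum_m = sum(wm)
    rw = sum(wi * p[0] for wi, p in zip(wm, pts)) / wsum_m
    cw = sum(wi * p[1] for wi, p in zip(wm, pts)) / wsum_m
    swrr = sum(wi * (p[0] - rw) ** 2 for wi, p in zip(wm, pts)) / wsum_m
    swcc = sum(wi * (p[1] - cw) ** 2 for wi, p in zip(wm, pts)) / wsum_m
    swrc = sum(wi * (p[0] - rw) * (p[1] - cw) for wi, p in zip(wm, pts)) / wsum_m
    tr2w = (swrr + swcc) / 2.0
    discw = math.sqrt(((swrr - swcc) / 2.0) ** 2 + swrc * swrc)
    lam_w_max, lam_w_min = tr2w + discw, max(tr2w - discw, 0.0)
    axial_small = 4.0 * math.sqrt(lam_w_min) * px
    axial_ratio = math.sqrt(lam_w_min / lam_w_max) if lam_w_max > 0 else 1.0

    dists = [math.hypot(p[0] - rw, p[1] - cw) * px for p in pts]
    radial_mean = sum(dists) / n
    var = sum((d - radial_mean) ** 2 for d in dists) / n
    radial_rel_dev = math.sqrt(var) / radial_mean if radial_mean > 0 else 0.0

    padded = np.pad(mask, 1)
    depth_full = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    depth = [float(depth_full[r, c]) for r, c in pts]
    dmax = max(depth)
    mean_j = sum(w) / n
    if mean_j <= 0:
        profile1 = profile2 = 1.0
    else:
        inner = [wi for wi, d in zip(w, depth) if d / dmax >= 0.5]
        outer = [wi for wi, d in zip(w, depth) if d / dmax < 0.5]
        p_in = (sum(inner) / len(inner)) / mean_j if inner else None
        p_out = (sum(outer) / len(outer)) / mean_j if outer else None
        if p_in is None:
            p_in = p_out
        if p_out is None:
            p_out = p_in
        profile1, profile2 = p_out, p_in

    nb = config.n_angular_bins
    mass = [0.0] * nb
    for wi, p in zip(wm, pts):
        theta = math.atan2(p[0] - rw, p[1] - cw)
        b = min(int((theta + math.pi) / (2 * math.pi) * nb), nb - 1)
        mass[max(b, 0)] += wi
    total_mass = sum(mass)
    symmetry = {}
    for k in config.harmonics:
        re = im = 0.0
        for b, m in enumerate(mass):
            ang = k * ((b + 0.5) * 2 * math.pi / nb - math.pi)
            re += m * math.cos(ang)
            im += m * math.sin(ang)
        symmetry[k] = 1.0 - math.hypot(re, im) / total_mass if total_mass > 0 else 1.0

    compactness = {}
    for pct in config.compactness_percentiles:
        t = np.percentile(np.asarray(w), pct)
        sub = np.zeros_like(mask)
        for (r, c), wi in zip(pts, w):
            if wi >= t:
                sub[r, c] = True
        a_sub = int(sub.sum()) * px * px
        if a_sub == 0:
            compactness[pct] = 0.0
            continue
        p_sub = naive_perimeter(sub) * px
        compactness[pct] = 4.0 * math.pi * a_sub / p_sub**2 if p_sub > 0 else 1.0

    return {
        "Area": area,
        "Roundness": roundness,
        "Width": width,
        "Length": length,
        "Ratio Width to Length": ratio_wl,
        "Axial Small Length": axial_small,
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
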