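"""Reproducible desk-scale benchmarks of every pipeline stage.

Each function regenerates its own inputs from a seed, runs the relevant
stages, and returns measured quantities: filter-bank agreement with the
naive reference implementation, segmentation recovery on simulated scenes,
classifier accuracies, end-to-end live-fraction error against simulated
ground truth, the vital-dye/classifier divergence, and the concordance
statistics.  The acceptance script and the acceptance tests both call
these, so the reported numbers always come from live computation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .features import (
    FEATURE_PANEL,
    background_median,
    feature_vector,
    ser_features,
    star_features,
)
from .imaging import Image2D
from .pipeline import analyze_plate, live_fraction_by_well
from .quantify import TrackedOrganoid, fleiss_kappa, track_organoids
from .reference import naive_ser_features, naive_star_features
from .segmentation import OrganoidROI, segment_organoids, train_texture_model
from .simulate import (
    SimConfig,
    make_texture_annotations,
    make_training_fixture,
    make_wells,
    patch_features,
    simulate_plate,
)
from .viability import DEAD, LIVE, ViabilityClassifier
from .vitaldye import VDParams

MOD = 2**31


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 10007 + offset) % MOD


def _roi_from_mask(mask: np.ndarray, px: float = 1.0) -> OrganoidROI:
    rr, cc = np.nonzero(mask)
    bbox = (rr.min(), cc.min(), rr.max() + 1, cc.max() + 1)
    return OrganoidROI(
        roi_id=1, well="W", field=0, timepoint_day=0.0, bbox=bbox,
        mask=mask[bbox[0]: bbox[2], bbox[1]: bbox[3]],
        centroid_um=(rr.mean() * px, cc.mean() * px),
        area_um2=float(mask.sum() * px * px), touches_border=False, pixel_size_um=px,
    )


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------


def filterbank_benchmark(seed: int) -> dict:
    """Fast vs naive per-pixel feature agreement, plus analytic disk fixtures."""
    max_rel = 0.0
    for i in range(3):
        rng = np.random.default_rng(_sub_seed(seed, i))
        img = ndi.gaussian_filter(rng.uniform(200, 1000, (64, 64)), 1.0)
        yy, xx = np.mgrid[0:64, 0:64]
        mask = np.hypot(yy - 32, xx - 30) <= 18
        im = Image2D(pixels=img, pixel_size_um=1.0)
        roi = _roi_from_mask(mask)
        bg = background_median(im, mask)
        fast = {**ser_features(im, roi, bg_median=bg),
                **star_features(im, roi, bg_median=bg)[0]}
        slow = {**naive_ser_features(im, roi, bg_median=bg),
                **naive_star_features(im, roi, bg_median=bg)}
        for name in FEATURE_PANEL:
            denom = max(abs(slow[name]), 1e-12)
            max_rel = max(max_rel, abs(fast[name] - slow[name]) / denom)

    yy, xx = np.mgrid[0:64, 0:64]
    disk = np.hypot(yy - 32, xx - 32) <= 20
    im = Image2D(pixels=np.where(disk, 500.0, 1000.0), pixel_size_um=1.0)
    vals, _ = star_features(im, _roi_from_mask(disk), bg_median=1000.0)
    area_err_pct = abs(vals["Area"] - np.pi * 400) / (np.pi * 400) * 100

    const = Image2D(pixels=np.full((64, 64), 700.0), pixel_size_um=1.0)
    ser_const = ser_features(const, _roi_from_mask(disk), bg_median=700.0)

    return {
        "max_rel_deviation_vs_naive": max_rel,
        "disk_area_error_pct": float(area_err_pct),
        "disk_ratio_width_to_length": vals["Ratio Width to Length"],
        "ser_constant_max_abs": max(abs(v) for v in ser_const.values()),
        "n_fixtures": 3,
    }


# ---------------------------------------------------------------------------
# segmentation recovery
# ---------------------------------------------------------------------------


def _scene_config(seed: int, **kw) -> SimConfig:
    wells = make_wells([("drug", 10.0, "treated")], n_replicates=1)
    return SimConfig(wells=wells, seed=seed, days=(0, 3), h_max=0.4, ec50=10.0,
                     hill_gamma=1.0, baseline_hazard=0.0, **kw)


def segmentation_benchmark(seed: int, n_scenes: int = 20) -> dict:
    """Recall / count error / centroid error over seeded mixed live-dead scenes."""
    model_plate = simulate_plate(_scene_config(_sub_seed(seed, 500)))
    well = model_plate.config.wells[0].well
    images, strokes = make_texture_annotations(
        model_plate, [(well, 0.0), (well, 3.0)], seed=seed % MOD
    )
    texture = train_texture_model(images, strokes, seed=seed % MOD)

    n_true_total = n_det_total = n_matched = 0
    centroid_errs = []
    count_errs = []
    for i in range(n_scenes):
        plate = simulate_plate(_scene_config(_sub_seed(seed, i)))
        image = plate.images[(well, 3.0)]
        px = plate.config.pixel_size_um
        result = segment_organoids(image, texture)
        truth = plate.truth[(plate.truth.day == 3.0) & ~plate.truth.touches_border]
        det = np.array([r.centroid_um for r in result.rois]).reshape(-1, 2)
        n_true, n_det = len(truth), len(det)
        matched = 0
        for row in truth.itertuples():
            if n_det == 0:
                break
            d = np.hypot(det[:, 0] - row.cy_um, det[:, 1] - row.cx_um)
            j = int(np.argmin(d))
            if d[j] <= row.radius_um:  # detection centered inside the organoid
                matched += 1
                centroid_errs.append(d[j] / px)
        n_true_total += n_true
        n_det_total += n_det
        n_matched += matched
        count_errs.append(abs(n_det - n_true) / n_true)

    # border-exclusion scene: deliberately border-touching organoids
    border_plate = simulate_plate(_scene_config(_sub_seed(seed, 900), border_fraction=0.2))
    b_img = border_plate.images[(well, 3.0)]
    b_result = segment_organoids(b_img, texture)
    b_truth = border_plate.truth[border_plate.truth.day == 3.0]
    border_hits = 0
    for row in b_truth[b_truth.touches_border].itertuples():
        for r in b_result.rois:
            if np.hypot(r.centroid_um[0] - row.cy_um, r.centroid_um[1] - row.cx_um) \
                    <= row.radius_um * 0.5:
                border_hits += 1
    return {
        "recall_pct": 100.0 * n_matched / n_true_total,
        "count_error_pct": 100.0 * float(np.mean(count_errs)),
        "centroid_error_px": float(np.mean(centroid_errs)),
        "border_exclusion_errors": border_hits,
        "n_scenes": n_scenes,
        "n_organoids": n_true_total,
    }


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def classifier_benchmark(seed: int, n_live: int = 500, n_dead: int = 500) -> dict:
    """Held-out accuracy on simulator patches + the two sanity baselines."""
    cfg = SimConfig(
        wells=make_wells([("media", 0.0, "negative"), ("staurosporine", 5.0, "positive")],
                         n_replicates=1),
        seed=_sub_seed(seed, 7),
    )
    plate = simulate_plate(cfg)
    well_neg = cfg.wells[0].well
    well_pos = cfg.wells[1].well
    images, strokes = make_texture_annotations(
        plate, [(well_neg, 0.0), (well_pos, 7.0), (well_pos, 3.0)], seed=seed % MOD
    )
    texture = train_texture_model(images, strokes, seed=seed % MOD)
    patches = make_training_fixture(cfg, n_live=n_live, n_dead=n_dead,
                                    seed=_sub_seed(seed, 8))
    feats = patch_features(patches, texture_model=texture)
    rng = np.random.default_rng(17)
    idx = rng.permutation(len(feats))
    cut = int(0.7 * len(idx))
    tr, te = feats.iloc[idx[:cut]], feats.iloc[idx[cut:]]
    model = ViabilityClassifier(random_state=17)
    model.fit(tr[list(FEATURE_PANEL)], tr["label"].to_numpy())
    heldout = float(np.mean(model.predict(te[list(FEATURE_PANEL)]) == te["label"].to_numpy()))

    # perfectly separable 2-feature clouds
    rng = np.random.default_rng(_sub_seed(seed, 9))
    n = 200
    Xl = rng.normal(0, 1, (n, 2))
    Xd = rng.normal(0, 1, (n, 2))
    Xl += 8.0
    X = pd.DataFrame(np.vstack([Xl, Xd]), columns=["a", "b"])
    y = np.array([LIVE] * n + [DEAD] * n, dtype=object)
    perm = rng.permutation(2 * n)
    cut2 = int(0.75 * 2 * n)
    m2 = ViabilityClassifier(random_state=17)
    m2.fit(X.iloc[perm[:cut2]], y[perm[:cut2]])
    separable = float(np.mean(m2.predict(X.iloc[perm[cut2:]]) == y[perm[cut2:]]))

    # label-shuffled data
    rng = np.random.default_rng(_sub_seed(seed, 10))
    n = 500
    Xn = pd.DataFrame(rng.normal(0, 1, (2 * n, 5)),
                      columns=["a", "b", "c", "d", "e"])
    yn = np.array([LIVE] * n + [DEAD] * n, dtype=object)
    yn = rng.permutation(yn)
    m3 = ViabilityClassifier(random_state=17)
    m3.fit(Xn, yn)

    return {
        "heldout_accuracy": heldout,
        "separable_clouds_accuracy": separable,
        "shuffled_cv_accuracy": float(m3.cv_accuracy_),
        "shuffled_n_selected": len(m3.selected_features_),
        "selected_features": list(model.selected_features_),
        "n_patches": len(feats),
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline + vital-dye divergence
# ---------------------------------------------------------------------------


def pipeline_benchmark(seed: int, dye_loss_prob: float = 0.5) -> dict:
    """Simulate a 3-dose, 3-replicate plate; run the full pipeline; compare
    live-fraction curves with simulated truth and count the day-7 vital-dye
    vs classifier dead calls on treated wells."""
    conditions = [("media", 0.0, "negative"), ("irinotecan", 10.0, "treated"),
                  ("irinotecan", 40.0, "treated")]
    wells = make_wells(conditions, n_replicates=3)
    cfg = SimConfig(wells=wells, seed=_sub_seed(seed, 21), dye_loss_prob=dye_loss_prob,
                    h_max=0.4, ec50=10.0, hill_gamma=1.0, baseline_hazard=0.0)
    plate = simulate_plate(cfg)
    media_well = wells[0].well
    high_well = wells[-1].well
    images, strokes = make_texture_annotations(
        plate, [(media_well, 0.0), (high_well, 7.0), (high_well, 3.0)], seed=seed % MOD
    )
    texture = train_texture_model(images, strokes, seed=seed % MOD)
    patches = make_training_fixture(cfg, n_live=80, n_dead=99, seed=_sub_seed(seed, 22))
    feats = patch_features(patches, texture_model=texture)
    model = ViabilityClassifier(random_state=17)
    model.fit(feats[list(FEATURE_PANEL)], feats["label"].to_numpy())

    analysis = analyze_plate(plate, texture, model, vd_params=VDParams())
    lf = live_fraction_by_well(analysis.calls)
    truth_lf = (
        plate.truth[~plate.truth.touches_border]
        .groupby(["well", "day"])["status"]
        .apply(lambda s: float((s == "live").mean()))
        .rename("true_lf")
        .reset_index()
    )
    merged = lf.merge(truth_lf, on=["well", "day"])
    group_of = {w.well: w.group for w in wells}
    merged["group"] = merged["well"].map(group_of)
    per_cond = merged.groupby(["group", "day"])[["live_fraction", "true_lf"]].mean()
    mae = float((per_cond["live_fraction"] - per_cond["true_lf"]).abs().mean())

    treated = [w.well for w in wells if w.control != "negative"]
    day7 = analysis.calls[(analysis.calls.day == 7.0) & analysis.calls.well.isin(treated)]
    ml_dead = int((day7["label"] == "dead").sum())
    vd_dead = int((day7["vd_label"] == "dead").sum())
    return {
        "live_fraction_mae": mae,
        "ml_dead_day7": ml_dead,
        "vd_dead_day7": vd_dead,
        "vd_under_ml": bool(vd_dead < ml_dead),
        "n_curve_points": len(per_cond),
        "n_rois": len(analysis.calls),
    }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def exhaustive_gated_matching_cost(pos_a, pos_b, gate: float) -> float:
    """Brute-force optimum of the tracking objective (small instances only)."""
    n, m = len(pos_a), len(pos_b)
    dist = np.linalg.norm(
        np.asarray(pos_a)[:, None, :] - np.asarray(pos_b)[None, :, :], axis=2
    )
    best = np.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                if any(dist[r, c] > gate for r, c in zip(rows, cols)):
                    continue
                cost = sum(dist[r, c] for r, c in zip(rows, cols))
                cost += gate * ((n - k) + (m - k))
                best = min(best, cost)
    return float(best)


def _tracking_cost(tracks: list[TrackedOrganoid], pos_a, pos_b, gate: float) -> float:
    dist = np.linalg.norm(
        np.asarray(pos_a)[:, None, :] - np.asarray(pos_b)[None, :, :], axis=2
    )
    cost = 0.0
    matched_a = matched_b = 0
    for t in tracks:
        ra, rb = t.roi_by_day.get(0.0), t.roi_by_day.get(1.0)
        if ra is not None and rb is not None:
            cost += dist[ra, rb]
            matched_a += 1
            matched_b += 1
    return cost + gate * ((len(pos_a) - matched_a) + (len(pos_b) - matched_b))


def statistics_benchmark(seed: int) -> dict:
    """Fleiss' kappa fixtures and the tracking-vs-enumeration check."""
    unanimous = fleiss_kappa(np.array([[9, 0], [0, 9], [9, 0], [0, 9], [9, 0]]))

    rng = np.random.default_rng(_sub_seed(seed, 31))
    labels = rng.integers(0, 2, (500, 9))
    M = np.stack([(labels == 0).sum(axis=1), (labels == 1).sum(axis=1)], axis=1)
    random_res = fleiss_kappa(M)

    hand = fleiss_kappa(np.array([[3, 0], [2, 1], [1, 2]]))

    max_gap = 0.0
    for i in range(5):
        rng = np.random.default_rng(_sub_seed(seed, 40 + i))
        n, m = (4, 4) if i % 2 == 0 else (6, 5)
        pos_a = rng.uniform(0, 200, (n, 2))
        pos_b = rng.uniform(0, 200, (m, 2))
        gate = 80.0
        days = {0.0: [(j, tuple(p)) for j, p in enumerate(pos_a)],
                1.0: [(j, tuple(p)) for j, p in enumerate(pos_b)]}
        tracks = track_organoids(days, max_displacement_um=gate)
        got = _tracking_cost(tracks, pos_a, pos_b, gate)
        want = exhaustive_gated_matching_cost(pos_a, pos_b, gate)
        max_gap = max(max_gap, abs(got - want))

    return {
        "kappa_unanimous": unanimous.kappa,
        "kappa_random": random_res.kappa,
        "kappa_hand_matrix": hand.kappa,
        "z_hand_matrix": hand.z,
        "tracking_oracle_max_cost_gap": max_gap,
        "n_random_subjects": 500,
    }
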