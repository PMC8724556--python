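"""Tracking, well-level aggregation, response curves and concordance statistics.

This module turns per-ROI live/dead calls into the assay's readouts:
individual-organoid tracks across imaging days, per-well counts and
class-wise feature means, replicate-averaged live-fraction response curves
(optionally normalized to day 0), inter-rater/method agreement (percent
agreement, majority vote, Fleiss' kappa with its large-sample z test), and
z-scored feature-by-condition heatmap matrices with hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from .errors import ValidationError

LIVE = "live"
DEAD = "dead"


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


@dataclass
class TrackedOrganoid:
    """One organoid followed across imaging days (None = lost that day)."""

    track_id: int
    roi_by_day: dict  # day -> roi_id or None
    birth_day: float
    lost_day: float | None = None
    well: str | None = None
    field: int = 0


def _gated_assignment(
    pos_a: np.ndarray, pos_b: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Min-cost one-to-one matching with a hard distance gate.

    Objective: minimize sum of matched centroid distances plus ``gate`` per
    unmatched point on either side — i.e. a pair is worth matching exactly
    when its distance is at most the gate.  Solved exactly on an augmented
    square cost matrix.
    """
    n, m = len(pos_a), len(pos_b)
    if n == 0 or m == 0:
        return []
    dist = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    BIG = 1e9 * max(gate, 1.0)
    size = n + m
    cost = np.full((size, size), BIG)
    cost[:n, :m] = np.where(dist <= gate, dist, BIG)
    for i in range(n):
        cost[i, m + i] = gate  # a_i stays unmatched
    for j in range(m):
        cost[n + j, j] = gate  # b_j appears unmatched
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and dist[r, c] <= gate
    ]


def track_organoids(
    rois_by_day: Mapping[float, Sequence],
    max_displacement_um: float = 50.0,
) -> list[TrackedOrganoid]:
    """Follow organoids across days by optimal centroid assignment.

    ``rois_by_day`` maps each imaging day to a sequence of ROIs (anything
    with ``roi_id`` and ``centroid_um``) or ``(roi_id, (y_um, x_um))``
    tuples.  Consecutive days are linked by a one-to-one assignment
    minimizing total centroid distance among pairs within the displacement
    gate (day gaps count as single steps).  Unmatched earlier ROIs are
    lost; unmatched later ROIs open new tracks.  Deterministic and
    invariant to ROI list order.
    """
    days = sorted(rois_by_day)
    if len(days) < 2:
        raise ValidationError("tracking requires at least 2 days")

    def unpack(item):
        if hasattr(item, "roi_id"):
            return item.roi_id, item.centroid_um
        rid, cen = item
        return rid, cen

    per_day = {}
    for day in days:
        items = sorted((unpack(it) for it in rois_by_day[day]), key=lambda t: t[0])
        per_day[day] = items

    tracks: list[TrackedOrganoid] = []
    active: dict[int, TrackedOrganoid] = {}  # index into current-day roi list -> track
    first = days[0]
    for idx, (rid, _) in enumerate(per_day[first]):
        t = TrackedOrganoid(track_id=len(tracks) + 1, roi_by_day={first: rid}, birth_day=first)
        tracks.append(t)
        active[idx] = t

    for prev_day, day in zip(days, days[1:]):
        pos_a = np.array([c for _, c in per_day[prev_day]], dtype=float).reshape(-1, 2)
        pos_b = np.array([c for _, c in per_day[day]], dtype=float).reshape(-1, 2)
        pairs = _gated_assignment(pos_a, pos_b, max_displacement_um)
        matched_a = {a: b for a, b in pairs}
        matched_b = {b for _, b in pairs}
        next_active: dict[int, TrackedOrganoid] = {}
        for a_idx, track in active.items():
            if a_idx in matched_a:
                b_idx = matched_a[a_idx]
                track.roi_by_day[day] = per_day[day][b_idx][0]
                next_active[b_idx] = track
            else:
                track.roi_by_day[day] = None
                if track.lost_day is None:
                    track.lost_day = day
        for b_idx, (rid, _) in enumerate(per_day[day]):
            if b_idx not in matched_b:
                t = TrackedOrganoid(
                    track_id=len(tracks) + 1, roi_by_day={day: rid}, birth_day=day
                )
                tracks.append(t)
                next_active[b_idx] = t
        active = next_active
    return tracks


def tracks_to_table(
    tracks: list[TrackedOrganoid],
    labels: Mapping[tuple[float, int], Mapping[str, str]] | None = None,
    well: str | None = None,
    field: int = 0,
) -> pd.DataFrame:
    """Long-form tracks table; ``labels[(day, roi_id)]`` may carry
    ``{"ml": ..., "vd": ...}`` vital labels."""
    rows = []
    for t in tracks:
        for day in sorted(t.roi_by_day):
            rid = t.roi_by_day[day]
            lab = labels.get((day, rid), {}) if (labels and rid is not None) else {}
            rows.append(
                {
                    "track_id": t.track_id,
                    "well": well,
                    "field": field,
                    "day": day,
                    "roi_id": rid,
                    "ml_label": lab.get("ml"),
                    "vd_label": lab.get("vd"),
                }
            )
    return pd.DataFrame(
        rows, columns=["track_id", "well", "field", "day", "roi_id", "ml_label", "vd_label"]
    )


# ---------------------------------------------------------------------------
# well summaries and response curves
# ---------------------------------------------------------------------------


def summarize_wells(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    layout=None,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (well, day): live/dead counts and class-wise feature means.

    ``calls`` needs columns well, day, roi_id, label; ``features`` the same
    provenance plus feature columns.  Every call must join to a feature
    row, else the orphan ROI ids are reported.
    """
    if feature_columns is None:
        from .features import FEATURE_PANEL

        feature_columns = [c for c in FEATURE_PANEL if c in features.columns]
    keys = ["well", "day", "roi_id"]
    merged = calls.merge(features, on=keys, how="left", validate="one_to_one")
    orphans = merged[merged[list(feature_columns)].isna().any(axis=1)]
    if len(orphans):
        ids = orphans[keys].to_dict(orient="records")
        raise ValidationError(f"calls with no matching feature row: {ids}")
    rows = []
    for (well, day), grp in merged.groupby(["well", "day"], sort=True):
        row = {"well": well, "day": day}
        if layout is not None:
            lay = layout.row(well)
            row["condition"] = f"{lay['treatment']} {lay['dose']}{lay['unit']}"
            row["group"] = lay["group"]
        row["n_live"] = int((grp["label"] == LIVE).sum())
        row["n_dead"] = int((grp["label"] == DEAD).sum())
        for cls in (LIVE, DEAD):
            sub = grp[grp["label"] == cls]
            for feat in feature_columns:
                row[f"{cls}:{feat}"] = float(sub[feat].mean()) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def response_curves(
    summaries: pd.DataFrame,
    layout,
    mode: str = "proportion",
    normalize: bool = False,
) -> pd.DataFrame:
    """Replicate-averaged live-fraction (or live/dead ratio) time courses.

    Per condition (replicate group) and day, the per-well statistic is
    averaged over replicate wells (mean, sample sd).  With ``normalize``,
    the curve is divided by its own day-0 mean (flagged missing when that
    reference is 0).
    """
    if mode not in ("proportion", "ratio"):
        raise ValidationError("mode must be 'proportion' or 'ratio'")
    df = summaries.copy()
    if "group" not in df.columns:
        df["group"] = df["well"].map(lambda w: layout.row(w)["group"])
    total = df["n_live"] + df["n_dead"]
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "proportion":
            df["stat"] = np.where(total > 0, df["n_live"] / total, np.nan)
        else:
            df["stat"] = np.where(df["n_dead"] > 0, df["n_live"] / df["n_dead"], np.nan)
    rows = []
    for (group, day), grp in df.groupby(["group", "day"], sort=True):
        vals = grp["stat"].dropna()
        rows.append(
            {
                "condition": group,
                "day": day,
                "mode": mode,
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_wells": int(len(vals)),
                "normalized": normalize,
            }
        )
    out = pd.DataFrame(rows)
    if normalize:
        for cond, grp in out.groupby("condition"):
            ref_rows = grp[grp["day"] == 0]
            ref = float(ref_rows["mean"].iloc[0]) if len(ref_rows) else np.nan
            idx = out["condition"] == cond
            if not np.isfinite(ref) or ref == 0:
                out.loc[idx, ["mean", "sd"]] = np.nan
            else:
                out.loc[idx, "mean"] = out.loc[idx, "mean"] / ref
                out.loc[idx, "sd"] = out.loc[idx, "sd"] / ref
    return out


# ---------------------------------------------------------------------------
# concordance statistics
# ---------------------------------------------------------------------------


def percent_agreement(calls_a: Sequence, calls_b: Sequence) -> tuple[float, int, int]:
    """Fraction of aligned positions with identical labels; returns
    (fraction, n_agree, n_total)."""
    if len(calls_a) != len(calls_b):
        raise ValidationError(f"length mismatch: {len(calls_a)} vs {len(calls_b)}")
    if len(calls_a) == 0:
        raise ValidationError("need at least one aligned call")
    n_agree = sum(1 for a, b in zip(calls_a, calls_b) if a == b)
    return n_agree / len(calls_a), n_agree, len(calls_a)


def majority_vote(ratings: Sequence) -> str | None:
    """Strict-majority consensus label; None (indeterminate) on an exact tie."""
    if len(ratings) == 0:
        raise ValidationError("need at least one rating")
    counts = pd.Series(list(ratings)).value_counts()
    top = counts.max()
    winners = counts[counts == top].index.tolist()
    return winners[0] if len(winners) == 1 else None


@dataclass
class ConcordanceResult:
    """Fleiss' kappa with its large-sample z test."""

    kappa: float
    z: float
    p_value: float
    n_subjects: int
    n_raters: int
    per_category_proportions: np.ndarray = field(default_factory=lambda: np.array([]))


def fleiss_kappa(matrix) -> ConcordanceResult:
    """Chance-corrected multi-rater agreement for categorical ratings.

    ``matrix`` is subjects x categories, entry (i, j) counting raters who
    assigned subject i to category j; every row must sum to the same rater
    count n >= 2.  P_i = (sum_j n_ij^2 - n) / (n (n-1)); kappa =
    (mean_i P_i - sum_j p_j^2) / (1 - sum_j p_j^2).  The z statistic uses
    the classic large-sample null standard error, with a two-sided normal
    p-value.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValidationError("rating matrix must be 2D with >= 2 subjects")
    if np.any(M < 0) or not np.allclose(M, np.round(M)):
        raise ValidationError("rating counts must be non-negative integers")
    row_sums = M.sum(axis=1)
    n = row_sums[0]
    if n < 2:
        raise ValidationError("need >= 2 raters per subject")
    if not np.all(row_sums == n):
        raise ValidationError("balanced design required: all rows must sum to the same rater count")
    N = M.shape[0]
    P_i = (np.sum(M**2, axis=1) - n) / (n * (n - 1))
    P_bar = P_i.mean()
    p_j = M.sum(axis=0) / (N * n)
    P_e = np.sum(p_j**2)
    if P_e == 1.0:
        kappa = 1.0  # all raters always use one category
    else:
        kappa = (P_bar - P_e) / (1 - P_e)
    var = (2.0 / (N * n * (n - 1))) * (
        (P_e - (2 * n - 3) * P_e**2 + 2 * (n - 2) * np.sum(p_j**3)) / (1 - P_e) ** 2
        if P_e != 1.0
        else 0.0
    )
    se = np.sqrt(var) if var > 0 else 0.0
    z = kappa / se if se > 0 else np.inf * np.sign(kappa) if kappa != 0 else 0.0
    p = 2 * (1 - norm.cdf(abs(z))) if np.isfinite(z) else 0.0
    return ConcordanceResult(
        kappa=float(kappa),
        z=float(z),
        p_value=float(p),
        n_subjects=int(N),
        n_raters=int(n),
        per_category_proportions=p_j,
    )


def ratings_to_matrix(ratings: pd.DataFrame, subject_col: str, label_col: str) -> np.ndarray:
    """Pivot long-form (subject, rater label) rows into a count matrix."""
    tab = pd.crosstab(ratings[subject_col], ratings[label_col])
    return tab.to_numpy()


# ---------------------------------------------------------------------------
# heatmap matrices
# ---------------------------------------------------------------------------


@dataclass
class HeatmapMatrix:
    """Row-z-scored feature x group matrix with dendrogram leaf orders."""

    values: pd.DataFrame  # rows = features, cols = groups, z-scored
    row_order: list[str]
    col_order: list[str]
    constant_rows: list[str]

    def ordered(self) -> pd.DataFrame:
        return self.values.loc[self.row_order, self.col_order]


def heatmap_matrix(group_means: pd.DataFrame) -> HeatmapMatrix:
    """Z-score rows (features) across columns (groups) and cluster both axes.

    Uses sample sd (ddof=1); constant rows become all-zero and are flagged.
    Clustering is agglomerative with Euclidean distance and complete
    linkage; rows/columns are pre-sorted by name so ties break
    deterministically.
    """
    if group_means.shape[1] < 2:
        raise ValidationError("need >= 2 groups for a heatmap")
    df = group_means.copy()
    df = df.loc[sorted(df.index.astype(str)), sorted(df.columns.astype(str))]
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    constant = sds == 0
    z = df.sub(means, axis=0)
    z = z.div(sds.where(~constant, 1.0), axis=0)
    z[constant] = 0.0

    def order(frame: pd.DataFrame) -> list[str]:
        if frame.shape[0] < 2:
            return list(frame.index)
        Z = linkage(frame.to_numpy(), method="complete", metric="euclidean")
        return [frame.index[i] for i in leaves_list(Z)]

    return HeatmapMatrix(
        values=z,
        row_order=order(z),
        col_order=order(z.T),
        constant_rows=list(df.index[constant]),
    )


def group_feature_means(
    summaries: pd.DataFrame,
    layout,
    class_filter: str = DEAD,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature x (treatment, day) group means from well summaries.

    Per-well class means are averaged across wells of the same (treatment,
    day) group — one value per group — restricted to the requested class
    (the dead class by default, matching drug-perturbation phenotyping).
    """
    if feature_columns is None:
        from .features import FEATURE_PANEL

        feature_columns = [
            c for c in FEATURE_PANEL if f"{class_filter}:{c}" in summaries.columns
        ]
    df = summaries.copy()
    df["treatment"] = df["well"].map(lambda w: str(layout.row(w)["treatment"]))
    out = {}
    for (treatment, day), grp in df.groupby(["treatment", "day"], sort=True):
        col = f"{treatment}|d{day:g}"
        out[col] = [
            float(grp[f"{class_filter}:{feat}"].mean(skipna=True)) for feat in feature_columns
        ]
    return pd.DataFrame(out, index=list(feature_columns))
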