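"""Tracking, well aggregation, response curves, concordance, heatmaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoidml.errors import ValidationError
from organoidml.quantify import (
    fleiss_kappa,
    group_feature_means,
    heatmap_matrix,
    majority_vote,
    percent_agreement,
    ratings_to_matrix,
    response_curves,
    summarize_wells,
    track_organoids,
    tracks_to_table,
)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _exhaustive_gated_matching(pos_a, pos_b, gate):
    """Enumerate every one-to-one partial matching; return the minimum of
    sum(matched distances) + gate * (#unmatched on either side)."""
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
    return best


def _tracking_cost(tracks, pos_a, pos_b, day_a, day_b, gate):
    dist = np.linalg.norm(
        np.asarray(pos_a)[:, None, :] - np.asarray(pos_b)[None, :, :], axis=2
    )
    cost = 0.0
    matched_a = matched_b = 0
    for t in tracks:
        ra, rb = t.roi_by_day.get(day_a), t.roi_by_day.get(day_b)
        if ra is not None and rb is not None:
            cost += dist[ra, rb]
            matched_a += 1
            matched_b += 1
    cost += gate * ((len(pos_a) - matched_a) + (len(pos_b) - matched_b))
    return cost


class TestTracking:
    def test_identical_days_identity_matching(self):
        pts = [(10.0, 10.0), (50.0, 80.0), (90.0, 30.0)]
        days = {0.0: [(i, p) for i, p in enumerate(pts)],
                1.0: [(i, p) for i, p in enumerate(pts)]}
        tracks = track_organoids(days, max_displacement_um=50.0)
        assert len(tracks) == 3
        for t in tracks:
            assert t.roi_by_day[0.0] == t.roi_by_day[1.0]
            assert t.lost_day is None

    def test_shift_within_gate_matches_beyond_gate_does_not(self):
        # points far enough apart that no shifted point can cross-match
        pts = np.array([(20.0, 20.0), (20.0, 220.0), (20.0, 420.0)])
        gate = 50.0
        for factor, expect_matches in ((0.5, 3), (2.0, 0)):
            shifted = pts + np.array([gate * factor, 0.0])
            days = {0.0: [(i, tuple(p)) for i, p in enumerate(pts)],
                    1.0: [(i, tuple(p)) for i, p in enumerate(shifted)]}
            tracks = track_organoids(days, max_displacement_um=gate)
            n_matched = sum(
                1 for t in tracks
                if t.roi_by_day.get(0.0) is not None and t.roi_by_day.get(1.0) is not None
            )
            assert n_matched == expect_matches

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        """Optimal-assignment cost equals brute-force enumeration (4x4, 5x3)."""
        rng = np.random.default_rng(seed)
        n, m = (4, 4) if seed % 2 == 0 else (5, 3)
        pos_a = rng.uniform(0, 200, (n, 2))
        pos_b = rng.uniform(0, 200, (m, 2))
        gate = 80.0
        days = {0.0: [(i, tuple(p)) for i, p in enumerate(pos_a)],
                1.0: [(i, tuple(p)) for i, p in enumerate(pos_b)]}
        tracks = track_organoids(days, max_displacement_um=gate)
        got = _tracking_cost(tracks, pos_a, pos_b, 0.0, 1.0, gate)
        want = _exhaustive_gated_matching(pos_a, pos_b, gate)
        assert got == pytest.approx(want, rel=1e-9)

    def test_permutation_invariant_to_roi_order(self):
        rng = np.random.default_rng(3)
        pos_a = rng.uniform(0, 200, (5, 2))
        pos_b = pos_a + rng.normal(0, 5, (5, 2))
        base = {0.0: [(i, tuple(p)) for i, p in enumerate(pos_a)],
                1.0: [(i, tuple(p)) for i, p in enumerate(pos_b)]}
        t1 = track_organoids(base, 50.0)
        shuffled = {d: list(reversed(v)) for d, v in base.items()}
        t2 = track_organoids(shuffled, 50.0)
        pairs1 = {(t.roi_by_day[0.0], t.roi_by_day[1.0]) for t in t1}
        pairs2 = {(t.roi_by_day[0.0], t.roi_by_day[1.0]) for t in t2}
        assert pairs1 == pairs2

    def test_lost_and_new_tracks_over_day_gaps(self):
        days = {
            0.0: [(0, (10.0, 10.0)), (1, (100.0, 100.0))],
            1.0: [(0, (12.0, 10.0))],
            3.0: [(0, (14.0, 10.0)), (5, (200.0, 200.0))],
        }
        tracks = track_organoids(days, 50.0)
        by_birth = sorted(tracks, key=lambda t: (t.birth_day, t.track_id))
        assert [t.birth_day for t in by_birth] == [0.0, 0.0, 3.0]
        lost = next(t for t in by_birth if t.roi_by_day[0.0] == 1)
        assert lost.lost_day == 1.0
        table = tracks_to_table(tracks)
        assert set(table.columns) == {
            "track_id", "well", "field", "day", "roi_id", "ml_label", "vd_label"
        }

    def test_requires_two_days(self):
        with pytest.raises(ValidationError):
            track_organoids({0.0: []})


# ---------------------------------------------------------------------------
# summaries and curves
# ---------------------------------------------------------------------------


def _calls_features(counts):
    """counts: {(well, day): (n_live, n_dead)} -> calls + feature tables."""
    call_rows, feat_rows = [], []
    rid = 0
    for (well, day), (n_live, n_dead) in counts.items():
        for label, n in (("live", n_live), ("dead", n_dead)):
            for _ in range(n):
                rid += 1
                call_rows.append({"well": well, "day": day, "roi_id": rid, "label": label})
                feat_rows.append({"well": well, "day": day, "roi_id": rid,
                                  "Area": 100.0 + rid, "Roundness": 0.9})
    return pd.DataFrame(call_rows), pd.DataFrame(feat_rows)


class _Layout:
    def __init__(self, groups):
        self.groups = groups

    def row(self, well):
        return {"treatment": "drug", "dose": 1.0, "unit": "uM", "group": self.groups[well]}


class TestSummaries:
    def test_counts_per_well(self):
        calls, feats = _calls_features({("A1", 0.0): (8, 2)})
        summary = summarize_wells(calls, feats, feature_columns=["Area", "Roundness"])
        row = summary.iloc[0]
        assert row["n_live"] == 8 and row["n_dead"] == 2

    def test_single_roi_class_mean_is_its_value(self):
        calls, feats = _calls_features({("A1", 0.0): (1, 0)})
        summary = summarize_wells(calls, feats, feature_columns=["Area"])
        assert summary.iloc[0]["live:Area"] == feats.iloc[0]["Area"]

    def test_three_roi_means_match_hand_computation(self):
        calls, feats = _calls_features({("A1", 0.0): (2, 1)})
        summary = summarize_wells(calls, feats, feature_columns=["Area"])
        live_rows = feats.merge(calls[calls.label == "live"], on=["well", "day", "roi_id"])
        assert summary.iloc[0]["live:Area"] == pytest.approx(live_rows["Area"].mean())
        dead_rows = feats.merge(calls[calls.label == "dead"], on=["well", "day", "roi_id"])
        assert summary.iloc[0]["dead:Area"] == pytest.approx(dead_rows["Area"].mean())

    def test_orphan_roi_reported(self):
        calls, feats = _calls_features({("A1", 0.0): (2, 1)})
        with pytest.raises(ValidationError, match="no matching feature"):
            summarize_wells(calls, feats.iloc[:-1], feature_columns=["Area"])


class TestResponseCurves:
    def test_all_live_everywhere_gives_unit_curves(self):
        counts = {(w, d): (10, 0) for w in ("A1", "A2") for d in (0.0, 1.0, 3.0)}
        calls, feats = _calls_features(counts)
        summary = summarize_wells(calls, feats, feature_columns=["Area"])
        layout = _Layout({"A1": "g", "A2": "g"})
        for normalize in (False, True):
            curves = response_curves(summary, layout, normalize=normalize)
            np.testing.assert_allclose(curves["mean"], 1.0)

    def test_proportion_and_ratio_arithmetic(self):
        calls, feats = _calls_features({("A1", 0.0): (8, 2)})
        summary = summarize_wells(calls, feats, feature_columns=["Area"])
        layout = _Layout({"A1": "g"})
        prop = response_curves(summary, layout, mode="proportion")
        ratio = response_curves(summary, layout, mode="ratio")
        assert prop["mean"].iloc[0] == pytest.approx(0.8)
        assert ratio["mean"].iloc[0] == pytest.approx(4.0)

    def test_replicate_mean_and_sample_sd(self):
        counts = {("A1", 0.0): (5, 5), ("A2", 0.0): (6, 4), ("A3", 0.0): (7, 3)}
        calls, feats = _calls_features(counts)
        summary = summarize_wells(calls, feats, feature_columns=["Area"])
        layout = _Layout({w: "g" for w in ("A1", "A2", "A3")})
        curves = response_curves(summary, layout)
        assert curves["mean"].iloc[0] == pytest.approx(0.6)
        assert curves["sd"].iloc[0] == pytest.approx(0.1)
        assert curves["n_wells"].iloc[0] == 3

    def test_normalization_divides_by_day0_and_flags_zero_reference(self):
        counts = {("A1", 0.0): (8, 2), ("A1", 1.0): (4, 6),
                  ("B1", 0.0): (0, 10), ("B1", 1.0): (5, 5)}
        calls, feats = _calls_features(counts)
        summary = summarize_wells(calls, feats, feature_columns=["Area"])
        layout = _Layout({"A1": "gA", "B1": "gB"})
        curves = response_curves(summary, layout, normalize=True)
        a = curves[curves.condition == "gA"].set_index("day")
        assert a.loc[0.0, "mean"] == pytest.approx(1.0)
        assert a.loc[1.0, "mean"] == pytest.approx(0.4 / 0.8)
        b = curves[curves.condition == "gB"]
        assert b["mean"].isna().all()  # day-0 reference is 0 -> flagged missing


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


class TestAgreement:
    def test_identical_and_fully_discordant(self):
        assert percent_agreement(["live", "dead"], ["live", "dead"])[0] == 1.0
        assert percent_agreement(["live", "dead"], ["dead", "live"])[0] == 0.0

    def test_counts_returned(self):
        frac, n_agree, n_total = percent_agreement(list("aabb"), list("abbb"))
        assert (frac, n_agree, n_total) == (0.75, 3, 4)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.sampled_from(["live", "dead"]), min_size=1, max_size=30),
           st.integers(0, 2**31 - 1))
    def test_symmetric(self, a, seed):
        b = list(np.random.default_rng(seed).permutation(a))
        assert percent_agreement(a, b)[0] == percent_agreement(b, a)[0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            percent_agreement(["live"], ["live", "dead"])


class TestMajorityVote:
    def test_five_four_split(self):
        assert majority_vote(["live"] * 5 + ["dead"] * 4) == "live"

    def test_unanimous(self):
        assert majority_vote(["dead"] * 9) == "dead"

    def test_exact_tie_is_indeterminate(self):
        assert majority_vote(["live"] * 4 + ["dead"] * 4) is None


class TestFleissKappa:
    def test_unanimous_agreement_is_kappa_one(self):
        M = np.array([[9, 0], [0, 9], [9, 0], [0, 9]])
        assert fleiss_kappa(M).kappa == pytest.approx(1.0)

    def test_hand_computed_three_by_three(self):
        """3 subjects x 3 raters over 2 categories, worked by hand:

        n_ij = [[3,0],[2,1],[1,2]]; n=3, N=3
        P_i = [(9+0-3)/6, (4+1-3)/6, (1+4-3)/6] = [1, 1/3, 1/3]
        P_bar = 5/9; p = [6/9, 3/9]; P_e = 36/81+9/81 = 5/9
        kappa = (5/9 - 5/9)/(1 - 5/9) = 0
        """
        M = np.array([[3, 0], [2, 1], [1, 2]])
        res = fleiss_kappa(M)
        assert res.kappa == pytest.approx(0.0, abs=1e-12)
        # z for the null-variance formula, also by hand:
        # var = 2/(N n (n-1)) * (Pe - (2n-3)Pe^2 + 2(n-2) sum pj^3) / (1-Pe)^2
        pe = 5.0 / 9.0
        sum_p3 = (6 / 9) ** 3 + (3 / 9) ** 3
        var = (2 / (3 * 3 * 2)) * (pe - 3 * pe**2 + 2 * sum_p3) / (1 - pe) ** 2
        assert res.z == pytest.approx(0.0 / np.sqrt(var), abs=1e-12)

    def test_matches_statsmodels_on_random_tables(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(0)
        for _ in range(5):
            counts = rng.multinomial(7, [0.5, 0.3, 0.2], size=12)
            res = fleiss_kappa(counts)
            assert res.kappa == pytest.approx(sm_fleiss(counts), rel=1e-9)

    def test_random_ratings_give_kappa_near_zero(self):
        rng = np.random.default_rng(42)
        labels = rng.integers(0, 2, (500, 9))
        M = np.stack([(labels == 0).sum(axis=1), (labels == 1).sum(axis=1)], axis=1)
        res = fleiss_kappa(M)
        assert abs(res.kappa) <= 0.05

    def test_kappa_invariant_under_category_relabeling(self):
        rng = np.random.default_rng(5)
        M = rng.multinomial(9, [0.4, 0.35, 0.25], size=18)
        base = fleiss_kappa(M).kappa
        for perm in itertools.permutations(range(3)):
            assert fleiss_kappa(M[:, list(perm)]).kappa == pytest.approx(base, rel=1e-12)

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValidationError, match="balanced"):
            fleiss_kappa(np.array([[3, 0], [2, 2]]))

    def test_long_form_pivot(self):
        ratings = pd.DataFrame(
            {"subject": [1, 1, 1, 2, 2, 2], "rater": list("abcabc"),
             "label": ["live", "live", "dead", "dead", "dead", "dead"]}
        )
        M = ratings_to_matrix(ratings, "subject", "label")
        np.testing.assert_array_equal(M, [[1, 2], [3, 0]])


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------


class TestHeatmap:
    def test_rows_z_scored_constant_rows_flagged_zero(self):
        df = pd.DataFrame(
            {"g1": [1.0, 5.0, 2.0], "g2": [2.0, 5.0, 4.0], "g3": [3.0, 5.0, 9.0]},
            index=["a", "const", "c"],
        )
        hm = heatmap_matrix(df)
        assert hm.constant_rows == ["const"]
        np.testing.assert_allclose(hm.values.loc["const"], 0.0)
        for row in ("a", "c"):
            vals = hm.values.loc[row]
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std(ddof=1) == pytest.approx(1.0)

    def test_toy_z_scores_match_hand_computation(self):
        df = pd.DataFrame({"g1": [1.0], "g2": [2.0], "g3": [3.0], "g4": [6.0]},
                          index=["f"])
        hm = heatmap_matrix(df)
        vals = np.array([1.0, 2.0, 3.0, 6.0])
        expect = (vals - vals.mean()) / vals.std(ddof=1)
        np.testing.assert_allclose(hm.values.loc["f"].to_numpy(), expect)

    def test_row_order_matches_bruteforce_complete_linkage(self):
        """Leaf order groups the two nearly identical rows together, as a
        brute-force complete-linkage agglomeration does."""
        df = pd.DataFrame(
            {
                "g1": [0.0, 0.1, 10.0, 20.0],
                "g2": [1.0, 1.1, 12.0, 25.0],
                "g3": [2.0, 2.1, 14.0, 30.0],
            },
            index=["near_a", "near_b", "far_c", "far_d"],
        )
        hm = heatmap_matrix(df)
        order = hm.row_order
        # brute force on the z-scored rows: the closest pair merges first
        z = hm.values.to_numpy()
        dists = {
            (i, j): np.linalg.norm(z[i] - z[j])
            for i in range(4) for j in range(i + 1, 4)
        }
        first_pair = min(dists, key=dists.get)
        names = list(hm.values.index)
        pos = {name: order.index(name) for name in names}
        assert abs(pos[names[first_pair[0]]] - pos[names[first_pair[1]]]) == 1

    def test_requires_two_groups(self):
        with pytest.raises(ValidationError):
            heatmap_matrix(pd.DataFrame({"g1": [1.0, 2.0]}))

    def test_group_means_from_summaries_dead_class_only(self):
        summaries = pd.DataFrame(
            [
                {"well": "A1", "day": 0.0, "dead:Area": 10.0, "live:Area": 99.0},
                {"well": "A2", "day": 0.0, "dead:Area": 20.0, "live:Area": 99.0},
                {"well": "A1", "day": 1.0, "dead:Area": 30.0, "live:Area": 99.0},
                {"well": "A2", "day": 1.0, "dead:Area": 50.0, "live:Area": 99.0},
            ]
        )
        layout = _Layout({"A1": "g", "A2": "g"})
        means = group_feature_means(summaries, layout, class_filter="dead",
                                    feature_columns=["Area"])
        assert means.loc["Area", "drug|d0"] == pytest.approx(15.0)
        assert means.loc["Area", "drug|d1"] == pytest.approx(40.0)
        assert "live" not in "".join(means.columns)
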