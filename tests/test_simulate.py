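"""Plate simulator: determinism, kinetics, phenotype contrast, dye loss."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from organoidml.features import FEATURE_PANEL
from organoidml.imaging import load_plate_map, load_run_config, load_stack, max_project
from organoidml.simulate import (
    SimConfig,
    make_training_fixture,
    make_wells,
    patch_features,
    simulate_plate,
    write_plate,
)


def _single_well_cfg(treatment="media", dose=0.0, control="negative", seed=0, **kw):
    wells = make_wells([(treatment, dose, control)], n_replicates=1)
    return SimConfig(wells=wells, seed=seed, **kw)


class TestDeterminism:
    def test_same_seed_bitwise_identical_images(self):
        cfg = _single_well_cfg(seed=4)
        p1 = simulate_plate(cfg)
        p2 = simulate_plate(cfg)
        for key in p1.images:
            np.testing.assert_array_equal(p1.images[key].pixels, p2.images[key].pixels)
            np.testing.assert_array_equal(
                p1.fluorescence[key].pixels, p2.fluorescence[key].pixels
            )
        assert p1.truth.equals(p2.truth)

    def test_different_seeds_differ(self):
        p1 = simulate_plate(_single_well_cfg(seed=4))
        p2 = simulate_plate(_single_well_cfg(seed=5))
        key = ("A1", 0.0)
        assert not np.array_equal(p1.images[key].pixels, p2.images[key].pixels)

    def test_training_fixture_reproducible(self):
        cfg = _single_well_cfg(seed=9)
        a = make_training_fixture(cfg, n_live=3, n_dead=3, seed=1)
        b = make_training_fixture(cfg, n_live=3, n_dead=3, seed=1)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image.pixels, pb.image.pixels)
            assert pa.label == pb.label


class TestKinetics:
    def test_zero_hazard_keeps_everything_alive_and_dye_free(self):
        cfg = _single_well_cfg(seed=2, baseline_hazard=0.0)
        plate = simulate_plate(cfg)
        assert (plate.truth["status"] == "live").all()
        assert not plate.truth["dye_positive"].any()
        # fluorescence channel carries only background noise
        fl = plate.fluorescence[("A1", 7.0)].pixels
        assert fl.max() < cfg.fluor_background + 10 * cfg.fluor_noise_sd

    def test_dose_at_ec50_matches_closed_form_hazard(self):
        """dose = EC50, gamma = 1, h_max = 0.4/day -> hazard 0.2/day; the
        day-7 dead fraction over ~500 organoids must sit inside the exact
        binomial 95% interval around 1 - exp(-0.2 * 7)."""
        wells = make_wells([("drug", 10.0, "treated")], n_replicates=15)
        cfg = SimConfig(wells=wells, seed=3, h_max=0.4, ec50=10.0, hill_gamma=1.0,
                        baseline_hazard=0.0)
        plate = simulate_plate(cfg, render=False)
        day7 = plate.truth[plate.truth.day == 7.0]
        n = len(day7)
        assert n >= 450
        p_expect = 1.0 - np.exp(-0.2 * 7.0)
        k = int((day7["status"] == "dead").sum())
        lo, hi = stats.binom.interval(0.95, n, p_expect)
        assert lo <= k <= hi

    @pytest.mark.parametrize("dose", [5.0, 10.0, 40.0])
    def test_hazard_closed_form_across_doses_and_days(self, dose):
        """Dead fraction at every imaging day sits in the exact binomial 99%
        interval of 1 - exp(-h(dose) * t)."""
        wells = make_wells([("drug", dose, "treated")], n_replicates=10)
        cfg = SimConfig(wells=wells, seed=int(dose), h_max=0.4, ec50=10.0,
                        hill_gamma=1.0, baseline_hazard=0.0)
        plate = simulate_plate(cfg, render=False)
        h = cfg.hazard(dose, "treated")
        for day in cfg.days[1:]:
            sub = plate.truth[plate.truth.day == day]
            n = len(sub)
            k = int((sub["status"] == "dead").sum())
            lo, hi = stats.binom.interval(0.99, n, 1.0 - np.exp(-h * day))
            assert lo <= k <= hi, (dose, day, k, n)

    def test_live_fraction_matches_statuses(self):
        plate = simulate_plate(_single_well_cfg("drug", 20.0, "treated", seed=6,
                                                h_max=0.4), render=False)
        for day in plate.config.days:
            sub = plate.truth[(plate.truth.well == "A1") & (plate.truth.day == day)]
            assert plate.live_fraction("A1", day) == pytest.approx(
                (sub["status"] == "live").mean()
            )

    def test_status_monotone_live_to_dead(self):
        plate = simulate_plate(
            _single_well_cfg("drug", 40.0, "treated", seed=7, h_max=0.6), render=False
        )
        for _, grp in plate.truth.groupby("organoid_id"):
            seq = grp.sort_values("day")["status"].tolist()
            dead_seen = False
            for s in seq:
                if dead_seen:
                    assert s == "dead"
                dead_seen |= s == "dead"

    def test_positive_control_saturates_hazard(self):
        cfg = _single_well_cfg()
        assert cfg.hazard(0.0, "positive") == cfg.baseline_hazard + cfg.h_max
        assert cfg.hazard(0.0, "negative") == cfg.baseline_hazard
        assert cfg.hazard(cfg.ec50, "treated") == pytest.approx(
            cfg.baseline_hazard + cfg.h_max / 2
        )


class TestPhenotypes:
    def test_dead_patches_have_higher_ridge_valley_texture(self, two_condition_config,
                                                           texture_model):
        """The granular dead rendering must dominate smooth live rendering in
        SER Ridge/Valley — the separability the classifier relies on."""
        patches = make_training_fixture(two_condition_config, n_live=25, n_dead=25, seed=3)
        feats = patch_features(patches, texture_model=texture_model)
        live = feats[feats.label == "live"]
        dead = feats[feats.label == "dead"]
        assert dead["SER Ridge"].mean() > live["SER Ridge"].mean()
        assert dead["SER Valley"].mean() > live["SER Valley"].mean()

    def test_fixture_counts_and_labels(self, two_condition_config):
        patches = make_training_fixture(two_condition_config, n_live=80, n_dead=99, seed=1)
        assert len(patches) == 179
        assert sum(p.label == "live" for p in patches) == 80
        assert sum(p.label == "dead" for p in patches) == 99
        tiny = make_training_fixture(two_condition_config, n_live=1, n_dead=1, seed=1)
        assert [p.label for p in tiny] == ["live", "dead"]

    def test_border_fraction_places_border_touching_organoids(self):
        cfg = _single_well_cfg(seed=8, border_fraction=0.2)
        plate = simulate_plate(cfg, render=False)
        day0 = plate.truth[plate.truth.day == 0.0]
        assert day0["touches_border"].sum() >= 1


class TestDyeLoss:
    def test_dye_positive_dead_count_decays_with_time(self):
        """With dye-loss probability 0.5 per step, most long-dead organoids
        lose the dye by day 7 while the true dead count only grows."""
        wells = make_wells([("staurosporine", 5.0, "positive")], n_replicates=6)
        cfg = SimConfig(wells=wells, seed=12, dye_loss_prob=0.5)
        plate = simulate_plate(cfg, render=False)
        t = plate.truth
        dead_by_day = t[t.status == "dead"].groupby("day").size()
        dye_by_day = t[t.dye_positive].groupby("day").size()
        assert dead_by_day.loc[7.0] > dead_by_day.loc[1.0]
        # at day 7 the dye-positive count lags far behind the dead count
        assert dye_by_day.loc[7.0] < dead_by_day.loc[7.0]
        # dye is only ever seen in dead organoids
        assert (t[t.dye_positive]["status"] == "dead").all()


class TestOnDiskRoundtrip:
    def test_written_stack_projects_back_to_the_scene(self, tmp_path):
        cfg = _single_well_cfg(seed=10, days=(0, 1), n_organoids=(5, 6))
        plate = simulate_plate(cfg)
        rc = write_plate(plate, tmp_path)
        rc2 = load_run_config(tmp_path / "run_config.yaml")
        assert rc2.pixel_size_um == cfg.pixel_size_um
        path = rc2.stack_path(tmp_path, "A1", 0, "0", "brightfield")
        stack = load_stack(path, pixel_size_um=rc2.pixel_size_um,
                           z_start_um=rc2.z_start_um, z_step_um=rc2.z_step_um,
                           well="A1", timepoint_day=0.0)
        assert stack.n_planes == cfg.n_z
        proj = max_project(stack)
        np.testing.assert_allclose(
            proj.pixels, plate.images[("A1", 0.0)].pixels.astype(np.float32), rtol=1e-6
        )
        layout = load_plate_map(tmp_path / "plate_map.csv")
        assert layout.wells == ["A1"]

    def test_stack_planes_never_exceed_projection(self):
        cfg = _single_well_cfg(seed=11, days=(0,), n_organoids=(5, 6))
        plate = simulate_plate(cfg)
        stack = plate.stack("A1", 0.0)
        scene = plate.images[("A1", 0.0)].pixels
        assert np.all(stack.planes <= scene[None] + 1e-9)
        np.testing.assert_array_equal(stack.planes.max(axis=0), scene)
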