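"""Texture segmentation: pixel features, model training, the ROI pipeline."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import disk_mask
from organoidml.errors import ParameterError, TrainingError
from organoidml.imaging import Image2D
from organoidml.segmentation import (
    BACKGROUND,
    ORGANOID,
    SegmentationParams,
    Stroke,
    TextureModel,
    compute_pixel_features,
    segment_organoids,
    train_texture_model,
)


def _image(pixels, px=2.0, **kw):
    return Image2D(pixels=np.asarray(pixels, dtype=float), pixel_size_um=px, **kw)


class TestPixelFeatures:
    def test_constant_image_has_zero_derivative_planes(self):
        fmap = compute_pixel_features(_image(np.full((32, 32), 500.0)))
        by_name = dict(zip(fmap.names, fmap.planes))
        for name in ("gradient_magnitude", "hessian_eig_max", "hessian_eig_min", "local_sd"):
            np.testing.assert_allclose(by_name[name], 0.0, atol=1e-9)
        np.testing.assert_allclose(by_name["smoothed_intensity"], 500.0)

    def test_constant_offset_leaves_derivatives_unchanged(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(100, 900, (32, 32))
        f1 = compute_pixel_features(_image(base)).planes
        f2 = compute_pixel_features(_image(base + 123.0)).planes
        # all but the smoothed-intensity plane are shift-invariant
        np.testing.assert_allclose(f1[1:], f2[1:], atol=1e-8)
        np.testing.assert_allclose(f2[0] - f1[0], 123.0, atol=1e-8)

    def test_gaussian_blob_response_peaks_at_center(self):
        yy, xx = np.mgrid[0:33, 0:33]
        blob = 100.0 * np.exp(-((yy - 16.0) ** 2 + (xx - 16.0) ** 2) / (2 * 2.0**2))
        fmap = compute_pixel_features(_image(blob + 10.0), texture_scale_px=2.0)
        by_name = dict(zip(fmap.names, fmap.planes))
        # a bright blob is a minimum of the Hessian: most negative eigenvalue at center
        assert np.unravel_index(np.argmin(by_name["hessian_eig_min"]), (33, 33)) == (16, 16)
        assert np.unravel_index(np.argmax(by_name["smoothed_intensity"]), (33, 33)) == (16, 16)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ParameterError):
            compute_pixel_features(_image(np.zeros((8, 8))), texture_scale_px=0.0)


def _textured_training_image(seed=0):
    """Smooth bright background with a granular dark square region."""
    rng = np.random.default_rng(seed)
    img = 1000.0 + rng.normal(0, 5, (96, 96))
    granular = 700.0 + 80.0 * ndi.gaussian_filter(rng.normal(0, 1, (40, 40)), 0.8) * 8
    img[28:68, 28:68] = granular
    return _image(np.clip(img, 0, None))


def _strokes(region_rows, region_cols, label, image_index=0):
    rr, cc = np.mgrid[region_rows, region_cols]
    return Stroke(image_index=image_index, rows=rr.ravel(), cols=cc.ravel(), label=label)


class TestTrainTextureModel:
    def test_separable_texture_high_heldout_accuracy(self):
        im = _textured_training_image(0)
        train = [
            _strokes(slice(32, 44), slice(32, 44), ORGANOID),
            _strokes(slice(4, 16), slice(4, 16), BACKGROUND),
        ]
        model = train_texture_model([im], train, seed=0)
        score = model.score(im)
        held_fg = score[50:64, 50:64] > 0.5  # unannotated organoid region
        held_bg = score[78:92, 78:92] > 0.5  # unannotated background region
        acc = 0.5 * held_fg.mean() + 0.5 * (1 - held_bg.mean())
        assert acc >= 0.95

    def test_statistically_identical_regions_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        im = _image(1000.0 + rng.normal(0, 20, (96, 96)))
        train = [
            _strokes(slice(10, 30), slice(10, 30), ORGANOID),
            _strokes(slice(60, 80), slice(60, 80), BACKGROUND),
        ]
        model = train_texture_model([im], train, seed=0)
        score = model.score(im)
        # held-out patches drawn from the same noise field, one per class
        held_fg = score[34:50, 10:26] > 0.5
        held_bg = score[34:50, 60:76] > 0.5
        acc = 0.5 * held_fg.mean() + 0.5 * (1 - held_bg.mean())
        assert 0.4 <= acc <= 0.6

    def test_single_class_raises(self):
        im = _textured_training_image(0)
        with pytest.raises(TrainingError):
            train_texture_model([im], [_strokes(slice(0, 10), slice(0, 10), ORGANOID)])

    def test_identical_features_warn_but_return_model(self):
        im = _image(np.full((32, 32), 500.0))
        train = [
            _strokes(slice(2, 6), slice(2, 6), ORGANOID),
            _strokes(slice(20, 24), slice(20, 24), BACKGROUND),
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            model = train_texture_model([im], train)
        assert model.degenerate

    def test_default_params_match_protocol(self):
        params = SegmentationParams()
        assert params.annotation_brush_px == 15
        assert params.texture_scale_px == 2
        assert params.region_scale_px == 6

    def test_json_roundtrip_preserves_scores(self, tmp_path):
        im = _textured_training_image(3)
        train = [
            _strokes(slice(32, 44), slice(32, 44), ORGANOID),
            _strokes(slice(4, 16), slice(4, 16), BACKGROUND),
        ]
        model = train_texture_model([im], train, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        model2 = TextureModel.from_json(path)
        np.testing.assert_array_equal(model.score(im), model2.score(im))


class TestSegmentOrganoids:
    def test_blank_image_yields_no_rois(self, plate, texture_model):
        rng = np.random.default_rng(0)
        blank = _image(1000.0 + rng.normal(0, 8, (256, 256)))
        result = segment_organoids(blank, texture_model)
        assert result.rois == []
        assert result.label_map.max() == 0

    def test_simulated_scene_full_recovery(self, plate, texture_model):
        """Every non-border simulated organoid is found within 2 px."""
        key = ("A1", 0.0)
        result = segment_organoids(plate.images[key], texture_model)
        orgs = plate.organoids["A1"]
        assert len(result.rois) == len(orgs)
        px = plate.config.pixel_size_um
        for o in orgs:
            dists = [
                np.hypot(r.centroid_um[0] - o.cy_um, r.centroid_um[1] - o.cx_um) / px
                for r in result.rois
            ]
            assert min(dists) <= 2.0

    def test_border_touching_organoid_removed_and_counted(self, texture_model):
        # place one simulated-style dark disk half off the image edge
        rng = np.random.default_rng(5)
        img = 1000.0 + rng.normal(0, 8, (256, 256))
        mask = disk_mask((256, 256), (128.0, 2.0), 20.0)
        img[mask] -= 250.0
        result = segment_organoids(_image(img), texture_model)
        assert result.counts["border_removed"] >= 1
        assert all(not r.touches_border for r in result.rois)

    def test_enclosed_lumen_is_filled(self, texture_model):
        """A dark ring with a background-bright lumen segments as a full disk."""
        rng = np.random.default_rng(6)
        img = 1000.0 + rng.normal(0, 8, (256, 256))
        yy, xx = np.mgrid[0:256, 0:256]
        rho = np.hypot(yy - 128, xx - 128)
        ring = (rho <= 30) & (rho >= 12)
        img[ring] -= 280.0  # lumen (rho < 12) stays at background intensity
        result = segment_organoids(_image(img), texture_model)
        assert len(result.rois) == 1
        filled_px = np.pi * 30.0**2
        assert result.rois[0].n_pixels >= 0.9 * filled_px

    def test_determinism(self, plate, texture_model):
        key = ("B1", 3.0)
        r1 = segment_organoids(plate.images[key], texture_model)
        r2 = segment_organoids(plate.images[key], texture_model)
        np.testing.assert_array_equal(r1.label_map, r2.label_map)

    def test_roi_invariants(self, plate, texture_model):
        params = SegmentationParams()
        key = ("B1", 7.0)
        result = segment_organoids(plate.images[key], texture_model, params)
        seen = np.zeros(plate.images[key].shape, dtype=bool)
        for roi in result.rois:
            assert params.area_min_um2 <= roi.area_um2 <= params.area_max_um2
            assert not roi.touches_border
            rmin, cmin, rmax, cmax = roi.bbox
            patch = seen[rmin:rmax, cmin:cmax]
            assert not (patch & roi.mask).any()  # pairwise disjoint
            patch |= roi.mask
            # area consistency: pixel count x pixel area
            assert roi.area_um2 == roi.n_pixels * plate.config.pixel_size_um**2
            # centroid inside bounding box
            cy, cx = roi.centroid_px
            assert rmin <= cy <= rmax and cmin <= cx <= cmax

    def test_label_map_matches_rois(self, plate, texture_model):
        key = ("A1", 1.0)
        result = segment_organoids(plate.images[key], texture_model)
        for roi in result.rois:
            rmin, cmin, rmax, cmax = roi.bbox
            assert (
                (result.label_map[rmin:rmax, cmin:cmax] == roi.roi_id) == roi.mask
            ).all()
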