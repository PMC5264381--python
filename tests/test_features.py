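"""GLCM/Haralick closed forms, shape and region statistics, and the
36-variable registry contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blastograde.errors import DegenerateInputError
from blastograde.features import (FEATURE_NAMES, GLCMSpec, assemble_vector,
                                  circularity_features, compute_glcm,
                                  haralick_features, region_stats,
                                  watershed_stats)
from blastograde.segment import WatershedLabels, split_ring_and_inner
from blastograde.synthgen import EmbryoCircle, SynthConfig, render_embryo


def _disk(size, r):
    rows, cols = np.mgrid[0:size, 0:size]
    return np.hypot(rows - size // 2, cols - size // 2) <= r


class TestGLCM:
    def test_constant_image_single_diagonal_entry(self):
        img = np.full((32, 32), 77, np.uint8)
        g = compute_glcm(img, np.ones((32, 32), bool), GLCMSpec(distances=(1,)))
        for a in range(g.shape[3]):
            m = g[:, :, 0, a]
            assert m[0, 0] == pytest.approx(1.0)
            assert m.sum() == pytest.approx(1.0)

    def test_checkerboard_mass_off_diagonal(self):
        img = np.indices((16, 16)).sum(axis=0) % 2 * 255
        spec = GLCMSpec(levels=32, distances=(1,), angles_deg=(0.0,))
        m = compute_glcm(img.astype(np.uint8), np.ones((16, 16), bool), spec)[:, :, 0, 0]
        assert np.trace(m) == pytest.approx(0.0)
        # all pairs separated by the full level range: contrast = L^2
        h = haralick_features(m)
        assert h["contrast"] == pytest.approx(31**2)

    def test_mask_too_small_raises(self):
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = True
        with pytest.raises(DegenerateInputError):
            compute_glcm(np.zeros((16, 16), np.uint8), mask, GLCMSpec())

    def test_masked_pixels_never_pair(self):
        # two bright columns separated by a masked-out gap: no (bright,
        # bright) co-occurrence at distance 1 horizontally
        img = np.zeros((8, 8), np.uint8)
        img[:, 3] = 255
        img[:, 5] = 255
        mask = np.ones((8, 8), bool)
        mask[:, 4] = False
        spec = GLCMSpec(levels=2, distances=(1,), angles_deg=(0.0,))
        m = compute_glcm(img, mask, spec)[:, :, 0, 0]
        assert m[1, 1] == pytest.approx(0.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_normalization_and_haralick_bounds(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        mask = rng.random((24, 24)) < 0.8
        mask[:2, :2] = True  # keep the mask workable
        spec = GLCMSpec(distances=(1,), angles_deg=(0.0, 90.0))
        g = compute_glcm(img, mask, spec)
        for a in range(g.shape[3]):
            m = g[:, :, 0, a]
            assert m.sum() == pytest.approx(1.0)
            h = haralick_features(m)
            assert 0 < h["energy"] <= 1
            assert 0 < h["homogeneity"] <= 1
            assert h["contrast"] >= 0
            assert h["entropy"] >= 0
            assert -1 <= h["correlation"] <= 1

    def test_constant_glcm_closed_forms(self):
        m = np.zeros((32, 32))
        m[5, 5] = 1.0
        h = haralick_features(m)
        assert h["contrast"] == 0
        assert h["energy"] == 1
        assert h["homogeneity"] == 1
        assert h["entropy"] == 0
        assert h["correlation"] == 0  # zero marginal variance convention


class TestCircularity:
    def test_ideal_disk_isoperimetric_near_one(self):
        mask = _disk(200, 80)
        f = circularity_features(EmbryoCircle(100, 100, 80), mask)
        assert 0.95 <= f["isoperimetric_ratio"] <= 1.05
        assert f["radial_sd"] < 0.01

    def test_square_matches_closed_form(self):
        mask = np.zeros((200, 200), bool)
        mask[50:150, 50:150] = True
        f = circularity_features(EmbryoCircle(99.5, 99.5, 50), mask)
        assert f["isoperimetric_ratio"] == pytest.approx(np.pi / 4, rel=0.05)

    def test_jittered_boundary_raises_radial_sd(self, config):
        from blastograde.segment import embryo_footprint
        vals = {}
        for g in (1, 3):
            item = render_embryo(config, g, seed=21)
            fp = embryo_footprint(item.image, item.truth.circle)
            vals[g] = circularity_features(item.truth.circle, fp)["radial_sd"]
        assert vals[3] > vals[1]


class TestRegionStats:
    def test_constant_image_degenerate_stats(self):
        img = np.full((256, 256), 90, np.uint8)
        masks = split_ring_and_inner(img, EmbryoCircle(128, 128, 80))
        s = region_stats(img, masks)
        for region in ("embryo", "ring", "inner"):
            assert s[f"{region}_sd"] == 0
            assert s[f"{region}_p10"] == s[f"{region}_p90"] == s[f"{region}_mean"]

    def test_area_fractions_partition(self, grade_fixtures):
        for item in grade_fixtures.values():
            masks = split_ring_and_inner(item.image, item.truth.circle)
            s = region_stats(item.image, masks)
            assert s["ring_area_fraction"] + s["inner_area_fraction"] == \
                pytest.approx(1.0, abs=1e-6)

    def test_bright_ring_dark_inner(self, grade_fixtures):
        item = grade_fixtures[1]
        masks = split_ring_and_inner(item.image, item.truth.circle)
        s = region_stats(item.image, masks)
        assert s["ring_mean"] > s["inner_mean"]


class TestWatershedStats:
    def test_single_region(self):
        labels = np.ones((10, 10), np.int32)
        s = watershed_stats(WatershedLabels(labels=labels, n_regions=1))
        assert s["ws_area_cv"] == 0
        assert s["ws_largest_fraction"] == 1

    def test_two_equal_basins(self):
        labels = np.ones((10, 10), np.int32)
        labels[:, 5:] = 2
        s = watershed_stats(WatershedLabels(labels=labels, n_regions=2))
        assert s["ws_area_cv"] == pytest.approx(0.0, abs=1e-12)
        assert s["ws_largest_fraction"] == pytest.approx(0.5)
        assert s["ws_n_regions"] == 2
        assert s["ws_area_mean"] * 2 == labels.size


class TestAssembleVector:
    def test_exactly_36_named_finite_values(self, grade_fixtures):
        for item in grade_fixtures.values():
            vec = assemble_vector(item.image)
            assert len(vec.values) == 36
            assert vec.names == FEATURE_NAMES
            assert np.isfinite(vec.values).all()

    def test_deterministic(self, grade_fixtures):
        item = grade_fixtures[2]
        a = assemble_vector(item.image)
        b = assemble_vector(item.image)
        assert np.array_equal(a.values, b.values)

    def test_shape_feature_rotation_invariant(self, config):
        item = render_embryo(config, 1, seed=33)
        vec = assemble_vector(item.image)
        rot = np.rot90(item.image).copy()
        vec_r = assemble_vector(rot)
        i = FEATURE_NAMES.index("isoperimetric_ratio")
        assert vec_r.values[i] == pytest.approx(vec.values[i], rel=0.02)


def test_inner_texture_contrast_tracks_grade(config):
    """Mean inner-region GLCM contrast strictly increases with grade over
    seeded cohorts, so the features carry the generator's quality signal."""
    spec = GLCMSpec(distances=(1,), angles_deg=(0.0, 90.0))
    means = []
    for g in (1, 2, 3):
        vals = []
        for seed in range(30):
            item = render_embryo(config, g, seed=500 + seed)
            inner = item.truth.region_masks["blastocoel"] | \
                item.truth.region_masks["icm"]
            glcm = compute_glcm(item.image, inner, spec)
            vals.append(np.mean([haralick_features(glcm[:, :, 0, a])["contrast"]
                                 for a in range(glcm.shape[3])]))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
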