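"""GLCM construction and the 19 texture features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from woundtherm import (
    BinaryMask,
    FEATURE_NAMES,
    GLCM,
    GLCMConfig,
    GreyImage,
    WoundBed,
    compute_glcm,
    extract_features,
    generate_wound_image,
    glcm_features,
    quantize,
    SyntheticParams,
)
from woundtherm.preprocess import extract_wound_bed

from oracle_glcm import naive_features
from conftest import random_glcm


def bed_from(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    return WoundBed(grey=GreyImage(values=values), mask=BinaryMask(values=mask))


class TestQuantize:
    def test_two_values_two_levels(self):
        bed = bed_from([[0.0, 1.0], [0.0, 1.0]])
        levels = quantize(bed, 2)
        assert set(levels.ravel()) == {1, 2}

    def test_constant_region_all_level_one(self):
        bed = bed_from(np.full((4, 4), 0.3))
        with pytest.warns(UserWarning):
            levels = quantize(bed, 8)
        assert (levels == 1).all()

    def test_uniform_ramp_equal_occupancy(self):
        # 0..1 ramp over 800 pixels into 8 bins: each level holds 1/8
        vals = np.linspace(0.0, 1.0, 800).reshape(8, 100)
        levels = quantize(bed_from(vals), 8)
        counts = np.bincount(levels.ravel(), minlength=9)[1:]
        assert counts.max() - counts.min() <= 1

    def test_excluded_pixels_are_level_zero(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0] = True
        levels = quantize(bed_from(np.random.default_rng(0).random((3, 3)), mask), 4)
        assert (levels[~mask] == 0).all() and (levels[mask] >= 1).all()


class TestComputeGLCM:
    def test_hand_enumerated_vertical_pairs(self):
        # [[1,2],[1,2]] at 90 deg, d=1, symmetric: pairs (1,1) and (2,2) only
        levels = np.array([[1, 2], [1, 2]])
        mask = np.ones((2, 2), dtype=bool)
        g = compute_glcm(levels, mask, GLCMConfig(n_levels=2, angle=90, distance=1))
        assert np.allclose(g.p, [[0.5, 0.0], [0.0, 0.5]])
        assert g.n_pairs == 4

    def test_constant_image_delta_distribution(self):
        levels = np.ones((5, 5), dtype=int)
        g = compute_glcm(levels, np.ones((5, 5), bool), GLCMConfig(n_levels=2))
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_normalised_and_symmetric_on_random_levels(self, rng):
        levels = rng.integers(1, 9, size=(20, 20))
        mask = rng.random((20, 20)) > 0.2
        for angle in (0, 45, 90, 135):
            g = compute_glcm(levels, mask, GLCMConfig(n_levels=8, angle=angle))
            assert abs(g.p.sum() - 1.0) < 1e-12
            assert np.array_equal(g.p, g.p.T)

    def test_asymmetric_mode_counts_ordered_pairs(self):
        levels = np.array([[1], [2]])  # one vertical pair: (2, 1) at 90 deg
        g = compute_glcm(
            levels, np.ones((2, 1), bool),
            GLCMConfig(n_levels=2, angle=90, symmetric=False),
        )
        # offset (-1, 0): src row 1 (level 2) pairs with row 0 (level 1)
        assert g.p[1, 0] == 1.0

    def test_mask_excludes_pairs(self):
        levels = np.array([[1, 2], [1, 2]])
        mask = np.array([[True, True], [False, False]])
        with pytest.raises(ValueError):
            compute_glcm(levels, mask, GLCMConfig(n_levels=2, angle=90))

    def test_single_pixel_mask_errors(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        with pytest.raises(ValueError):
            compute_glcm(np.ones((3, 3), int), mask, GLCMConfig(n_levels=2))


class TestFeatures:
    def test_hand_computed_two_level_case(self):
        g = GLCM(
            p=np.array([[0.5, 0.0], [0.0, 0.5]]),
            n_pairs=4,
            config=GLCMConfig(n_levels=2),
        )
        fv = glcm_features(g)
        assert fv.Eng == pytest.approx(0.5)
        assert fv.Cont == 0.0
        assert fv.Hom == pytest.approx(1.0)
        assert fv.maxProb == pytest.approx(0.5)
        assert fv.Entr == pytest.approx(np.log(2))
        assert fv.Corr == pytest.approx(1.0)
        assert fv.aCorr == pytest.approx(2.5)
        assert fv.sumAv == pytest.approx(3.0)

    def test_constant_image_limits(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        fv = glcm_features(GLCM(p=p, n_pairs=10, config=GLCMConfig(n_levels=4)))
        for name in ("Eng", "maxProb", "Hom", "idHom", "idNorm", "idmNorm"):
            assert getattr(fv, name) == pytest.approx(1.0)
        for name in ("Cont", "Entr", "dSim"):
            assert getattr(fv, name) == pytest.approx(0.0)
        assert fv.degenerate

    @pytest.mark.parametrize("ng", [2, 5, 16])
    def test_matches_naive_oracle(self, rng, ng):
        for _ in range(20):
            g = random_glcm(rng, ng=ng)
            fv = glcm_features(g).as_dict()
            ref = naive_features(g.p.tolist())
            for name in FEATURE_NAMES:
                assert fv[name] == pytest.approx(ref[name], abs=1e-10), name

    def test_log2_base(self, rng):
        g = random_glcm(rng, ng=6)
        g2 = GLCM(p=g.p, n_pairs=g.n_pairs,
                  config=GLCMConfig(n_levels=6, log_base="2"))
        nat = glcm_features(g)
        two = glcm_features(g2)
        assert two.Entr == pytest.approx(nat.Entr / np.log(2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_feature_bounds_on_random_glcms(self, seed):
        g = random_glcm(np.random.default_rng(seed), ng=6)
        fv = glcm_features(g)
        assert 0.0 <= fv.Eng <= 1.0
        assert 0.0 <= fv.maxProb <= 1.0
        assert fv.Cont >= 0.0 and fv.Entr >= 0.0
        assert -1.0 <= fv.Corr <= 1.0 + 1e-12
        for name in ("Hom", "idHom", "idNorm", "idmNorm"):
            assert 0.0 <= getattr(fv, name) <= 1.0 + 1e-12
        # (i-j)^2 >= |i-j| for integer levels, so Hom's denominators are
        # larger and Hom <= idHom
        assert fv.Hom <= fv.idHom + 1e-12

    def test_cross_check_against_skimage_on_full_mask(self, rng):
        """Independent library cross-check: full-frame mask equals the
        standard unmasked GLCM feature values."""
        from skimage.feature import graycomatrix, graycoprops

        levels = rng.integers(1, 9, size=(30, 30))
        mask = np.ones((30, 30), bool)
        cfg = GLCMConfig(n_levels=8, angle=90, distance=1)
        ours = glcm_features(compute_glcm(levels, mask, cfg))
        sk = graycomatrix(
            (levels - 1).astype(np.uint8), distances=[1],
            angles=[np.pi / 2], levels=8, symmetric=True, normed=True,
        )
        assert ours.Cont == pytest.approx(
            float(graycoprops(sk, "contrast")[0, 0]))
        assert ours.Eng == pytest.approx(
            float(graycoprops(sk, "ASM")[0, 0]))
        assert ours.Corr == pytest.approx(
            float(graycoprops(sk, "correlation")[0, 0]), abs=1e-10)
        assert ours.dSim == pytest.approx(
            float(graycoprops(sk, "dissimilarity")[0, 0]))


class TestEndToEndFeatures:
    def test_translation_invariance(self):
        """Shifting the wound bed inside the frame leaves features unchanged."""
        rng = np.random.default_rng(3)
        patch = rng.random((10, 10))
        frame = np.full((40, 40), 0.2)
        cfg = GLCMConfig(n_levels=8)
        fvs = []
        for (r, c) in [(5, 5), (20, 12)]:
            grey = frame.copy()
            grey[r : r + 10, c : c + 10] = patch
            mask = np.zeros((40, 40), bool)
            mask[r : r + 10, c : c + 10] = True
            bed = extract_wound_bed(GreyImage(values=grey), BinaryMask(values=mask))
            levels = quantize(bed, 8)
            fvs.append(glcm_features(compute_glcm(levels, mask, cfg)).as_array())
        assert np.array_equal(fvs[0], fvs[1])

    def test_same_image_gives_identical_vectors(self):
        img = generate_wound_image(SyntheticParams(), "unhealed", 7)
        f1, n1 = extract_features(img)
        f2, n2 = extract_features(img)
        assert n1 == n2
        assert np.array_equal(f1.as_array(), f2.as_array())

    def test_class_directions_on_paired_seeds(self):
        """Unhealed beds show higher contrast and cluster prominence and
        lower idmNorm than healed beds (median over paired seeds)."""
        params = SyntheticParams()
        cont, pro, idm = [], [], []
        for s in range(12):
            fu, _ = extract_features(generate_wound_image(params, "unhealed", s))
            fh, _ = extract_features(generate_wound_image(params, "healed", s))
            cont.append((fu.Cont, fh.Cont))
            pro.append((fu.clPro, fh.clPro))
            idm.append((fu.idmNorm, fh.idmNorm))
        cont, pro, idm = map(np.array, (cont, pro, idm))
        assert np.median(cont[:, 0]) > np.median(cont[:, 1])
        assert np.median(pro[:, 0]) > np.median(pro[:, 1])
        assert np.median(idm[:, 0]) < np.median(idm[:, 1])
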