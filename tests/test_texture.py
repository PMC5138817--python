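import numpy as np
import pytest

import ctradiomics as cr
from ctradiomics.texture import (
    ExtractionConfig,
    catalog,
    extract_all,
    glcm,
    glcm_features,
    quantize,
    rlm,
    rlm_features,
)
from oracles import (
    glcm_brute,
    glcm_features_naive,
    rlm_brute,
    rlm_features_naive,
)

CANONICAL_OFFSETS = [(0, 1), (1, 0), (1, 1), (1, -1)]


class TestQuantize:
    def test_closed_form_bin_edges(self):
        vals = np.arange(256, dtype=float).reshape(1, 16, 16)
        q = quantize(vals, np.ones_like(vals, bool), Ng=8)
        assert q.levels[0, 0, 0] == 1  # value 0
        assert q.levels[0, 15, 15] == 8  # value 255

    def test_constant_roi_single_level(self):
        vals = np.full((1, 4, 4), 3.0)
        q = quantize(vals, np.ones_like(vals, bool), Ng=16)
        assert set(np.unique(q.levels)) == {1}

    def test_affine_invariance(self, rng):
        vals = rng.normal(size=(2, 6, 6))
        mask = rng.random((2, 6, 6)) > 0.3
        q1 = quantize(vals, mask, Ng=12)
        q2 = quantize(3.5 * vals + 100.0, mask, Ng=12)
        np.testing.assert_array_equal(q1.levels, q2.levels)

    def test_out_of_mask_excluded(self, rng):
        vals = rng.normal(size=(1, 5, 5))
        mask = np.zeros((1, 5, 5), bool)
        mask[0, :2] = True
        q = quantize(vals, mask, Ng=4)
        assert (q.levels[~mask] == 0).all()

    def test_ng_too_small(self):
        with pytest.raises(ValueError, match="Ng"):
            quantize(np.ones((1, 2, 2)), np.ones((1, 2, 2), bool), Ng=1)


class TestGLCM:
    def test_brute_force_agreement_on_random_masked_images(self, rng):
        for _ in range(25):
            ng = int(rng.integers(2, 6))
            lv = rng.integers(0, ng + 1, size=(5, 5)).astype(np.int32)
            if not (lv > 0).any():
                continue
            q = cr.QuantizedROI(lv, ng, (0, 1, "equal-width"))
            for off in CANONICAL_OFFSETS:
                expected = glcm_brute(lv, off, ng)
                if expected.sum() == 0:
                    with pytest.raises(ValueError):
                        glcm(q, off)
                else:
                    np.testing.assert_array_equal(glcm(q, off).counts, expected)

    def test_strip_hand_enumeration(self):
        lv = np.array([[1, 1, 2, 2]], dtype=np.int32)
        m = glcm(cr.QuantizedROI(lv, 2, (0, 1, "eq")), (0, 1))
        assert m.counts[0, 0] == 2
        assert m.counts[0, 1] + m.counts[1, 0] == 2
        assert m.counts[1, 1] == 2
        # unordered pair probabilities uniform 1/3
        assert m.p[0, 0] == pytest.approx(1 / 3)
        assert m.p[0, 1] + m.p[1, 0] == pytest.approx(1 / 3)

    def test_single_level_image(self):
        lv = np.ones((3, 3), dtype=np.int32)
        m = glcm(cr.QuantizedROI(lv, 1, (0, 0, "eq")), (0, 1))
        assert m.p[0, 0] == 1.0

    def test_no_valid_pairs_names_offset(self):
        lv = np.ones((1, 1, 1), dtype=np.int32)
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            glcm(cr.QuantizedROI(lv, 1, (0, 0, "eq")), (0, 1))


class TestGLCMFeatures:
    def test_checkerboard_correlation_and_contrast(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 + 1
        m = glcm(cr.QuantizedROI(board.astype(np.int32), 2, (0, 1, "eq")), (0, 1))
        f = glcm_features(m)
        assert f["correlation"] == pytest.approx(-1.0, abs=1e-12)
        assert f["contrast"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_image_degenerate_values(self):
        lv = np.ones((4, 4), dtype=np.int32)
        f = glcm_features(glcm(cr.QuantizedROI(lv, 3, (0, 0, "eq")), (0, 1)))
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert np.isnan(f["correlation"])

    def test_matches_naive_reference_on_random_images(self, rng):
        for _ in range(10):
            lv = rng.integers(1, 5, size=(6, 6)).astype(np.int32)
            m = glcm(cr.QuantizedROI(lv, 4, (0, 1, "eq")), (1, 1))
            ours = glcm_features(m)
            ref = glcm_features_naive(m.p)
            for k in ours:
                assert ours[k] == pytest.approx(ref[k], abs=1e-12)

    def test_correlation_bounds_and_energy_entropy_ranges(self, rng):
        for _ in range(20):
            lv = rng.integers(1, 6, size=(7, 7)).astype(np.int32)
            f = glcm_features(glcm(cr.QuantizedROI(lv, 5, (0, 1, "eq")), (0, 1)))
            if not np.isnan(f["correlation"]):
                assert -1.0 - 1e-12 <= f["correlation"] <= 1.0 + 1e-12
            assert 0.0 < f["energy"] <= 1.0
            assert f["entropy"] >= 0.0

    def test_gray_level_reversal_preserves_contrast_and_correlation(self, rng):
        ng = 5
        lv = rng.integers(1, ng + 1, size=(6, 6)).astype(np.int32)
        rev = (ng + 1 - lv).astype(np.int32)
        f1 = glcm_features(glcm(cr.QuantizedROI(lv, ng, (0, 1, "eq")), (0, 1)))
        f2 = glcm_features(glcm(cr.QuantizedROI(rev, ng, (0, 1, "eq")), (0, 1)))
        assert f1["contrast"] == pytest.approx(f2["contrast"], abs=1e-12)
        assert f1["correlation"] == pytest.approx(f2["correlation"], abs=1e-10)


class TestRLM:
    def test_row_hand_enumeration(self):
        lv = np.array([[1, 1, 1, 2]], dtype=np.int32)
        m = rlm(cr.QuantizedROI(lv, 2, (0, 1, "eq")), 1)
        assert m.r[0, 2] == 1  # level 1, length 3
        assert m.r[1, 0] == 1  # level 2, length 1
        assert m.N_r == 2

    def test_checkerboard_all_runs_length_one(self):
        board = (np.indices((5, 5)).sum(axis=0) % 2 + 1).astype(np.int32)
        m = rlm(cr.QuantizedROI(board, 2, (0, 1, "eq")), 1)
        assert m.r[:, 1:].sum() == 0
        assert m.N_r == 25

    @pytest.mark.parametrize("direction", [1, 2, 3])
    def test_brute_force_agreement(self, rng, direction):
        for _ in range(25):
            ng = int(rng.integers(2, 5))
            lv = rng.integers(0, ng + 1, size=(7, 7)).astype(np.int32)
            if not (lv > 0).any():
                continue
            q = cr.QuantizedROI(lv, ng, (0, 1, "eq"))
            ours = rlm(q, direction).r
            ref = rlm_brute(lv, direction, ng)
            np.testing.assert_array_equal(ours[:, : ref.shape[1]], ref)
            assert ours[:, ref.shape[1]:].sum() == 0

    def test_run_lengths_cover_every_masked_voxel(self, rng):
        lv = rng.integers(0, 4, size=(2, 6, 6)).astype(np.int32)
        lv[0, 0, 0] = 1
        q = cr.QuantizedROI(lv, 3, (0, 1, "eq"))
        n_masked = int((lv > 0).sum())
        for d in (1, 2, 3):
            m = rlm(q, d)
            j = np.arange(1, m.max_len + 1)
            assert int((m.r * j[None, :]).sum()) == n_masked


class TestRLMFeatures:
    def test_single_run_closed_form(self):
        lv = np.full((1, 6), 2, dtype=np.int32)  # one run of length 6
        f = rlm_features(rlm(cr.QuantizedROI(lv, 2, (0, 1, "eq")), 1))
        assert f["LRE"] == pytest.approx(36.0, abs=1e-12)
        assert f["SRE"] == pytest.approx(1 / 36.0, abs=1e-12)

    def test_all_unit_runs(self):
        board = (np.indices((4, 4)).sum(axis=0) % 2 + 1).astype(np.int32)
        f = rlm_features(rlm(cr.QuantizedROI(board, 2, (0, 1, "eq")), 1))
        assert f["SRE"] == 1.0
        assert f["LRE"] == 1.0

    def test_matches_naive_reference(self, rng):
        for _ in range(10):
            lv = rng.integers(1, 4, size=(6, 6)).astype(np.int32)
            m = rlm(cr.QuantizedROI(lv, 3, (0, 1, "eq")), 2)
            ours = rlm_features(m)
            ref = rlm_features_naive(m.r)
            for k in ours:
                assert ours[k] == pytest.approx(ref[k], abs=1e-12)


class TestExtractAll:
    CFG = ExtractionConfig(n_levels=8, glcm_offsets=((1, 1),),
                           rl_directions=(1, 3), include_gabor=False)

    def _phantom(self, seed=0):
        design = cr.CohortDesign(
            image_shape=(28, 28, 28), tumor_radius_range=(6.0, 6.0),
            texture_corr_length_by_class={"A": 1.5}, class_probs={"A": 1.0},
        )
        rng = np.random.Generator(np.random.PCG64(seed))
        return cr.generate_tumor_phantom(design, "A", rng)

    def test_row_covers_exactly_the_catalog(self):
        vol, mask = self._phantom()
        row = extract_all(vol, mask, self.CFG)
        assert list(row) == catalog(self.CFG)

    def test_default_catalog_count_matches_documented_enumeration(self):
        cfg = ExtractionConfig()
        # 5 images x (6 hist + 6 offsets x 5 GLCM + 3 directions x 5 RLM)
        # + 1 scale x 30 orientations x 5 Gabor stats + 4 shape
        expected = 5 * (6 + 6 * 5 + 3 * 5) + 30 * 5 + 4
        assert len(catalog(cfg)) == expected == 409

    def test_identical_patients_identical_rows(self):
        vol, mask = self._phantom(3)
        r1 = extract_all(vol, mask, self.CFG)
        r2 = extract_all(vol, mask, self.CFG)
        assert r1 == r2

    def test_slice_shuffle_leaves_pooled_features_unchanged(self, rng):
        # permute slices within the ROI's z-extent: pooled matrices and
        # histogram statistics must not depend on slice order
        vol, mask = self._phantom(4)
        zs = np.where(mask.voxels.any(axis=(1, 2)))[0]
        perm = np.arange(vol.shape[0])
        perm[zs] = rng.permutation(zs)
        vol2 = cr.ImageVolume(vol.intensities[perm], vol.spacing)
        mask2 = cr.ROIMask(mask.voxels[perm], mask.spacing)
        cfg = ExtractionConfig(n_levels=8, glcm_offsets=((1, 1),),
                               rl_directions=(1, 3), include_gabor=False,
                               include_shape=False)
        r1 = extract_all(vol, mask, cfg)
        r2 = extract_all(vol2, mask2, cfg)
        for name in r1:
            assert r1[name] == pytest.approx(r2[name], rel=1e-9), name

    def test_flat_roi_emits_row_with_missing_correlation(self):
        img = np.zeros((6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:5, 2:5, 2:5] = True
        row = extract_all(cr.ImageVolume(img), cr.ROIMask(mask), self.CFG)
        assert np.isnan(row["CO_correlation_d1_a1_orig"])
        assert row["CO_contrast_d1_a1_orig"] == 0.0
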