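import numpy as np
import pytest

import seedvision as sv
from seedvision.texture import ORIENTATIONS, quantize

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(gray, mask, d, theta, levels):
    """Brute-force pair enumeration, independent of the vectorized path."""
    q = quantize(gray, levels)
    h, w = q.shape
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
    assert counts.sum() > 0
    return counts / counts.sum()


class TestGLCM:
    def test_constant_image_single_entry(self):
        g = sv.compute_glcm(np.full((5, 5), 100), None, 1, 45, 8)
        q = quantize(np.array(100), 8)
        assert g.p[q, q] == 1.0
        assert g.p.sum() == 1.0

    def test_two_by_two_hand_enumeration(self):
        img = np.array([[0, 128], [0, 128]])
        g = sv.compute_glcm(img, None, 1, 0, 2)
        expected = np.zeros((2, 2))
        expected[0, 1] = 1.0  # both horizontal pairs are (0 -> 1)
        np.testing.assert_array_equal(g.p, expected)

    def test_checkerboard_hand_enumeration(self):
        img = (np.indices((4, 4)).sum(0) % 2) * 255
        g = sv.compute_glcm(img, None, 1, 0, 2)
        assert g.p[0, 1] == 0.5 and g.p[1, 0] == 0.5
        assert g.p[0, 0] == 0.0 and g.p[1, 1] == 0.0

    def test_mask_restricts_pairs(self):
        img = np.array([[0, 255, 0, 255]])
        mask = np.array([[True, True, False, True]])
        g = sv.compute_glcm(img, mask, 1, 0, 2)
        # only the (0,255) pair at columns 0-1 is fully inside the mask
        assert g.p[0, 1] == 1.0

    @pytest.mark.parametrize("theta", ORIENTATIONS)
    def test_matches_bruteforce_oracle(self, theta):
        rng = np.random.default_rng(42)
        for _ in range(25):
            img = rng.integers(0, 256, (8, 8))
            mask = rng.random((8, 8)) > 0.2
            levels = int(rng.integers(2, 17))
            try:
                g = sv.compute_glcm(img, mask, 1, theta, levels)
            except ValueError:
                continue
            np.testing.assert_array_equal(g.p, glcm_oracle(img, mask, 1, theta, levels))

    def test_no_valid_pair_raises(self):
        with pytest.raises(ValueError, match="pair"):
            sv.compute_glcm(np.zeros((3, 3)), np.zeros((3, 3), bool), 1, 0, 2)


class TestGLCMFeatures:
    @pytest.mark.parametrize("p, expected", [
        # single mass on the diagonal: perfectly uniform texture
        (np.array([[1.0, 0.0], [0.0, 0.0]]), (1.0, 0.0, 0.0, 1.0)),
        # single off-diagonal mass
        (np.array([[0.0, 1.0], [0.0, 0.0]]), (1.0, 0.0, 1.0, 0.5)),
        # checkerboard
        (np.array([[0.0, 0.5], [0.5, 0.0]]), (0.5, np.log(2), 1.0, 0.5)),
    ])
    def test_hand_computed_statistics(self, p, expected):
        asm, ent, con, hom = sv.glcm_features(sv.GLCMatrix(p, 2, 1, 0))
        assert (asm, con, hom) == pytest.approx((expected[0], expected[2], expected[3]))
        assert ent == pytest.approx(expected[1])

    def test_asm_and_entropy_antimonotone_with_randomness(self):
        rng = np.random.default_rng(1)
        constant = np.full((16, 16), 120)
        blocks = np.kron(rng.integers(0, 4, (4, 4)) * 80, np.ones((4, 4))).astype(int)
        noise = rng.integers(0, 256, (16, 16))
        stats = [sv.glcm_features(sv.compute_glcm(img, None, 1, 0, 8))
                 for img in (constant, blocks, noise)]
        asms = [s[0] for s in stats]
        ents = [s[1] for s in stats]
        assert asms[0] > asms[1] > asms[2]
        assert ents[0] < ents[1] < ents[2]


class TestAggregation:
    def test_mean_of_four(self):
        assert sv.aggregate_orientations([1, 1, 1, 1]) == 1.0
        assert sv.aggregate_orientations([0, 1, 0, 1]) == 0.5
        with pytest.raises(ValueError):
            sv.aggregate_orientations([1, 2, 3])

    def test_aggregated_contrast_invariant_under_90deg_rotation(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (12, 12))

        def agg_con(image):
            vals = [sv.glcm_features(sv.compute_glcm(image, None, 1, th, 8))[2]
                    for th in ORIENTATIONS]
            return sv.aggregate_orientations(vals)

        assert agg_con(np.rot90(img)) == pytest.approx(agg_con(img), rel=1e-12)


class TestLSP:
    def test_constant_image_all_ones(self):
        vals, elig = sv.lsp_map(np.full((6, 6), 50), np.ones((6, 6), bool))
        assert np.all(vals[elig] == 1.0)

    def test_hand_counted_neighborhood(self):
        img = np.full((3, 3), 100.0)
        img[0] = 200.0
        img[1, 0] = 200.0  # 4 of the 8 neighbours differ by > t
        vals, elig = sv.lsp_map(img, np.ones((3, 3), bool), similarity_t=10)
        assert elig[1, 1] and vals[1, 1] == 0.5

    def test_isolated_speck_scores_zero(self):
        img = np.full((5, 5), 100.0)
        img[2, 2] = 250.0
        vals, _ = sv.lsp_map(img, np.ones((5, 5), bool), similarity_t=10)
        assert vals[2, 2] == 0.0

    def test_no_eligible_pixel_raises(self):
        with pytest.raises(ValueError, match="neighbours"):
            sv.lsp_map(np.zeros((2, 2)), np.ones((2, 2), bool))

    def test_spotted_surface_scores_below_smooth(self):
        smooth = sv.SeedSpec("circular", "reddish_brown", 0.0, 0.0, 13.0, (20.0, 20.0))
        spotted = sv.SeedSpec("circular", "reddish_brown", 0.12, 0.0, 13.0, (20.0, 20.0))
        out = {}
        for name, spec in [("smooth", smooth), ("spotted", spotted)]:
            frame, _ = sv.make_frame(sv.FramePlan([spec], frame_shape=(40, 40),
                                                  grid=(1, 1), rng_seed=4))
            reg = sv.segment_frame(frame)[0]
            out[name], _ = sv.lsp_features(reg.gray, reg.mask)
        assert out["spotted"] < out["smooth"]

    def test_coarseness_larger_for_blocks_than_checkerboard(self):
        fine = (np.indices((32, 32)).sum(0) % 2) * 200.0
        blocks = np.kron((np.indices((4, 4)).sum(0) % 2) * 200.0, np.ones((8, 8)))
        mask = np.ones((32, 32), bool)
        _, c_fine = sv.lsp_features(fine, mask, coarseness_kmax=3)
        _, c_blocks = sv.lsp_features(blocks, mask, coarseness_kmax=3)
        assert c_blocks > c_fine

    def test_region_smaller_than_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            sv.lsp_features(np.zeros((4, 4)), np.ones((4, 4), bool), coarseness_kmax=4)
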