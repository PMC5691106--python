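"""Discretization, co-occurrence/run-length matrices and their features, energies."""

import numpy as np
import pytest
from _util import (
    cm_bruteforce,
    cm_features_bruteforce,
    discretize_bruteforce,
    make_volume,
    random_discrete_voi,
    rlm_bruteforce,
    rlm_features_bruteforce,
)

from petdyntex.segmentation import EmptySegmentationError
from petdyntex.texture import (
    CooccurrenceMatrix,
    DiscretizedVOI,
    RunLengthMatrix,
    build_cm,
    build_rlm,
    cm_features,
    discretize_voi,
    energy_features,
    extract_features,
    rlm_features,
)


def dvoi(levels, n_levels=16):
    return DiscretizedVOI(levels=np.asarray(levels, dtype=np.int32),
                          n_levels=n_levels, spacing=(1.0, 1.0, 1.0))


class TestDiscretize:
    def test_constant_voi_maps_to_level_one(self):
        vol = make_volume(np.full((3, 3, 3), 4.2))
        d = discretize_voi(vol, np.ones(vol.shape, dtype=bool))
        assert set(d.levels[d.mask].tolist()) == {1}

    def test_exact_bin_edges_span_all_levels(self):
        vals = np.arange(16, dtype=float).reshape(4, 2, 2)
        d = discretize_voi(make_volume(vals), np.ones((4, 2, 2), dtype=bool), n_levels=16)
        assert sorted(d.levels[d.mask].tolist()) == list(range(1, 17))

    def test_matches_loop_binning_oracle(self, rng):
        for _ in range(20):
            vol = make_volume(rng.uniform(0, 20, size=(5, 5, 5)))
            mask = rng.random(vol.shape) < 0.6
            mask.flat[0] = mask.flat[-1] = True
            d = discretize_voi(vol, mask, n_levels=16)
            got = d.levels[d.mask]
            want = discretize_bruteforce(vol.suv[mask], 16)
            np.testing.assert_array_equal(np.sort(got), np.sort(want))
            assert d.histogram.sum() == mask.sum()

    def test_permuting_voxels_preserves_histogram_not_texture(self, rng):
        vol = make_volume(rng.uniform(0, 10, size=(4, 4, 4)))
        mask = np.ones(vol.shape, dtype=bool)
        vals = vol.suv[mask]
        perm = make_volume(rng.permutation(vals).reshape(vol.shape))
        d1, d2 = discretize_voi(vol, mask), discretize_voi(perm, mask)
        np.testing.assert_array_equal(d1.histogram, d2.histogram)
        f1, f2 = cm_features(build_cm(d1)), cm_features(build_cm(d2))
        assert f1["CON"] != pytest.approx(f2["CON"], rel=1e-6)


class TestCooccurrence:
    def test_two_adjacent_voxels_give_symmetric_half_mass(self):
        cm = build_cm(dvoi([[[3, 5]]]))
        assert cm.matrix[2, 4] == pytest.approx(0.5)
        assert cm.matrix[4, 2] == pytest.approx(0.5)
        assert cm.matrix.sum() == pytest.approx(1.0)

    def test_constant_cube_has_all_mass_at_one_one(self):
        cm = build_cm(dvoi(np.ones((2, 2, 2), dtype=int)))
        assert cm.matrix[0, 0] == pytest.approx(1.0)

    def test_isolated_voxel_is_an_error(self):
        with pytest.raises(EmptySegmentationError):
            build_cm(dvoi([[[7]]]))

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            levels = random_discrete_voi(rng, max_side=5)
            try:
                cm = build_cm(dvoi(levels))
            except EmptySegmentationError:
                continue
            want, total = cm_bruteforce(levels, 16)
            assert cm.pair_count == total
            np.testing.assert_allclose(cm.matrix, want, atol=1e-15)

    def test_symmetric_and_normalized(self, rng):
        levels = random_discrete_voi(rng, max_side=6)
        cm = build_cm(dvoi(levels))
        np.testing.assert_allclose(cm.matrix, cm.matrix.T, atol=0)
        assert cm.matrix.sum() == pytest.approx(1.0, abs=1e-12)


class TestCmFeatures:
    def test_homogeneous_limit(self):
        p = np.zeros((16, 16))
        p[0, 0] = 1.0
        f = cm_features(CooccurrenceMatrix(p, pair_count=10))
        assert f == {"ENT": 0.0, "HOM": 1.0, "CON": 0.0, "DIS": 0.0, "UNI": 1.0}

    def test_hand_evaluated_two_level_matrix(self):
        p = np.zeros((16, 16))
        p[0, 1] = p[1, 0] = 0.5
        f = cm_features(CooccurrenceMatrix(p, pair_count=2))
        assert f["ENT"] == pytest.approx(np.log(2), rel=1e-12)
        assert f["HOM"] == pytest.approx(0.5, rel=1e-12)
        assert f["CON"] == pytest.approx(1.0, rel=1e-12)
        assert f["DIS"] == pytest.approx(1.0, rel=1e-12)
        assert f["UNI"] == pytest.approx(0.5, rel=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            cm_features(CooccurrenceMatrix(np.full((4, 4), 0.1), pair_count=1))

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            levels = random_discrete_voi(rng, max_side=5)
            try:
                cm = build_cm(dvoi(levels))
            except EmptySegmentationError:
                continue
            want = cm_features_bruteforce(cm.matrix)
            got = cm_features(cm)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-12)

    def test_dissimilarity_bounded_by_sqrt_contrast(self, rng):
        for _ in range(20):
            levels = random_discrete_voi(rng, max_side=5)
            try:
                f = cm_features(build_cm(dvoi(levels)))
            except EmptySegmentationError:
                continue
            assert f["DIS"] <= np.sqrt(f["CON"]) + 1e-12


class TestRunLength:
    def test_single_voxel_gives_13_unit_runs(self):
        r = build_rlm(dvoi([[[4]]]))
        assert r.n_runs == 13
        assert r.matrix[3, 0] == 13
        assert r.matrix.shape[1] == 1

    def test_constant_line_hand_enumeration(self):
        r = build_rlm(dvoi(np.ones((1, 1, 4), dtype=int)))
        assert r.matrix[0, 3] == 1  # one run of length 4 along the line
        assert r.matrix[0, 0] == 48  # 12 other directions x 4 unit runs
        assert r.n_runs == 49

    def test_matches_groupby_line_oracle(self, rng):
        for _ in range(30):
            levels = random_discrete_voi(rng, max_side=5)
            r = build_rlm(dvoi(levels))
            want = rlm_bruteforce(levels, 16)
            np.testing.assert_array_equal(r.matrix, want)

    def test_voxel_direction_conservation(self, rng):
        for _ in range(20):
            levels = random_discrete_voi(rng, max_side=6)
            r = build_rlm(dvoi(levels))
            assert r.n_voxel_direction == 13 * int((levels > 0).sum())
            assert r.n_runs == int(r.matrix.sum())


class TestRlmFeatures:
    def test_degenerate_unit_run_matrix(self):
        mat = np.zeros((16, 1), dtype=int)
        mat[0, 0] = 7
        f = rlm_features(RunLengthMatrix(mat))
        for k in ("SRE", "LRE", "RPC", "LGRE", "HGRE"):
            assert f[k] == pytest.approx(1.0)
        assert f["GLNU"] == pytest.approx(7.0)
        assert f["RLNU"] == pytest.approx(7.0)

    def test_constant_line_hand_values(self):
        r = build_rlm(dvoi(np.ones((1, 1, 4), dtype=int)))
        f = rlm_features(r)
        assert f["SRE"] == pytest.approx((48 + 1 / 16) / 49, rel=1e-12)
        assert f["LRE"] == pytest.approx(64 / 49, rel=1e-12)
        assert f["RPC"] == pytest.approx(49 / 52, rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            levels = random_discrete_voi(rng, max_side=5)
            r = build_rlm(dvoi(levels))
            want = rlm_features_bruteforce(r.matrix)
            got = rlm_features(r)
            for k in want:
                assert got[k] == pytest.approx(want[k], rel=1e-12)


class TestEnergies:
    def test_constant_voi_has_zero_energies(self):
        vol = make_volume(np.full((4, 4, 4), 6.0))
        f = energy_features(vol, np.ones(vol.shape, dtype=bool))
        assert f["SE"] == 0.0 and f["TE"] == 0.0

    def test_scale_invariance(self, rng):
        vol = make_volume(rng.uniform(1, 10, size=(5, 5, 5)))
        mask = np.ones(vol.shape, dtype=bool)
        f1 = energy_features(vol, mask)
        f2 = energy_features(make_volume(vol.suv * 4.0), mask)
        assert f2["SE"] == pytest.approx(f1["SE"], rel=1e-12)
        assert f2["TE"] == pytest.approx(f1["TE"], rel=1e-12)

    def test_linear_ramp_closed_form(self):
        a = 1.7
        x = np.arange(4.0)
        vol = make_volume(np.broadcast_to(a * x[:, None, None], (4, 4, 4)).copy())
        f = energy_features(vol, np.ones((4, 4, 4), dtype=bool))
        # every voxel's gradient is (a, 0, 0): central in the interior,
        # one-sided at the faces, both equal a on a linear ramp
        grad_energy = np.sqrt(64 * a**2 * 1.0)
        u_norm = np.sqrt(16 * a**2 * (0 + 1 + 4 + 9) * 1.0)
        assert f["SE"] == pytest.approx(grad_energy / u_norm, rel=1e-12)
        assert f["SE"] == pytest.approx(0.5345224838248488, rel=1e-12)
        assert f["TE"] == pytest.approx(grad_energy / (3 * a), rel=1e-12)

    def test_gradient_uses_physical_spacing(self):
        a = 2.0
        z = np.arange(4.0)
        arr = np.broadcast_to(a * z[None, None, :], (4, 4, 4)).copy()
        f1 = energy_features(make_volume(arr, spacing=(1, 1, 1)),
                             np.ones((4, 4, 4), dtype=bool))
        f2 = energy_features(make_volume(arr, spacing=(1, 1, 2)),
                             np.ones((4, 4, 4), dtype=bool))
        # halving the slope (per mm) halves SE; TE also picks up the dV change
        assert f2["SE"] == pytest.approx(f1["SE"] / 2, rel=1e-12)


class TestExtractFeatures:
    def _phantom(self, rng, noise=0.0):
        base = np.full((8, 8, 8), 5.0)
        if noise:
            base = base + rng.normal(0, noise, base.shape)
        vol = make_volume(np.clip(base, 0, None))
        from petdyntex.segmentation import BoundingBox, threshold_voi

        return vol, threshold_voi(vol, BoundingBox(0, 8, 0, 8, 0, 8), fraction=0.4)

    def test_uniform_phantom_hits_homogeneous_limits(self, rng):
        vol, mask = self._phantom(rng, noise=0.0)
        f = extract_features(vol, mask)
        assert f["ENT"] == 0.0 and f["CON"] == 0.0 and f["DIS"] == 0.0
        assert f["HOM"] == 1.0 and f["UNI"] == 1.0
        assert f["SE"] == 0.0 and f["TE"] == 0.0

    def test_noise_ladder_orders_heterogeneity_features(self, rng):
        ladder = [0.0, 0.1, 0.2, 0.4]
        feats = []
        for amp in ladder:
            vol, mask = self._phantom(np.random.default_rng(99), noise=amp)
            feats.append(extract_features(vol, mask))
        for name in ("ENT", "CON", "DIS", "SE"):
            vals = [f[name] for f in feats]
            assert vals == sorted(vals), name
        for name in ("HOM", "UNI"):
            vals = [f[name] for f in feats]
            assert vals == sorted(vals, reverse=True), name

    def test_shuffled_voxels_are_rougher_than_smooth_field(self, rng):
        x = np.linspace(0, 1, 8)
        smooth = 4.0 + 3.0 * np.add.outer(np.add.outer(x, x), x) / 3.0
        vol_s = make_volume(smooth)
        shuffled = rng.permutation(smooth.ravel()).reshape(smooth.shape)
        vol_r = make_volume(shuffled)
        from petdyntex.segmentation import BoundingBox, threshold_voi

        box = BoundingBox(0, 8, 0, 8, 0, 8)
        fs = extract_features(vol_s, threshold_voi(vol_s, box, 0.4))
        fr = extract_features(vol_r, threshold_voi(vol_r, box, 0.4))
        assert fr["CON"] > fs["CON"] and fr["DIS"] > fs["DIS"]
        assert fr["SE"] > fs["SE"] and fr["HOM"] < fs["HOM"]

    def test_repeat_call_determinism(self, rng):
        vol, mask = self._phantom(rng, noise=0.3)
        f1 = extract_features(vol, mask)
        f2 = extract_features(vol, mask)
        assert (f1 == f2).all()
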