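"""Profiles, peak selection, gradient fit and cluster statistics."""

import numpy as np
import pytest

from eventscales.gradient import (
    PeakSet,
    WeightMap,
    cluster_permutation_map,
    compare_accuracy_maps,
    compare_slopes_between_models,
    find_peaks,
    fit_gradient,
    rotation_analysis,
    weight_profile,
)


def _grid_map(shape=(10, 40), fill=0.0):
    ap, isax = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    coords = np.column_stack([ap.ravel(), isax.ravel()]).astype(float)
    return WeightMap(weights=np.full(coords.shape[0], fill), coords=coords)


class TestWeightProfile:
    def test_constant_map_gives_constant_profile(self):
        wm = _grid_map(fill=0.7)
        pos, prof = weight_profile(wm, smooth_window=12.0)
        assert np.allclose(prof, 0.7, atol=1e-9)

    def test_profile_length_formula(self):
        wm = _grid_map(shape=(4, 30))
        pos, prof = weight_profile(wm, window_height=2.0, step=1.0, smooth_window=10.0)
        extent = 29.0  # occupied inferior-superior extent
        assert len(prof) == int(np.floor((extent - 2.0) / 1.0)) + 1

    def test_localised_bump_peaks_at_its_location(self):
        wm = _grid_map(shape=(6, 50))
        bump = np.abs(wm.coords[:, 1] - 30) <= 3
        wm.weights[bump] = 5.0 - np.abs(wm.coords[bump, 1] - 30)
        pos, prof = weight_profile(wm, smooth_window=12.0)
        assert pos[np.argmax(prof)] == pytest.approx(30.0, abs=2.0)

    def test_robust_smoother_downweights_isolated_spike(self):
        # a spike confined to a single 1-mm row is an outlier to the
        # bisquare smoother and must not dominate the profile
        wm = _grid_map(shape=(6, 50))
        spike = (wm.coords[:, 1] == 30) & (wm.coords[:, 0] == 3)
        wm.weights[spike] = 5.0
        pos, prof = weight_profile(wm, smooth_window=12.0)
        raw_peak = 5.0 / 6.0  # window mean at the spike row before smoothing
        assert prof.max() < 0.5 * raw_peak

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            weight_profile(WeightMap(weights=np.array([]), coords=np.empty((0, 2))))


class TestFindPeaks:
    def test_enumerated_local_maxima(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        positions = np.arange(5.0)
        ps = find_peaks([profile], positions, "unconstrained")
        # local maxima at indices 1 and 3; highest positive is index 3
        assert ps.coordinates[0] == 3.0 and not ps.fallback[0]

    def test_monotone_profile_falls_back_to_last_sample(self):
        profile = np.arange(6, dtype=float)
        ps = find_peaks([profile], np.arange(6.0), "unconstrained")
        assert ps.coordinates[0] == 5.0 and ps.fallback[0]

    def test_all_negative_profile_flagged(self):
        profile = -np.array([1.0, 3.0, 2.0])
        ps = find_peaks([profile], np.arange(3.0), "unconstrained")
        assert ps.fallback[0]

    def test_constrained_scale1_restricted_to_inferior_half(self):
        positions = np.arange(11.0)
        p1 = np.zeros(11)
        p1[2] = 1.0  # inferior local maximum
        p1[8] = 5.0  # larger but superior -> not admissible for scale 1
        p2 = np.zeros(11)
        p2[6] = 2.0
        ps = find_peaks([p1, p2], positions, "constrained")
        assert ps.coordinates[0] == 2.0
        assert ps.coordinates[1] == 6.0

    def test_constrained_higher_scales_superior_to_scale1(self):
        positions = np.arange(11.0)
        p1 = np.zeros(11)
        p1[4] = 1.0
        p2 = np.zeros(11)
        p2[1] = 3.0  # inferior to scale 1's peak -> excluded
        p2[7] = 0.5
        ps = find_peaks([p1, p2], positions, "constrained")
        assert ps.coordinates[1] == 7.0

    def test_peaks_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 30)
        positions = np.arange(30.0)
        a = find_peaks([profile], positions, "unconstrained").coordinates
        b = find_peaks([5.0 * profile], positions, "unconstrained").coordinates
        assert np.array_equal(a, b)


class TestFitGradient:
    def test_perfect_linear_coordinates(self):
        ps = PeakSet(np.array([0.0, 10, 20, 30, 40]), "unconstrained", np.zeros(5, bool))
        res = fit_gradient([ps, ps], n_shuffle=100, seed=0)
        assert res.grand_average == pytest.approx(10.0)
        assert np.allclose(res.r_squared, 1.0)

    def test_shuffle_null_mean_near_zero(self):
        rng = np.random.default_rng(1)
        sets = [
            PeakSet(rng.uniform(0, 40, 5), "unconstrained", np.zeros(5, bool))
            for _ in range(6)
        ]
        res = fit_gradient(sets, n_shuffle=10000, seed=2)
        se = res.null.std() / np.sqrt(len(res.null))
        assert abs(res.null.mean()) < 2 * se + 0.02

    def test_constrained_mode_keeps_scale1_fixed_in_null(self):
        # with only the scale-1 coordinate distinct, shuffles of scales 2-5
        # leave every permutation's slope unchanged -> degenerate null
        ps = PeakSet(np.array([0.0, 20, 20, 20, 20]), "constrained", np.zeros(5, bool))
        res = fit_gradient([ps, ps], n_shuffle=50, seed=3)
        assert np.allclose(res.null, res.grand_average)

    def test_between_model_comparison(self):
        a = np.array([10.0, 11.0, 9.0, 10.5])
        obs, p = compare_slopes_between_models(a, a, n_perm=100, seed=0)
        assert obs == 0.0 and p == 1.0


class TestClusterPermutation:
    def _coords(self, shape=(8, 8)):
        ap, isax = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return np.column_stack([ap.ravel(), isax.ravel()]).astype(float)

    def test_all_zero_maps_give_no_clusters(self):
        coords = self._coords()
        rng = np.random.default_rng(0)
        maps = rng.normal(0, 1e-12, (5, coords.shape[0]))
        scr = rng.normal(0, 1e-12, (10, 5, coords.shape[0]))
        assert cluster_permutation_map(maps, scr, coords) == []

    def test_block_cluster_summed_t_by_direct_addition(self):
        from scipy import stats

        coords = self._coords()
        rng = np.random.default_rng(1)
        maps = rng.normal(0, 0.1, (8, coords.shape[0]))
        block = (coords[:, 0] < 3) & (coords[:, 1] < 3)
        maps[:, block] += 3.0
        scr = rng.normal(0, 0.1, (20, 8, coords.shape[0]))
        clusters = cluster_permutation_map(maps, scr, coords)
        pos = [c for c in clusters if c["sign"] == 1]
        assert len(pos) == 1
        t, p = stats.ttest_1samp(maps, 0.0, axis=0)
        members = pos[0]["members"]
        assert set(members) == set(np.flatnonzero(block))
        assert pos[0]["summed_t"] == pytest.approx(t[block].sum())
        assert pos[0]["significant"]

    def test_isolated_vertex_with_one_neighbor_not_clustered(self):
        coords = self._coords()
        rng = np.random.default_rng(2)
        maps = rng.normal(0, 0.1, (8, coords.shape[0]))
        # two adjacent significant vertices: each has only 1 significant
        # neighbour -> below the two-neighbour rule
        pair = [0, 1]
        maps[:, pair] += 5.0
        scr = rng.normal(0, 0.1, (10, 8, coords.shape[0]))
        clusters = cluster_permutation_map(maps, scr, coords)
        for c in clusters:
            assert not set(pair) & set(c["members"])

    def test_no_scrambles_rejected(self):
        coords = self._coords()
        with pytest.raises(ValueError):
            cluster_permutation_map(
                np.zeros((3, coords.shape[0])), np.zeros((0, 3, coords.shape[0])), coords
            )


class TestCompareAccuracyMaps:
    def test_equal_maps_give_no_clusters(self):
        coords = np.column_stack(
            [np.repeat(np.arange(6), 6), np.tile(np.arange(6), 6)]
        ).astype(float)
        rng = np.random.default_rng(3)
        A = rng.normal(0, 1, (6, 36))
        assert compare_accuracy_maps(A, A.copy(), coords, n_perm=20, seed=0) == []

    def test_sign_symmetry_on_swap(self):
        coords = np.column_stack(
            [np.repeat(np.arange(6), 6), np.tile(np.arange(6), 6)]
        ).astype(float)
        rng = np.random.default_rng(4)
        A = rng.normal(0, 0.1, (8, 36))
        B = A + 0.0
        B = B.copy()
        region = coords[:, 1] < 3
        A = A.copy()
        A[:, region] += 1.0
        c_ab = compare_accuracy_maps(A, B, coords, n_perm=50, seed=1)
        c_ba = compare_accuracy_maps(B, A, coords, n_perm=50, seed=1)
        t_ab = sorted(c["summed_t"] for c in c_ab)
        t_ba = sorted(-c["summed_t"] for c in c_ba)
        assert np.allclose(t_ab, t_ba)

    def test_planted_region_localised(self):
        coords = np.column_stack(
            [np.repeat(np.arange(8), 8), np.tile(np.arange(8), 8)]
        ).astype(float)
        rng = np.random.default_rng(5)
        A = rng.normal(0, 1, (10, 64))
        B = rng.normal(0, 1, (10, 64))
        region = (coords[:, 0] < 4) & (coords[:, 1] < 4)
        A[:, region] += 2.0
        clusters = compare_accuracy_maps(A, B, coords, n_perm=60, seed=2)
        pos = [c for c in clusters if c["sign"] == 1 and c["significant"]]
        assert pos
        members = set(np.concatenate([c["members"] for c in pos]))
        assert members <= set(np.flatnonzero(region))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_accuracy_maps(np.zeros((3, 6)), np.zeros((3, 7)), np.zeros((6, 2)))


class TestRotation:
    def _linear_maps(self, n_sub=3, shape=(10, 24), slope=4.0):
        ap, isax = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        coords = np.column_stack([ap.ravel(), isax.ravel()]).astype(float)
        rng = np.random.default_rng(6)
        maps = []
        for _ in range(n_sub):
            per_scale = []
            for s in range(1, 6):
                w = np.exp(-0.5 * ((coords[:, 1] - slope * (s - 1) - 2) / 2.0) ** 2)
                w = w + rng.normal(0, 0.02, w.size)
                per_scale.append(WeightMap(weights=w, coords=coords))
            maps.append(per_scale)
        return maps

    def test_zero_rotation_reproduces_unrotated_slope(self):
        maps = self._linear_maps()
        out = rotation_analysis(maps, step_deg=90.0, n_shuffle=60, seed=0,
                                profile_kwargs={"smooth_window": 8.0})
        from eventscales.gradient import find_peaks, fit_gradient, weight_profile

        peaksets = []
        for per_scale in maps:
            profs, pos = [], None
            for wm in per_scale:
                pos, pr = weight_profile(wm, smooth_window=8.0)
                profs.append(pr)
            peaksets.append(find_peaks(profs, pos, "unconstrained"))
        direct = fit_gradient(peaksets, n_shuffle=10, seed=1).grand_average
        assert out["slope"][0] == pytest.approx(direct)

    def test_half_turn_flips_slope_sign(self):
        maps = self._linear_maps()
        out = rotation_analysis(maps, step_deg=180.0, n_shuffle=40, seed=2,
                                profile_kwargs={"smooth_window": 8.0})
        assert out["slope"][0] > 0
        assert np.sign(out["slope"][1]) == -np.sign(out["slope"][0])

    def test_aligned_gradient_yields_cluster_near_zero_rotation(self):
        maps = self._linear_maps()
        out = rotation_analysis(maps, step_deg=45.0, n_shuffle=80, seed=3,
                                profile_kwargs={"smooth_window": 8.0})
        sig = [c for c in out["clusters"] if c["p"] < 0.2]
        assert sig
        rots = np.concatenate([c["rotations"] for c in sig])
        # wrap to [-180, 180): the planted gradient is axis-aligned
        wrapped = (rots + 180) % 360 - 180
        assert np.any(np.abs(wrapped) <= 45)
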