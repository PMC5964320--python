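import numpy as np
import pytest

from neuroadaptive.inference_maps import (
    VoxelMaps,
    cluster_summaries,
    compare_with_hypothesis,
    spatial_similarity,
    tmax_permutation,
    voxelwise_prediction_maps,
)
from neuroadaptive.fixtures import fixture_bundle
from neuroadaptive.synthetic_bold import GroundTruthSurface, SyntheticScanner
from neuroadaptive.target_measure import contrasts_from_run


def _voxel_maps(preds, clusters=None):
    preds = np.atleast_2d(np.asarray(preds, float))
    n = preds.shape[0]
    return VoxelMaps(
        predictions=preds,
        candidate_ids=tuple(f"t{j}" for j in range(preds.shape[1])),
        voxel_clusters=tuple(clusters or ["c1"] * n),
        noise_sd=np.zeros(n),
    )


class TestSpatialSimilarity:
    def test_identical_map_hits_clip(self):
        ref = np.array([0.1, 0.5, 0.9, 0.3])
        sim = spatial_similarity(_voxel_maps([ref]), ref)
        assert sim.r[0] == pytest.approx(1.0)
        assert sim.z[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_anticorrelated_map(self):
        ref = np.array([0.1, 0.5, 0.9, 0.3])
        sim = spatial_similarity(_voxel_maps([-ref]), ref)
        assert sim.r[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        a, b = rng.normal(size=16), rng.normal(size=16)
        sim = spatial_similarity(_voxel_maps([a]), b)
        oracle = ((a - a.mean()) @ (b - b.mean())) / (
            np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert sim.r[0] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_voxel_flagged(self):
        ref = np.array([0.1, 0.5, 0.9])
        sim = spatial_similarity(_voxel_maps([[1.0, 1.0, 1.0]]), ref)
        assert not sim.valid[0]
        assert np.isnan(sim.r[0])

    def test_fisher_z_monotone_in_r(self, rng):
        ref = rng.normal(size=10)
        maps = _voxel_maps([ref + rng.normal(size=10) * s for s in (0.1, 1.0, 5.0)])
        sim = spatial_similarity(maps, ref)
        order_r = np.argsort(sim.r)
        order_z = np.argsort(sim.z)
        assert np.array_equal(order_r, order_z)


class TestClusterSummaries:
    def test_constant_cluster_mean(self):
        z = np.full((1, 5), 0.5)
        mat, ids = cluster_summaries(z, ["c1"] * 5, min_voxels=1)
        assert ids == ("c1",)
        assert mat[0, 0] == pytest.approx(0.5)

    def test_size_threshold_boundary(self):
        labels = ["small"] * 199 + ["big"] * 200
        z = np.zeros((2, 399))
        mat, ids = cluster_summaries(z, labels, min_voxels=200)
        assert ids == ("big",)

    def test_two_surviving_clusters(self):
        labels = ["a"] * 250 + ["b"] * 300
        z = np.ones((3, 550))
        mat, ids = cluster_summaries(z, labels, min_voxels=200)
        assert mat.shape == (3, 2)

    def test_no_survivors_rejected(self):
        with pytest.raises(ValueError):
            cluster_summaries(np.zeros((1, 3)), ["a"] * 3, min_voxels=10)


class TestTmaxPermutation:
    def test_ten_subjects_enumerates_1024_sign_flips(self, rng):
        data = rng.normal(size=(10, 3))
        res = tmax_permutation(data, exhaustive=True)
        assert res.n_permutations == 2**10
        assert res.corrected_p.min() >= 1 / 1024

    def test_all_zero_data_rejects_nothing(self):
        data = np.zeros((8, 4))
        data[:, 0] = [1e-9, -1e-9] * 4  # keep one testable column
        with pytest.warns(UserWarning):
            res = tmax_permutation(data)
        assert np.all(res.corrected_p > 0.05)

    def test_strong_effect_detected(self, rng):
        data = rng.normal(size=(10, 4))
        data[:, 2] += 3.0
        res = tmax_permutation(data)
        assert res.corrected_p[2] <= 0.05
        assert res.observed_t[2] > res.critical_t

    def test_identity_assignment_in_null(self, rng):
        """Corrected p can never fall below 1/2^n."""
        data = rng.normal(size=(6, 2)) + 10.0
        res = tmax_permutation(data, exhaustive=True)
        assert np.all(res.corrected_p >= 1 / 2**6)

    def test_zero_variance_cluster_excluded_with_warning(self, rng):
        data = np.column_stack([rng.normal(size=8), np.ones(8)])
        with pytest.warns(UserWarning):
            res = tmax_permutation(data, cluster_ids=("ok", "flat"))
        assert res.excluded == ("flat",)
        assert res.cluster_ids == ("ok",)

    def test_monte_carlo_mode_seeded(self, rng):
        data = rng.normal(size=(20, 3))
        a = tmax_permutation(data, exhaustive=False, n_permutations=500, seed=4)
        b = tmax_permutation(data, exhaustive=False, n_permutations=500, seed=4)
        assert np.allclose(a.corrected_p, b.corrected_p)


@pytest.fixture(scope="module")
def run_and_bundle():
    bundle = fixture_bundle("exp1_like")
    quiet = GroundTruthSurface(roi_means=bundle.truth.roi_means, noise_sd=0.2)
    scanner = SyntheticScanner(
        bundle.space, quiet, protocol="exp1", max_blocks=16,
        voxels_per_roi=4, seed=3, voxel_noise_sd=0.2,
    )
    return scanner.run_for(bundle.space.ids), bundle


class TestVoxelwiseBackProjection:
    def test_reference_voxels_are_flat(self, run_and_bundle):
        run, bundle = run_and_bundle
        vmaps = voxelwise_prediction_maps(run, "vFPN", bundle.space, restarts=2)
        ref_idx = run.voxel_rois["vFPN"]
        # vFPN voxels contrasted against the vFPN timecourse: predictions ~ 0
        assert np.all(np.abs(vmaps.predictions[ref_idx]) < 0.25)

    def test_target_voxels_recover_contrast_surface(self, run_and_bundle):
        run, bundle = run_and_bundle
        vmaps = voxelwise_prediction_maps(run, "vFPN", bundle.space, restarts=2)
        amps = bundle.truth.roi_means
        truth = np.array(
            [amps["dFPN"][t] - amps["vFPN"][t] for t in bundle.space.ids]
        )
        for v in run.voxel_rois["dFPN"]:
            assert np.corrcoef(vmaps.predictions[v], truth)[0, 1] > 0.8

    def test_requires_voxel_data(self, run_and_bundle):
        run, bundle = run_and_bundle
        obs_run = type(run)(
            roi_timecourses=run.roi_timecourses, motion=run.motion,
            design=run.design, true_block_betas=run.true_block_betas,
        )
        with pytest.raises(ValueError):
            voxelwise_prediction_maps(obs_run, "vFPN", bundle.space)


class TestCompareWithHypothesis:
    def test_equal_maps_give_zero_differences(self, rng):
        ref = rng.normal(size=16)
        maps = [_voxel_maps(np.tile(ref, (6, 1)) + 0.01 * rng.normal(size=(6, 16)),
                            clusters=["c1"] * 3 + ["c2"] * 3)
                for _ in range(5)]
        hyp = {f"t{j}": float(ref[j]) for j in range(16)}
        with pytest.warns(UserWarning):
            mat, ids, res = compare_with_hypothesis(maps, hyp, ref, min_voxels=2)
        # identical references give identically-zero paired differences:
        # nothing testable, nothing rejected
        assert np.all(np.abs(mat) < 1e-12)
        assert np.all(res.corrected_p > 0.05)

    def test_group_aligned_truth_detected(self):
        """Voxel maps built to match the group map and anti-correlate with the
        hypothesized map yield positive, significant paired differences."""
        rng = np.random.default_rng(99)
        detections = 0
        n_rep = 100
        group = rng.normal(size=16)
        hyp_map = {f"t{j}": float(-group[j]) for j in range(16)}
        for _ in range(n_rep):
            maps = [
                _voxel_maps(
                    np.tile(group, (8, 1)) + 0.5 * rng.normal(size=(8, 16)),
                    clusters=["c1"] * 4 + ["c2"] * 4,
                )
                for _ in range(10)
            ]
            mat, ids, res = compare_with_hypothesis(maps, hyp_map, group, min_voxels=2)
            if np.all(mat.mean(axis=0) > 0) and np.any(res.corrected_p <= 0.05):
                detections += 1
        assert detections / n_rep >= 0.95

    def test_paired_permutation_count(self, rng):
        group = rng.normal(size=8)
        maps = [_voxel_maps(np.tile(group, (3, 1)) + rng.normal(size=(3, 8)))
                for _ in range(10)]
        hyp = {f"t{j}": float(rng.normal()) for j in range(8)}
        _, _, res = compare_with_hypothesis(maps, hyp, group, min_voxels=1)
        assert res.n_permutations == 1024
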