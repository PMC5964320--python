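import numpy as np
import pytest
from scipy import stats

from neuroadaptive.synthetic_bold import (
    GroundTruthSurface,
    MotionTrace,
    make_block_design,
    simulate_run,
)
from neuroadaptive.target_measure import (
    Contrast,
    GLMDesign,
    build_incremental_design,
    compute_contrasts,
    contrasts_from_run,
    fit_glm,
    grubbs_exclude,
    kalman_despike,
    scrub_frames,
)
from neuroadaptive.task_space import build_parametric_space


class TestKalmanDespike:
    def test_constant_series_unchanged(self):
        y = np.full(50, 3.2)
        assert np.array_equal(kalman_despike(y), y)

    def test_large_spike_removed(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        y[100] += 10.0
        clean = kalman_despike(y, gate=3.0)
        assert abs(clean[100]) < 3.0

    def test_white_noise_mostly_preserved(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=500)
        clean = kalman_despike(y, gate=3.0)
        assert np.corrcoef(y, clean)[0, 1] >= 0.95

    def test_non_spike_frames_pass_through(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=300)
        clean = kalman_despike(y, gate=3.0)
        changed = clean != y
        assert changed.mean() < 0.05  # only gated frames are touched


class TestIncrementalDesign:
    def test_column_bookkeeping_grows_with_blocks(self):
        tasks = [f"t{i}" for i in range(20)]
        motion = MotionTrace(np.zeros((10 + 620, 6)))
        full = make_block_design("exp1", tasks)
        for k, expected in [(1, 10), (20, 29)]:
            design = full.truncated(k)
            gdes = build_incremental_design(design, motion, design.n_frames)
            assert gdes.matrix.shape[1] == expected
            assert sum(r.startswith("block:") for r in gdes.roles) == k

    def test_frames_must_cover_events(self):
        design = make_block_design("exp1", ["a"])
        motion = MotionTrace(np.zeros((100, 6)))
        with pytest.raises(ValueError):
            build_incremental_design(design, motion, 10)

    def test_zero_motion_design_still_fits(self):
        design = make_block_design("exp1", ["a", "b"])
        motion = MotionTrace(np.zeros((10 + design.n_frames, 6)))
        gdes = build_incremental_design(design, motion, design.n_frames)
        y = gdes.matrix[:, 0] * 2.0 + 1.0
        fit = fit_glm(y, gdes)  # rank-deficient: motion columns are zero
        assert fit.betas[0] == pytest.approx(2.0, abs=1e-8)


class TestFitGLM:
    def test_exact_recovery(self, rng):
        X = rng.normal(size=(60, 5))
        beta0 = rng.normal(size=5)
        gdes = GLMDesign(X, tuple(f"block:{i}:t" for i in range(5)))
        fit = fit_glm(X @ beta0, gdes)
        assert np.allclose(fit.betas, beta0, atol=1e-10)
        assert fit.dof == 55

    def test_orthonormal_design_betas_are_projections(self, rng):
        Q, _ = np.linalg.qr(rng.normal(size=(40, 4)))
        y = rng.normal(size=40)
        fit = fit_glm(y, GLMDesign(Q, ("a", "b", "c", "d")))
        assert np.allclose(fit.betas, Q.T @ y, atol=1e-12)

    def test_against_normal_equations_oracle(self, rng):
        X = rng.normal(size=(60, 8))
        y = rng.normal(size=60)
        fit = fit_glm(y, GLMDesign(X, tuple(f"c{i}" for i in range(8))))
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(fit.betas - oracle)) <= 1e-8


class TestContrasts:
    def _fits(self, betas_by_roi):
        from neuroadaptive.target_measure import GLMFit

        out = {}
        for roi, blocks in betas_by_roi.items():
            roles = tuple(f"block:{i}:t" for i in range(len(blocks)))
            out[roi] = GLMFit(
                betas=np.asarray(blocks, float), residual_variance=0.0,
                dof=0, roles=roles,
            )
        return out

    def test_pairwise_and_one_vs_mean(self, square_space):
        tasks = [square_space["a"]]
        fits = self._fits({"d": [2.0], "v": [1.0], "x": [0.0], "y": [2.0]})
        pair = compute_contrasts(fits, Contrast("d", ("v",)), tasks)
        assert pair[0].value == pytest.approx(1.0)
        ovm = compute_contrasts(fits, Contrast("d", ("v", "x", "y")), tasks)
        assert ovm[0].value == pytest.approx(2.0 - 1.0)

    def test_symmetry_gives_zero(self, square_space):
        fits = self._fits({"d": [1.0], "v": [1.0], "w": [1.0], "u": [1.0]})
        obs = compute_contrasts(fits, Contrast("d", ("v", "w", "u")), [square_space["a"]])
        assert obs[0].value == pytest.approx(0.0)

    def test_mismatched_blocks_rejected(self, square_space):
        fits = self._fits({"d": [1.0, 2.0], "v": [1.0]})
        with pytest.raises(ValueError):
            compute_contrasts(fits, Contrast("d", ("v",)), [square_space["a"]] * 2)


class TestEndToEndExactness:
    def test_noiseless_contrasts_equal_planted_surface(self):
        """GLM on a noiseless simulated run recovers the planted per-block
        contrast exactly (closes the simulator/estimator loop)."""
        space = build_parametric_space((4,), name="tiny")
        amps_d = {t: 1.0 + 0.5 * i for i, t in enumerate(space.ids)}
        amps_v = {t: 0.9 for t in space.ids}
        truth = GroundTruthSurface(
            roi_means={"d": amps_d, "v": amps_v}, noise_sd=0.0, drift_slope=0.01
        )
        blocks = ["L01", "L03", "L00", "L02", "L01"]
        run = simulate_run(space, truth, make_block_design("exp1", blocks), seed=0)
        obs = contrasts_from_run(run, Contrast("d", ("v",)), space)
        for o, tid in zip(obs, blocks):
            assert o.value == pytest.approx(amps_d[tid] - 0.9, abs=1e-8)

    def test_refresh_consistency_on_noiseless_runs(self):
        """Re-estimating after more blocks does not change earlier noiseless
        contrasts (orthogonalized nuisance structure)."""
        space = build_parametric_space((4,), name="tiny")
        truth = GroundTruthSurface(
            roi_means={
                "d": {t: 1.0 + i for i, t in enumerate(space.ids)},
                "v": {t: 1.0 for t in space.ids},
            },
            noise_sd=0.0,
        )
        blocks = ["L00", "L02", "L03"]
        run = simulate_run(space, truth, make_block_design("exp1", blocks), seed=0)
        contrast = Contrast("d", ("v",))
        two = contrasts_from_run(run, contrast, space, n_blocks=2)
        three = contrasts_from_run(run, contrast, space, n_blocks=3)
        for a, b in zip(two, three):
            assert a.value == pytest.approx(b.value, abs=1e-8)


class TestScrubbing:
    def test_threshold_masks(self):
        fd = np.array([0.0, 2.0, 1.4, 1.6])
        assert scrub_frames(fd, 1.5).tolist() == [True, False, True, False]

    def test_all_zero_and_empty(self):
        assert scrub_frames(np.zeros(4)).all()
        assert scrub_frames(np.array([])).size == 0

    def test_infinite_threshold_is_identity(self, rng):
        fd = np.abs(rng.normal(size=30))
        assert scrub_frames(fd, np.inf).all()


class TestGrubbs:
    def test_identical_values_no_outliers(self):
        assert grubbs_exclude([5.0] * 10) == set()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            grubbs_exclude([1.0, 2.0])

    def test_flags_extreme_value_and_matches_critical_value_oracle(self):
        values = [8.0, 8.1, 7.9, 8.2, 20.0]
        out = grubbs_exclude(values, alpha=0.05)
        assert out == {4}
        # closed-form oracle for the first pass
        x = np.asarray(values)
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        n = len(x)
        t_crit = stats.t.ppf(1 - 0.05 / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        assert g > g_crit
        # remaining four are not outliers under the same rule
        assert grubbs_exclude([8.0, 8.1, 7.9, 8.2], alpha=0.05) == set()
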