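import numpy as np
import pytest

from neuroadaptive.synthetic_bold import (
    GroundTruthSurface,
    MotionTrace,
    SyntheticScanner,
    compute_fd,
    convolve_design,
    convolve_events,
    hrf_double_gamma,
    make_block_design,
    simulate_run,
)
from neuroadaptive.task_space import build_parametric_space


class TestBlockDesign:
    def test_exp1_run_duration_matches_protocol(self):
        design = make_block_design("exp1", [f"t{i}" for i in range(20)])
        assert design.total_seconds == 1240.0          # 20.67 min
        assert design.lead_in_frames == 10
        assert design.n_blocks == 20

    def test_exp2_run_duration_matches_protocol(self):
        design = make_block_design("exp2", [f"t{i}" for i in range(20)])
        assert design.total_seconds == 1080.0          # 18 min

    def test_zero_blocks(self):
        design = make_block_design("exp1", [])
        assert design.events == ()
        assert design.total_seconds == 0.0

    def test_unknown_protocol(self):
        with pytest.raises(ValueError):
            make_block_design("exp9", ["t"])

    def test_block_anatomy(self):
        design = make_block_design("exp1", ["a"])
        instr, task = design.events
        assert (instr.duration, instr.role) == (5.0, "nuisance")
        assert (task.onset, task.duration, task.role) == (8.0, 35.0, "task_of_interest")

    def test_truncation_keeps_whole_blocks(self):
        design = make_block_design("exp1", ["a", "b", "c"])
        short = design.truncated(2)
        assert short.n_blocks == 2
        assert short.total_seconds == pytest.approx(124.0)


class TestHRF:
    def test_zero_at_origin_and_peak_near_five_seconds(self):
        t = np.arange(0.0, 32.0, 0.1)
        h = hrf_double_gamma(t)
        assert h[0] == pytest.approx(0.0, abs=1e-12)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.2)
        assert h.max() == pytest.approx(1.0, abs=1e-3)

    def test_small_tail_at_thirty_seconds(self):
        h30 = hrf_double_gamma(np.array([1e-9, 30.0]))[1]
        assert abs(h30) < 0.01

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            hrf_double_gamma(np.array([]))


class TestConvolution:
    def test_zero_duration_event_gives_zero_regressor(self):
        design = make_block_design("exp1", ["a"])
        from neuroadaptive.synthetic_bold import Event

        reg = convolve_events(design, [Event(10.0, 0.0, "x", "nuisance")])
        assert np.allclose(reg, 0.0)

    def test_linearity_in_the_boxcar(self):
        d = make_block_design("exp1", ["a", "b"])
        both = convolve_events(d, d.block_events).sum(axis=1)
        summed = sum(convolve_events(d, [e])[:, 0] for e in d.block_events)
        assert np.allclose(both, summed, atol=1e-12)

    def test_against_brute_force_discrete_convolution(self):
        """Single 35 s block at onset 100 s vs direct summation of shifted HRFs."""
        design = make_block_design("exp1", ["a", "b", "c"])
        ev = design.block_events[1]  # onset 70.0
        dt = 0.1
        reg = convolve_events(design, [ev], dt=dt)[:, 0]
        n_micro = int(np.ceil(design.total_seconds / dt)) + 1
        tt = np.arange(n_micro) * dt
        hrf = hrf_double_gamma(np.arange(0.0, 32.0 + dt, dt))
        box_idx = np.where((tt >= ev.onset) & (tt < ev.onset + ev.duration))[0]
        brute = np.zeros(n_micro)
        for i in box_idx:  # shifted, scaled impulse responses
            end = min(i + hrf.size, n_micro)
            brute[i:end] += hrf[: end - i] * dt
        frame_idx = np.round(np.arange(design.n_frames) * 2.0 / dt).astype(int)
        assert np.allclose(reg, brute[frame_idx], atol=1e-10)

    def test_condition_without_events_is_zero_column(self):
        design = make_block_design("exp1", ["a"])
        cols = convolve_design(design, ["a", "missing"])
        assert cols[:, 1].sum() == 0.0
        assert cols[:, 0].sum() > 0.0


@pytest.fixture(scope="module")
def space():
    return build_parametric_space((4,), name="tiny")


class TestSimulateRun:
    def _truth(self, space, **kw):
        amp = {t: 1.0 + i for i, t in enumerate(space.ids)}
        return GroundTruthSurface(
            roi_means={"roiA": amp, "roiB": {t: 1.0 for t in space.ids}}, **kw
        )

    def test_noiseless_run_equals_model_prediction(self, space):
        truth = self._truth(space, noise_sd=0.0)
        design = make_block_design("exp1", ["L00", "L02"])
        run = simulate_run(space, truth, design, seed=1)
        regs = convolve_events(design, design.block_events)
        lead = design.lead_in_frames
        expected = 1.0 * regs[:, 0] + 3.0 * regs[:, 1]  # 1+i amplitudes
        assert np.allclose(run.roi_timecourses["roiA"][lead:], expected, atol=1e-12)
        assert np.allclose(run.roi_timecourses["roiA"][:lead], 0.0)

    def test_seed_determinism(self, space):
        truth = self._truth(space, noise_sd=1.0, spike_rate=0.01, spike_sd=5.0)
        design = make_block_design("exp1", ["L00", "L01"])
        r1 = simulate_run(space, truth, design, voxels_per_roi=3, seed=7)
        r2 = simulate_run(space, truth, design, voxels_per_roi=3, seed=7)
        for roi in r1.roi_timecourses:
            assert np.array_equal(r1.roi_timecourses[roi], r2.roi_timecourses[roi])
        assert np.array_equal(r1.motion.params, r2.motion.params)
        assert np.array_equal(r1.voxel_data, r2.voxel_data)

    def test_residual_noise_sd_close_to_nominal(self, space):
        truth = self._truth(space, noise_sd=1.0)
        blocks = [space.ids[i % 4] for i in range(20)]
        design = make_block_design("exp1", blocks)
        run = simulate_run(space, truth, design, seed=3)
        quiet = simulate_run(space, self._truth(space, noise_sd=0.0), design, seed=3)
        resid = run.roi_timecourses["roiA"] - quiet.roi_timecourses["roiA"]
        assert np.std(resid) == pytest.approx(1.0, rel=0.1)

    def test_unknown_task_rejected(self, space):
        truth = self._truth(space)
        design = make_block_design("exp1", ["nope"])
        with pytest.raises(KeyError):
            simulate_run(space, truth, design, seed=0)

    def test_true_block_betas_recorded(self, space):
        truth = self._truth(space)
        design = make_block_design("exp1", ["L03", "L00"])
        run = simulate_run(space, truth, design, seed=0)
        assert run.true_block_betas[(0, "roiA")] == 4.0
        assert run.true_block_betas[(1, "roiA")] == 1.0

    def test_scanner_prefix_property(self, space):
        """k-block run is a frame-prefix of the (k+1)-block run."""
        truth = self._truth(space, noise_sd=1.0)
        scanner = SyntheticScanner(space, truth, max_blocks=3, seed=5)
        r2 = scanner.run_for(["L00", "L01"])
        r3 = scanner.run_for(["L00", "L01", "L02"])
        n = r2.n_frames
        assert np.array_equal(
            r2.roi_timecourses["roiB"], r3.roi_timecourses["roiB"][:n]
        )


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert np.all(compute_fd(MotionTrace(np.zeros((5, 6)))) == 0.0)

    def test_constant_offset_invariance(self, rng):
        p = rng.normal(size=(20, 6))
        shifted = p + rng.normal(size=6)
        assert np.allclose(
            compute_fd(MotionTrace(p)), compute_fd(MotionTrace(shifted)), atol=1e-12
        )

    def test_single_jump_formula(self):
        p = np.zeros((6, 6))
        p[3, 0] = 1.0  # transient 1 mm x-excursion at frame 3
        fd = compute_fd(MotionTrace(p))
        assert fd.tolist() == [0.0, 0.0, 0.0, 1.0, 1.0, 0.0]
        step = np.zeros((6, 6))
        step[3:, 0] = 1.0  # persistent step moves only once
        assert compute_fd(MotionTrace(step)).tolist() == [0, 0, 0, 1.0, 0, 0]

    def test_rotation_uses_50mm_arc(self):
        p = np.zeros((2, 6))
        p[1, 4] = 0.01  # rad
        assert compute_fd(MotionTrace(p))[1] == pytest.approx(0.5)
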