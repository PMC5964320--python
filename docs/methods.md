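# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `neuroadaptive` pipeline. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Experiment spaces

A task space is a finite set of runnable tasks embedded in 1D or 2D
coordinates on the unit interval/square.

* **Meta-analytic spaces** place each task at its probability of recruiting
  two network components, `(Pr(compA | task), Pr(compB | task))`. The true
  recruitment probabilities of the 16 tasks are not public, so the package
  ships a *synthetic, plausible* probability table
  (`fixtures.DEFAULT_TASK_TABLE`) and treats it strictly as input. The table
  is written so the prior's pairwise optimum (Wisconsin Card Sorting,
  Counting/Calculation) differs from the planted simulation optimum (Tower
  of London, Deductive Reasoning); a successful closed-loop run must
  overturn the prior, which is the scientific situation the method exists
  for. Raw probabilities are used as coordinates (figures of this design
  suggest raw axes; nothing in the pipeline depends on an affine rescaling
  beyond the kernel lengthscales absorbing it).
* **Parametric spaces** are full-factorial grids of difficulty levels
  normalized linearly onto [0, 1] per dimension, so one lengthscale scale
  applies across spaces.

Candidates are id-sorted at construction; every downstream argmax tie-break
refers to that order, making all analyses deterministic.

## Synthetic BOLD generator

The generator (`synthetic_bold`) stands in for the scanner. Per run:

* **Design.** Blocks follow one of two protocols at TR 2 s: 5 s instruction
  (nuisance) + 3 s rest + 35 s task + 19 s rest (62 s/block; 20 blocks =
  20.67 min), or 30 s problem + 5 s response (nuisance) + 19 s rest
  (54 s/block; 20 blocks = 18 min). Ten lead-in frames model T1
  equilibration and are generated then discarded by all consumers. (The
  15-block variant of the first protocol lasts 15.5 min; the 15.67 min
  sometimes quoted for such runs presumably includes extra setup time — the
  62 s block anatomy is used as-is.)
* **Signal.** ROI signal = Σ_blocks amplitude(roi, task) × block regressor +
  drift·t + σ·N(0,1) + spikes, where the block regressor is the boxcar
  convolved with the canonical double-gamma HRF (peak delay 6 s, undershoot
  delay 16 s, unit dispersions, peak:undershoot 6:1, unit peak) on a 0.1 s
  microtime grid (Riemann-sum convention, sampled at frame onsets;
  discretization error is negligible against all test tolerances).
* **Noise model defaults** (held fixed for all studies; chosen once as
  realistic for ROI-mean timecourses in arbitrary units with amplitudes of
  order 1): frame noise SD 2.0 (per-block beta SNR of a few), drift
  0.003/frame, spike rate 0.005/frame with SD 10 (≈5σ outliers, exercising
  the despiker), motion as smoothed random walks (0.02 mm / 4·10⁻⁴ rad
  steps) with rare ±2.5 mm jumps (rate 0.002) exceeding the 1.5 mm
  framewise-displacement scrub threshold.
* **Voxel data** add independent voxel noise to the parent ROI's clean
  signal; each ROI's voxels are split into two labelled sub-clusters for the
  cluster-level inference stages. There is no spatial autocorrelation beyond
  the shared ROI signal, no k-space physics, and no registration — synthetic
  volumes are written with an identity affine.
* **Determinism.** All noise streams are drawn up front for the maximum run
  length from one seed, so the k-block run is a frame-prefix of the
  (k+1)-block run — exactly what a scanner provides to a closed loop — and
  identical seeds give bit-identical runs.

What passing tests therefore show: the estimator stack is exact, calibrated
and well-behaved *under this generative model*. What they do not show:
robustness to physiological noise spectra (1/f, respiration/cardiac),
spatially structured artifacts, registration error, or hemodynamic
variability across regions and subjects.

## Target measure

The despiker is a local-level Kalman filter with innovation gating: the
observation variance comes from a robust (MAD) scale of first differences,
the level variance equals it (fast adaptation, so block transients are
tracked rather than flagged), and frames whose innovation exceeds
`gate × innovation SD` (gate 3 by default) are replaced by the filtered
prediction; all other frames pass through unchanged. A constant series is
returned unchanged.

The incremental GLM contains one regressor per completed task block, one
pooled regressor per nuisance event class (per-block nuisance columns would
nearly double the design for no identifiable gain), six motion parameters, a
centered linear trend and an intercept. Fits are ordinary least squares; on
rank-deficient designs (e.g. an all-zero motion trace in a degenerate
simulation) the minimum-norm solution is used rather than erroring. After
every block *all* betas are re-estimated and the full refreshed contrast set
is handed to the optimizer (an append-only mode is not provided; refreshing
follows from re-estimation). Scrubbing (FD > 1.5 mm) removes rows from both
data and design and is used only in the offline back-projection stage. Run
exclusion uses the iterative two-sided Grubbs rule at α = 0.05 with the
t-based critical value.

## Surrogate model and acquisition

The GP is zero-mean with squared-exponential ARD kernel and white noise;
posteriors use a Cholesky factorization with an escalating jitter fallback
(10⁻¹⁰ → 10⁻⁶). Type-2 ML tuning maximizes the log marginal likelihood over
log-hyperparameters with multi-restart L-BFGS-B inside data-scaled bounds
(signal and noise SD relative to the response SD; lengthscales 0.05–2 on the
unit-normalized coordinates). In-loop hyperparameters are tuned once on
pilot runs (eight simulated pilot runs with random task sequences, fixed
seeds) and then held fixed, mirroring the real-time design.

Expected improvement uses `z = (m − f_max)/std` — the standard closed form;
a printed variant of this design divides by the *variance*, which is
dimensionally inconsistent with the closed form and is read as a typo. The
degenerate `std = 0` case returns `max(m − f_max, 0)`. The argmax is
restricted to the discrete candidate set (the only runnable tasks), ties
going to the lowest candidate index; `f_max` is either the maximum posterior
mean over candidates (`max_predicted`, the API default) or the maximum
observed contrast (`max_observed`). Burn-in samples five candidates
uniformly *without* replacement (maximizes early coverage).

**Acquisition mode of the packaged fixtures.** With per-block contrast noise
of the size these runs produce, `max_predicted` over-exploits: once a
mediocre task has been sampled, its EI stays `≈ 0.4·std(x*)` while every
alternative's EI is exponentially penalized, and the loop can lock in
(modal-recovery ≈ 0.7 across 200 seeded runs). Benchmarking the incumbent
against the maximum *observed* value restores exploration (recovery 0.95),
which is also the remedy the underlying real-time design adopted when it
observed the same behavior; the packaged fixtures therefore pin
`max_observed`. The flip side, measured by `scripts/acceptance.py`, is that
the explore-to-exploit transition (declining distance between successive
samples) becomes unreliable as a *per-run* signature: when the optimum is
found early, EI spends its late budget confirming unexplored tasks, so the
last-five-step distances are not systematically smaller than the first five
(the decline criterion holds in only ~half of successful runs). Both modes
remain available per run.

## Group analysis

The group map retunes hyperparameters by Type-2 ML on the pooled
observations of all runs and predicts over both the dense grid and the
candidates. Trend tests fit random-intercept-per-subject mixed models by
full ML (fixed effects are compared, so REML is inappropriate): linear
(plus optional second factor and interaction) versus the same plus
`level²` (plus `level²:factor` when the factor is present), compared by a
likelihood-ratio test with df = number of added terms. Difficulty enters as
a continuous covariate. Singular or non-converged fits are reported in the
result dict, never silently dropped.

## Back-projection and permutation inference

Per voxel: scrub, linearly detrend, fit the full-run GLM, contrast block
betas against the reference network's betas (identically preprocessed), fit
a per-voxel GP by Type-2 ML (reduced restart count for speed, configurable),
and predict over the candidates. Similarity to a reference map is Pearson r
across candidates, Fisher-z transformed with |r| clipped at 1 − 10⁻⁷ to keep
z finite and averageable; zero-variance voxel maps are flagged missing.
Cluster summaries drop clusters below the size threshold (200 voxels by
default; synthetic studies pass their own threshold since voxel counts are
small).

The tmax permutation test sign-flips subjects, takes the maximum |t| (or t,
one-tailed) across clusters per assignment, and enumerates all 2ⁿ
assignments when 2ⁿ ≤ 2¹⁶ (Monte-Carlo with a seed otherwise, identity
assignment always included). The corrected p is the rank of the observed
statistic in the null, hence never below 2⁻ⁿ; the critical t is the
(1 − α) null quantile. One-sample tests are two-tailed; the paired
comparison (group map vs hypothesized map similarity) is likewise
two-tailed, matching the paired-test convention. Zero-variance clusters are
excluded with a warning; if nothing is testable an empty no-rejection result
is returned (identically-zero paired differences are a legitimate
degenerate input, not an error).

## Validation studies (sizes and rationale)

All entry points live in `validation` and are shared by the tests, the
acceptance script and the analysis drivers. Problem sizes were chosen as
the smallest that give stable rates on one CPU: EI vs 10⁶-draw Monte-Carlo
per (m, std, f_max) combination; GP vs dense matrix-inverse oracle on
n ≤ 8 problems; noiseless end-to-end exactness at 10⁻⁸; closed-loop
recovery over 200 seeds (success = modal post-burn-in sample in the planted
optimal set); tmax family-wise error over 1000 null replicates of
10 subjects × 5 clusters; mixed-model LRT type-I error over 1000 linear
replicates and power over 200 strongly-quadratic replicates
(curvature ≫ noise); back-projection recovery over 50 seeds in a
strong-signal regime (frame/voxel noise SD 0.5, balanced 16-block runs),
success = mean Fisher-z of target-network voxels above unrelated-network
voxels.

## Known limitations

* The synthetic generator's simplifications listed above; in particular the
  per-block contrast noise is near-white, whereas real-time fMRI contrasts
  carry serial structure from shared nuisance regressors.
* The Kalman despiker is a purpose-built local-level filter meeting the
  stated contract (remove large spikes, leave everything else untouched); it
  is not a reimplementation of any specific published real-time filter.
* Mixed-model LRT p-values use the χ² reference distribution; for very few
  subjects or levels this is approximate.
* Per-voxel GP tuning with few restarts can land in local optima for
  individual voxels; the cluster-level averages used for inference are
  insensitive to this in the validation studies.
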