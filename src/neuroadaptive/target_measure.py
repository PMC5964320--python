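"""The optimizer's objective: per-block network contrasts from an incremental GLM.

After every completed task block the design matrix is rebuilt with one
HRF-convolved regressor per block played so far, pooled nuisance regressors
(instruction/response periods), six motion parameters, a linear trend and an
intercept; all betas are re-estimated on the timecourse observed so far, and
the contrast of a target network's block betas against another network (or
the mean of several) becomes the observation fed to the Bayesian optimizer.

Also houses the run-quality primitives: a local-level Kalman despiker for
large signal spikes, framewise-displacement scrubbing, and the iterative
Grubbs outlier rule used for run exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .synthetic_bold import (
    BlockDesign,
    MotionTrace,
    TASK_ROLE,
    convolve_events,
)
from .task_space import TaskPoint

__all__ = [
    "GLMDesign",
    "GLMFit",
    "Observation",
    "Contrast",
    "kalman_despike",
    "build_incremental_design",
    "fit_glm",
    "compute_contrasts",
    "contrasts_from_run",
    "scrub_frames",
    "grubbs_exclude",
]


@dataclass(frozen=True)
class GLMDesign:
    matrix: np.ndarray            # (frames, regressors)
    roles: tuple[str, ...]        # per-column label

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.roles):
            raise ValueError("matrix/roles mismatch")
        object.__setattr__(self, "matrix", m)

    @property
    def block_columns(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r.startswith("block:")]


@dataclass(frozen=True)
class GLMFit:
    betas: np.ndarray
    residual_variance: float
    dof: int
    roles: tuple[str, ...]

    def block_betas(self) -> np.ndarray:
        return self.betas[[i for i, r in enumerate(self.roles) if r.startswith("block:")]]


@dataclass(frozen=True)
class Observation:
    """One (task, contrast) pair entering the surrogate model."""

    task: TaskPoint
    value: float
    iteration: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("contrast value must be finite")


@dataclass(frozen=True)
class Contrast:
    """Target network versus one other (`pairwise`) or the mean of several."""

    target: str
    others: tuple[str, ...]

    def __post_init__(self) -> None:
        others = tuple(self.others)
        if not others:
            raise ValueError("need at least one comparison ROI")
        if self.target in others:
            raise ValueError("target ROI cannot also be a comparison ROI")
        object.__setattr__(self, "others", others)

    @property
    def rois(self) -> tuple[str, ...]:
        return (self.target, *self.others)


def kalman_despike(series: np.ndarray, gate: float = 3.0) -> np.ndarray:
    """Remove large signal spikes with a gated local-level Kalman filter.

    A random-walk level tracks the slow signal; frames whose innovation
    exceeds `gate` times the innovation SD are treated as spikes and replaced
    by the filtered prediction.  All other frames pass through unchanged.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 frames")
    if gate <= 0:
        raise ValueError("gate must be positive")
    if np.ptp(y) == 0.0:
        return y.copy()
    # observation variance from a robust scale of first differences; the
    # level is allowed to move fast enough to follow block-sized transients
    diffs = np.diff(y)
    sd = np.median(np.abs(diffs - np.median(diffs))) / 0.6745
    if sd == 0.0:
        sd = np.std(diffs) / np.sqrt(2) or 1.0
    r = sd * sd
    q = r  # fast-adapting level: smooth structure is signal, not spike
    out = y.copy()
    level, p = y[0], r
    for t in range(1, y.size):
        p_pred = p + q
        s = p_pred + r
        innov = y[t] - level
        if abs(innov) > gate * np.sqrt(s):
            out[t] = level          # spike: replace with prediction
            obs = level
        else:
            obs = y[t]
        k = p_pred / s
        level = level + k * (obs - level)
        p = (1 - k) * p_pred
    return out


def build_incremental_design(
    design: BlockDesign,
    motion: MotionTrace,
    frames_elapsed: int,
    dt: float = 0.1,
) -> GLMDesign:
    """Design matrix after `frames_elapsed` post-lead-in frames.

    Columns: one regressor per completed task block, one pooled regressor per
    nuisance event class, six motion parameters, a linear trend, an intercept.
    `motion` must cover lead-in + elapsed frames; lead-in frames are excluded.
    """
    lead = design.lead_in_frames
    blocks = design.block_events
    tr = design.tr_seconds
    last_end = max((e.onset + e.duration for e in design.events), default=0.0)
    if frames_elapsed * tr < last_end - 1e-9:
        raise ValueError("frames_elapsed does not cover the design's events")
    if motion.n_frames < lead + frames_elapsed:
        raise ValueError("motion trace shorter than elapsed frames")

    full = convolve_events(design, design.events, dt=dt) if design.events else \
        np.zeros((design.n_frames, 0))
    full = full[:frames_elapsed] if full.shape[0] >= frames_elapsed else np.vstack(
        [full, np.zeros((frames_elapsed - full.shape[0], full.shape[1]))]
    )

    cols: list[np.ndarray] = []
    roles: list[str] = []
    for i, ev in enumerate(design.events):
        if ev.role == TASK_ROLE:
            b = blocks.index(ev)
            cols.append(full[:, i])
            roles.append(f"block:{b}:{ev.condition}")
    nuisance_classes = sorted({e.condition for e in design.events if e.role != TASK_ROLE})
    for cls in nuisance_classes:
        idx = [i for i, e in enumerate(design.events)
               if e.role != TASK_ROLE and e.condition == cls]
        cols.append(full[:, idx].sum(axis=1))
        roles.append(f"nuisance:{cls}")
    mot = motion.params[lead:lead + frames_elapsed]
    for j in range(6):
        cols.append(mot[:, j])
        roles.append(f"motion:{j + 1}")
    t = np.arange(frames_elapsed, dtype=float)
    cols.append(t - t.mean() if frames_elapsed else t)
    roles.append("linear_trend")
    cols.append(np.ones(frames_elapsed))
    roles.append("intercept")
    return GLMDesign(np.column_stack(cols), tuple(roles))


def fit_glm(y: np.ndarray, design: GLMDesign) -> GLMFit:
    """Ordinary least squares; rank-deficient designs get the minimum-norm
    solution so degenerate simulations (e.g. zero motion) remain analyzable."""
    y = np.asarray(y, dtype=float)
    X = design.matrix
    if y.size < 2:
        raise ValueError("need at least 2 frames")
    if y.size != X.shape[0]:
        raise ValueError("frame count mismatch between data and design")
    betas, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ betas
    dof = y.size - int(rank)
    rss = float(resid @ resid)
    return GLMFit(
        betas=betas,
        residual_variance=rss / dof if dof > 0 else 0.0,
        dof=dof,
        roles=design.roles,
    )


def compute_contrasts(
    fits: Mapping[str, GLMFit],
    contrast: Contrast,
    block_tasks: Sequence[TaskPoint],
    iteration: int | None = None,
) -> list[Observation]:
    """Per-block target-vs-comparison beta differences, one Observation each."""
    for roi in contrast.rois:
        if roi not in fits:
            raise KeyError(f"no GLM fit for roi {roi!r}")
    per_roi = {roi: fits[roi].block_betas() for roi in contrast.rois}
    counts = {len(b) for b in per_roi.values()}
    if len(counts) != 1:
        raise ValueError("ROI fits disagree on block count")
    n_blocks = counts.pop()
    if n_blocks != len(block_tasks):
        raise ValueError("block_tasks length does not match fitted blocks")
    other = np.mean([per_roi[r] for r in contrast.others], axis=0)
    values = per_roi[contrast.target] - other
    it = n_blocks if iteration is None else iteration
    return [Observation(task, float(v), it) for task, v in zip(block_tasks, values)]


def contrasts_from_run(
    run,
    contrast: Contrast,
    space,
    n_blocks: int | None = None,
    despike_gate: float | None = None,
) -> list[Observation]:
    """Full target-measure pipeline on a simulated (or recorded) run.

    Optionally despikes each ROI timecourse, builds the incremental design up
    to `n_blocks` completed blocks (default: all), fits each ROI separately
    and returns the per-block contrasts.
    """
    design = run.design if n_blocks is None else run.design.truncated(n_blocks)
    frames = design.n_frames
    lead = design.lead_in_frames
    gdes = build_incremental_design(design, run.motion, frames)
    fits = {}
    for roi in contrast.rois:
        y = np.asarray(run.roi_timecourses[roi], dtype=float)[lead:lead + frames]
        if despike_gate is not None:
            y = kalman_despike(y, gate=despike_gate)
        fits[roi] = fit_glm(y, gdes)
    tasks = [space[e.condition] for e in design.block_events]
    return compute_contrasts(fits, contrast, tasks)


def scrub_frames(fd: np.ndarray, threshold: float = 1.5) -> np.ndarray:
    """Keep-mask over frames: True where FD <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    return fd <= threshold


def grubbs_exclude(values: Sequence[float], alpha: float = 0.05) -> set[int]:
    """Iterative two-sided Grubbs test; returns indices of excluded outliers.

    At each pass the single most extreme value is removed if its Grubbs
    statistic G = max|x - mean|/sd exceeds the t-based critical value at
    `alpha`; repeats until no value is flagged or fewer than 3 remain.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    remaining = list(range(x.size))
    out: set[int] = set()
    while len(remaining) >= 3:
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        g = dev[j] / sd
        n = len(remaining)
        t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        if g > g_crit:
            out.add(remaining.pop(j))
        else:
            break
    return out
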