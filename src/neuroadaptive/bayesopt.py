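"""Closed-loop Bayesian optimization over a discrete task space.

Each iteration: (1) refresh the per-block contrasts for every block played so
far (the incremental GLM re-estimates all betas), (2) condition the GP
surrogate on all (task coordinates, contrast) pairs with fixed, pre-tuned
hyperparameters, (3) pick the next task by maximizing expected improvement
over the candidate set, (4) play the block.  The first `burn_in` tasks are
drawn uniformly at random without replacement.

``f_max`` in the improvement criterion is either the maximum posterior mean
over candidates (`max_predicted`) or the maximum observed contrast
(`max_observed`); the former discounts observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import stats

from .gp import GPHyperparams, GPPosterior, gp_condition
from .target_measure import Contrast, Observation, contrasts_from_run
from .task_space import TaskPoint, TaskSpace

__all__ = [
    "AcquisitionConfig",
    "LoopConfig",
    "RunRecord",
    "expected_improvement",
    "select_next",
    "run_closed_loop",
    "SyntheticSource",
    "ReplaySource",
    "euclidean_distance_trajectory",
    "sampling_frequency",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    f_max_mode: str = "max_predicted"

    def __post_init__(self) -> None:
        if self.f_max_mode not in ("max_predicted", "max_observed"):
            raise ValueError(f"unknown f_max mode {self.f_max_mode!r}")


@dataclass(frozen=True)
class LoopConfig:
    n_iterations: int
    burn_in: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < self.burn_in:
            raise ValueError("n_iterations must be >= burn_in")


@dataclass
class RunRecord:
    """Complete audit trail of one closed-loop run."""

    space_name: str
    burn_in: int
    seed: int
    chosen_ids: list[str] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)  # final refresh
    ei_trace: list[np.ndarray] = field(default_factory=list)       # per guided iter
    f_max_trace: list[float] = field(default_factory=list)
    contrast_history: list[list[float]] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.chosen_ids)

    def to_dict(self) -> dict:
        return {
            "space": self.space_name,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "chosen_ids": list(self.chosen_ids),
            "observations": [
                {"task": o.task.id, "coords": list(o.task.coords),
                 "value": o.value, "iteration": o.iteration}
                for o in self.observations
            ],
            "ei_trace": [list(map(float, e)) for e in self.ei_trace],
            "f_max_trace": [float(f) for f in self.f_max_trace],
            "contrast_history": [list(map(float, c)) for c in self.contrast_history],
        }


def expected_improvement(m, std, f_max) -> np.ndarray | float:
    """Closed-form EI of a Gaussian belief N(m, std^2) over incumbent f_max.

    EI = (m - f_max) Phi(z) + std phi(z) with z = (m - f_max)/std; the
    degenerate std = 0 case is the deterministic improvement max(m - f_max, 0).
    Always nonnegative.
    """
    m = np.asarray(m, dtype=float)
    std = np.asarray(std, dtype=float)
    if np.any(std < 0):
        raise ValueError("std must be >= 0")
    diff = m - f_max
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 0, diff / np.where(std > 0, std, 1.0), 0.0)
        z = np.clip(z, -40.0, 40.0)  # phi/Phi saturate; avoids overflow in z**2
        ei = np.where(
            std > 0,
            diff * stats.norm.cdf(z) + std * stats.norm.pdf(z),
            np.maximum(diff, 0.0),
        )
    ei = np.maximum(ei, 0.0)
    return ei if ei.ndim else float(ei)


def select_next(
    posterior: GPPosterior,
    space: TaskSpace,
    config: AcquisitionConfig,
    observed_y: Sequence[float] | None = None,
) -> tuple[TaskPoint, np.ndarray, float]:
    """Argmax of EI over the candidate set; ties go to the lowest candidate
    index (candidates are id-sorted).  Returns (task, EI values, f_max)."""
    Xc = space.coords
    m, s = posterior.predict(Xc)
    if config.f_max_mode == "max_predicted":
        f_max = float(np.max(m))
    else:
        if observed_y is None or len(observed_y) == 0:
            raise ValueError("max_observed requires at least one observation")
        f_max = float(np.max(observed_y))
    ei = np.asarray(expected_improvement(m, s, f_max))
    return space.candidates[int(np.argmax(ei))], ei, f_max


class ObservationSource(Protocol):
    def observe(self, task: TaskPoint) -> None: ...
    def contrasts(self) -> list[Observation]: ...


class SyntheticSource:
    """Adapter from a `SyntheticScanner` + target-measure pipeline to the loop."""

    def __init__(self, scanner, contrast: Contrast, despike_gate: float | None = 3.0):
        self.scanner = scanner
        self.contrast = contrast
        self.despike_gate = despike_gate
        self._blocks: list[str] = []

    def observe(self, task: TaskPoint) -> None:
        self._blocks.append(task.id)

    def contrasts(self) -> list[Observation]:
        run = self.scanner.run_for(self._blocks)
        return contrasts_from_run(
            run, self.contrast, self.scanner.space, despike_gate=self.despike_gate
        )

    @property
    def run(self):
        return self.scanner.run_for(self._blocks)


class ReplaySource:
    """Replays a recorded sequence of (task id, contrast); the recorded tasks
    override the acquisition's choice so a finished run can be re-analyzed."""

    def __init__(self, space: TaskSpace, sequence: Sequence[tuple[str, float]]):
        self.space = space
        self.sequence = list(sequence)
        self._i = 0

    def forced_task(self, iteration: int) -> TaskPoint:
        if iteration >= len(self.sequence):
            raise IndexError("replay source exhausted")
        return self.space[self.sequence[iteration][0]]

    def observe(self, task: TaskPoint) -> None:
        if self._i >= len(self.sequence):
            raise IndexError("replay source exhausted")
        self._i += 1

    def contrasts(self) -> list[Observation]:
        return [
            Observation(self.space[tid], val, self._i)
            for tid, val in self.sequence[: self._i]
        ]


def run_closed_loop(
    space: TaskSpace,
    source: ObservationSource,
    loop: LoopConfig,
    acq: AcquisitionConfig,
    hyper: GPHyperparams,
) -> RunRecord:
    """Burn-in then guided search; see module docstring for the iteration."""
    rng = np.random.default_rng(loop.seed)
    record = RunRecord(space_name=space.name, burn_in=loop.burn_in, seed=loop.seed)
    forced = getattr(source, "forced_task", None)

    n_burn = min(loop.burn_in, len(space.candidates))
    burn_idx = rng.choice(len(space.candidates), size=n_burn, replace=False)
    obs: list[Observation] = []
    for it in range(loop.n_iterations):
        if it < n_burn:
            task = space.candidates[int(burn_idx[it])]
        else:
            obs = source.contrasts()
            X = np.array([o.task.coords for o in obs])
            y = np.array([o.value for o in obs])
            post = gp_condition(X, y, hyper)
            task, ei, f_max = select_next(post, space, acq, y)
            record.ei_trace.append(ei)
            record.f_max_trace.append(f_max)
            record.contrast_history.append([o.value for o in obs])
        if forced is not None:
            task = forced(it)  # replay: re-analyze a recorded run's choices
        source.observe(task)
        record.chosen_ids.append(task.id)
    record.observations = source.contrasts()
    record.contrast_history.append([o.value for o in record.observations])
    return record


def euclidean_distance_trajectory(record: RunRecord, space: TaskSpace) -> np.ndarray:
    """Distances between successively sampled task-space points; a declining
    trajectory marks the explore-to-exploit transition."""
    if record.n_iterations < 2:
        raise ValueError("need at least 2 observations")
    coords = np.array([space[tid].coords for tid in record.chosen_ids])
    return np.linalg.norm(np.diff(coords, axis=0), axis=1)


def sampling_frequency(
    records: Sequence[RunRecord],
    space: TaskSpace,
    exclude_burn_in: bool = True,
) -> dict[str, float]:
    """Proportion of post-burn-in samples per task, pooled over records."""
    counts = {tid: 0 for tid in space.ids}
    total = 0
    for rec in records:
        start = rec.burn_in if exclude_burn_in else 0
        for tid in rec.chosen_ids[start:]:
            counts[tid] += 1
            total += 1
    if total == 0:
        raise ValueError("no post-burn-in observations")
    return {tid: c / total for tid, c in counts.items()}
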