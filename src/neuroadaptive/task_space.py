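"""Discrete experiment spaces searched by the optimizer.

An experiment space is a small set of runnable cognitive tasks embedded in a
low-dimensional coordinate system.  Two constructions are supported:

* meta-analytic spaces, where each task sits at its probability of recruiting
  two brain-network components, ``(Pr(compA | task), Pr(compB | task))``;
* parametric spaces, where a task family is varied over a factorial grid of
  difficulty parameters, normalized per dimension onto [0, 1].

Coordinates are the GP surrogate's inputs, so every space keeps its candidate
list in a deterministic (id-sorted) order; all downstream argmax tie-breaks
refer to that order.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskPoint",
    "TaskSpace",
    "TaskProbabilityTable",
    "build_metaanalytic_space",
    "build_parametric_space",
    "hypothesized_predictions",
    "prediction_grid",
]


@dataclass(frozen=True)
class TaskPoint:
    """A runnable task at a fixed location in the experiment space."""

    id: str
    coords: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("task id must be nonempty")
        coords = tuple(float(c) for c in self.coords)
        if not all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for task {self.id!r}")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class TaskSpace:
    """An ordered set of candidate tasks with per-dimension bounds."""

    name: str
    dim: int
    candidates: tuple[TaskPoint, ...]
    bounds: tuple[tuple[float, float], ...]
    grid_resolution: int = 50

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError("only 1D and 2D spaces are supported")
        if len(self.candidates) < 2:
            raise ValueError("a task space needs at least 2 candidates")
        if len(self.bounds) != self.dim:
            raise ValueError("one (lo, hi) bound pair per dimension required")
        ids = [c.id for c in self.candidates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate task ids in space")
        ordered = tuple(sorted(self.candidates, key=lambda c: c.id))
        for cand in ordered:
            if len(cand.coords) != self.dim:
                raise ValueError(
                    f"task {cand.id!r} has {len(cand.coords)} coords, space is {self.dim}D"
                )
            for x, (lo, hi) in zip(cand.coords, self.bounds):
                if not (lo <= x <= hi):
                    raise ValueError(f"task {cand.id!r} outside bounds")
        if self.grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")
        object.__setattr__(self, "candidates", ordered)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.candidates]

    @property
    def coords(self) -> np.ndarray:
        """Candidate coordinates as an (n_candidates, dim) array."""
        return np.array([c.coords for c in self.candidates], dtype=float)

    def __getitem__(self, task_id: str) -> TaskPoint:
        for cand in self.candidates:
            if cand.id == task_id:
                return cand
        raise KeyError(task_id)

    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "dim": self.dim,
            "bounds": [list(b) for b in self.bounds],
            "grid_resolution": self.grid_resolution,
            "candidates": [{"id": c.id, "coords": list(c.coords)} for c in self.candidates],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskSpace":
        d = json.loads(text)
        return cls(
            name=d["name"],
            dim=int(d["dim"]),
            candidates=tuple(TaskPoint(c["id"], tuple(c["coords"])) for c in d["candidates"]),
            bounds=tuple((float(lo), float(hi)) for lo, hi in d["bounds"]),
            grid_resolution=int(d["grid_resolution"]),
        )


@dataclass(frozen=True)
class TaskProbabilityTable:
    """Mapping task id -> Pr(component | task) for a fixed set of components.

    The component order is shared across rows; indices into that order select
    the axes of a meta-analytic space and the terms of hypothesized contrasts.
    """

    rows: Mapping[str, tuple[float, ...]]
    component_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        rows = {str(k): tuple(float(p) for p in v) for k, v in self.rows.items()}
        if not rows:
            raise ValueError("empty probability table")
        n_comp = {len(v) for v in rows.values()}
        if len(n_comp) != 1:
            raise ValueError("inconsistent component count across rows")
        for task, probs in rows.items():
            for p in probs:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability outside [0, 1] for task {task!r}")
        names = self.component_names or tuple(f"comp{i}" for i in range(n_comp.pop()))
        if len(names) != len(next(iter(rows.values()))):
            raise ValueError("component_names length mismatch")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "component_names", tuple(names))

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    @classmethod
    def from_csv(cls, path) -> "TaskProbabilityTable":
        df = pd.read_csv(path)
        if df["task_id"].duplicated().any():
            raise ValueError("duplicate task ids in table")
        comp_cols = [c for c in df.columns if c != "task_id"]
        rows = {r.task_id: tuple(float(getattr(r, c)) for c in comp_cols) for r in df.itertuples()}
        return cls(rows=rows, component_names=tuple(comp_cols))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [{"task_id": t, **dict(zip(self.component_names, p))} for t, p in self.rows.items()]
        )
        df.to_csv(path, index=False)


def build_metaanalytic_space(
    table: TaskProbabilityTable,
    component_pair: tuple[int, int],
    name: str = "metaanalytic",
    grid_resolution: int = 50,
) -> TaskSpace:
    """Place every task of `table` at its recruitment probabilities for two components.

    The two chosen component indices become the x and y axes; bounds are the
    unit square.  Identical coordinates for distinct tasks are allowed (the id
    disambiguates).
    """
    ia, ib = component_pair
    n = table.n_components
    if not (0 <= ia < n and 0 <= ib < n):
        raise ValueError("component index out of range")
    if len(table.rows) < 2:
        raise ValueError("need at least 2 tasks")
    cands = tuple(
        TaskPoint(task, (probs[ia], probs[ib])) for task, probs in table.rows.items()
    )
    return TaskSpace(
        name=name,
        dim=2,
        candidates=cands,
        bounds=((0.0, 1.0), (0.0, 1.0)),
        grid_resolution=grid_resolution,
    )


def build_parametric_space(
    levels_per_dim: Sequence[int],
    name: str = "parametric",
    grid_resolution: int = 50,
) -> TaskSpace:
    """Full-factorial grid of difficulty levels, normalized onto [0, 1] per axis.

    ``levels (16,)`` gives 16 points at 0, 1/15, ..., 1 (ids ``L00``..``L15``);
    ``levels (8, 2)`` gives an 8 x 2 grid (ids ``L<i>_C<j>``).
    """
    levels = [int(k) for k in levels_per_dim]
    if any(k < 1 for k in levels):
        raise ValueError("level counts must be positive")
    if int(np.prod(levels)) < 2:
        raise ValueError("need at least 2 candidates in total")
    dim = len(levels)

    def axis(k: int) -> np.ndarray:
        return np.zeros(1) if k == 1 else np.linspace(0.0, 1.0, k)

    cands = []
    for idx in itertools.product(*(range(k) for k in levels)):
        coords = tuple(float(axis(k)[i]) for i, k in zip(idx, levels))
        if dim == 1:
            tid = f"L{idx[0]:02d}"
        else:
            tid = f"L{idx[0]:02d}_" + "_".join(f"C{j}" for j in idx[1:])
        cands.append(TaskPoint(tid, coords))
    return TaskSpace(
        name=name,
        dim=dim,
        candidates=tuple(cands),
        bounds=tuple((0.0, 1.0) for _ in range(dim)),
        grid_resolution=grid_resolution,
    )


def hypothesized_predictions(
    table: TaskProbabilityTable,
    target: int,
    others: Sequence[int],
) -> dict[str, float]:
    """Meta-analysis-derived prediction map over tasks.

    With a single `other` this is the pairwise score
    ``Pr(target | task) - Pr(other | task)``; with several it is
    ``Pr(target | task) - mean_j Pr(other_j | task)``.
    """
    others = list(others)
    if not others:
        raise ValueError("need at least one comparison component")
    if target in others:
        raise ValueError("target must not appear among the comparison components")
    n = table.n_components
    for i in [target, *others]:
        if not (0 <= i < n):
            raise ValueError("component index out of range")
    return {
        task: float(probs[target] - np.mean([probs[j] for j in others]))
        for task, probs in table.rows.items()
    }


def prediction_grid(space: TaskSpace) -> np.ndarray:
    """Regular lattice covering the space bounds, row-major, for dense maps."""
    axes = [np.linspace(lo, hi, space.grid_resolution) for lo, hi in space.bounds]
    if space.dim == 1:
        return axes[0][:, None]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)
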