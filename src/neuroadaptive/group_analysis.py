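"""Group-level synthesis of closed-loop runs.

Two stages mirror the subject-level analyses:

* a group prediction map — one GP conditioned on the pooled observations of
  all runs, hyperparameters retuned by Type-2 maximum likelihood, predicted
  over both the dense grid and the runnable candidates;
* linear-vs-quadratic trend tests on per-subject predictions along a
  parametric axis (difficulty), fit as mixed models with a random intercept
  per subject and compared by likelihood ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .bayesopt import RunRecord
from .gp import GPHyperparams, GPPosterior, gp_condition, tune_hyperparams
from .task_space import TaskSpace, prediction_grid

__all__ = ["GroupPredictionMap", "fit_group_map", "quadratic_trend_test"]


@dataclass(frozen=True)
class GroupPredictionMap:
    grid_coords: np.ndarray
    grid_mean: np.ndarray
    grid_std: np.ndarray
    candidate_ids: tuple[str, ...]
    candidate_mean: np.ndarray
    candidate_std: np.ndarray
    hyper: GPHyperparams

    def candidate_map(self) -> dict[str, float]:
        return dict(zip(self.candidate_ids, map(float, self.candidate_mean)))


def pool_observations(records: Sequence[RunRecord]) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for rec in records:
        for o in rec.observations:
            X.append(o.task.coords)
            y.append(o.value)
    return np.array(X, dtype=float), np.array(y, dtype=float)


def fit_group_map(
    records: Sequence[RunRecord],
    space: TaskSpace,
    restarts: int = 8,
    seed: int = 0,
) -> GroupPredictionMap:
    """GP over all runs' pooled observations with retuned hyperparameters."""
    X, y = pool_observations(records)
    if y.size < 3:
        raise ValueError("need at least 3 pooled observations")
    hyper = tune_hyperparams(X, y, restarts=restarts, seed=seed)
    post: GPPosterior = gp_condition(X, y, hyper)
    grid = prediction_grid(space)
    gm, gs = post.predict(grid)
    cm, cs = post.predict(space.coords)
    return GroupPredictionMap(
        grid_coords=grid, grid_mean=gm, grid_std=gs,
        candidate_ids=tuple(space.ids), candidate_mean=cm, candidate_std=cs,
        hyper=hyper,
    )


def quadratic_trend_test(
    values: np.ndarray,
    levels: np.ndarray,
    second_factor: np.ndarray | None = None,
    interaction: bool = True,
) -> dict:
    """Likelihood-ratio test for curvature in subject-level predictions.

    `values` is (subjects, conditions); `levels` gives each condition's
    continuous difficulty coordinate (and `second_factor` an optional binary
    covariate, e.g. a convolution flag).  Both models have a per-subject
    random intercept and are fit by full ML (fixed effects are compared);
    the quadratic model adds `level^2` (plus its interaction with the second
    factor when requested), so the LRT df equals the number of added terms.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels, dtype=float)
    n_sub, n_cond = values.shape
    if n_sub < 3 or len(np.unique(levels)) < 4:
        raise ValueError("need >= 3 subjects and >= 4 distinct levels")
    rows = []
    for s in range(n_sub):
        for c in range(n_cond):
            row = {"subject": s, "level": levels[c], "value": values[s, c]}
            if second_factor is not None:
                row["factor"] = float(second_factor[c])
            rows.append(row)
    df = pd.DataFrame(rows)

    base = "value ~ level"
    quad_terms = ["I(level**2)"]
    if second_factor is not None:
        base += " + factor"
        if interaction:
            base += " + level:factor"
            quad_terms.append("I(level**2):factor")
    full = base + " + " + " + ".join(quad_terms)

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit0 = smf.mixedlm(base, df, groups=df["subject"]).fit(reml=False)
            fit1 = smf.mixedlm(full, df, groups=df["subject"]).fit(reml=False)
            converged = bool(fit0.converged and fit1.converged)
        except Exception as err:
            return {"lrt": np.nan, "df": len(quad_terms), "p": np.nan,
                    "converged": False, "error": str(err)}
    lrt = max(2.0 * (fit1.llf - fit0.llf), 0.0)
    dof = len(quad_terms)
    return {
        "lrt": float(lrt),
        "df": dof,
        "p": float(stats.chi2.sf(lrt, dof)),
        "converged": converged,
    }
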