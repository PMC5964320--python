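"""Gaussian-process surrogate: squared-exponential kernel, exact posterior,
marginal likelihood and Type-2 maximum-likelihood hyperparameter tuning.

The model is a zero-mean GP over task-space coordinates with an ARD
squared-exponential covariance

    k(x, y) = sigma^2 exp(-1/2 sum_d ((x_d - y_d) / l_d)^2)

and i.i.d. Gaussian observation noise of SD `noise_sd`.  With no data the
posterior is the prior (mean 0, SD sigma).  Factorizations use a Cholesky
with an escalating jitter fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GPHyperparams",
    "GPPosterior",
    "se_kernel",
    "se_kernel_matrix",
    "gp_condition",
    "log_marginal_likelihood",
    "tune_hyperparams",
]

_JITTERS = (1e-10, 1e-8, 1e-6)


@dataclass(frozen=True)
class GPHyperparams:
    """Signal SD, per-dimension lengthscales, observation-noise SD."""

    signal_sd: float
    lengthscales: tuple[float, ...]
    noise_sd: float

    def __post_init__(self) -> None:
        ls = tuple(float(l) for l in np.atleast_1d(self.lengthscales))
        vals = (self.signal_sd, *ls, self.noise_sd)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("all GP hyperparameters must be finite and > 0")
        object.__setattr__(self, "lengthscales", ls)

    @property
    def dim(self) -> int:
        return len(self.lengthscales)


def se_kernel(x: np.ndarray, y: np.ndarray, hyper: GPHyperparams) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ls = np.asarray(hyper.lengthscales)
    if x.shape != y.shape or x.size != ls.size:
        raise ValueError("dimension mismatch between points and lengthscales")
    z = (x - y) / ls
    return float(hyper.signal_sd**2 * np.exp(-0.5 * np.dot(z, z)))


def se_kernel_matrix(X: np.ndarray, Y: np.ndarray, hyper: GPHyperparams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ls = np.asarray(hyper.lengthscales)
    if X.shape[1] != ls.size or Y.shape[1] != ls.size:
        raise ValueError("dimension mismatch between points and lengthscales")
    d2 = np.sum(((X[:, None, :] - Y[None, :, :]) / ls) ** 2, axis=-1)
    return hyper.signal_sd**2 * np.exp(-0.5 * d2)


def _chol_with_jitter(K: np.ndarray) -> np.ndarray:
    last = None
    for jit in _JITTERS:
        try:
            return linalg.cholesky(K + jit * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError as err:  # pragma: no cover - pathological
            last = err
    raise linalg.LinAlgError(f"covariance not positive definite after jitter: {last}")


class GPPosterior:
    """Exact GP posterior; prior when conditioned on no data."""

    def __init__(self, X: np.ndarray, y: np.ndarray, hyper: GPHyperparams) -> None:
        X = np.atleast_2d(np.asarray(X, dtype=float)) if np.size(X) else \
            np.empty((0, hyper.dim))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on n")
        if y.size and not np.all(np.isfinite(y)):
            raise ValueError("non-finite observations")
        self.X, self.y, self.hyper = X, y, hyper
        if y.size:
            K = se_kernel_matrix(X, X, hyper) + hyper.noise_sd**2 * np.eye(y.size)
            self._L = _chol_with_jitter(K)
            self._alpha = linalg.cho_solve((self._L, True), y)
        else:
            self._L = self._alpha = None

    @property
    def n(self) -> int:
        return self.y.size

    def predict(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and SD of the latent function at `Xs`."""
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        if self.n == 0:
            m = np.zeros(Xs.shape[0])
            return m, np.full(Xs.shape[0], self.hyper.signal_sd)
        Ks = se_kernel_matrix(Xs, self.X, self.hyper)
        mean = Ks @ self._alpha
        v = linalg.solve_triangular(self._L, Ks.T, lower=True)
        var = self.hyper.signal_sd**2 - np.sum(v * v, axis=0)
        return mean, np.sqrt(np.clip(var, 0.0, None))

    def mean(self, Xs: np.ndarray) -> np.ndarray:
        return self.predict(Xs)[0]

    def std(self, Xs: np.ndarray) -> np.ndarray:
        return self.predict(Xs)[1]


def gp_condition(X: np.ndarray, y: np.ndarray, hyper: GPHyperparams) -> GPPosterior:
    return GPPosterior(X, y, hyper)


def log_marginal_likelihood(X: np.ndarray, y: np.ndarray, hyper: GPHyperparams) -> float:
    """Log evidence of y under N(0, K + noise_sd^2 I)."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("need at least one observation")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = se_kernel_matrix(X, X, hyper) + hyper.noise_sd**2 * np.eye(y.size)
    L = _chol_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * y.size * np.log(2 * np.pi)
    )


def default_bounds(y: np.ndarray, dim: int) -> dict[str, tuple[float, float]]:
    """Data-scaled box for Type-2 ML: SDs relative to the response scale,
    lengthscales relative to the unit-normalized coordinate axes."""
    scale = float(np.std(np.asarray(y, dtype=float))) or 1.0
    return {
        "signal_sd": (0.05 * scale, 20.0 * scale),
        "lengthscale": (0.05, 2.0),
        "noise_sd": (0.02 * scale, 5.0 * scale),
    }


def tune_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    bounds: dict[str, tuple[float, float]] | None = None,
    restarts: int = 8,
    seed: int = 0,
) -> GPHyperparams:
    """Type-2 maximum likelihood: multi-restart bounded L-BFGS-B on the log
    hyperparameters.  Returns the best restart's optimum."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations to tune")
    dim = X.shape[1]
    b = bounds or default_bounds(y, dim)
    lo = np.log([b["signal_sd"][0]] + [b["lengthscale"][0]] * dim + [b["noise_sd"][0]])
    hi = np.log([b["signal_sd"][1]] + [b["lengthscale"][1]] * dim + [b["noise_sd"][1]])

    def unpack(theta: np.ndarray) -> GPHyperparams:
        p = np.exp(theta)
        return GPHyperparams(p[0], tuple(p[1:1 + dim]), p[1 + dim])

    def neg_lml(theta: np.ndarray) -> float:
        try:
            return -log_marginal_likelihood(X, y, unpack(theta))
        except linalg.LinAlgError:
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += [rng.uniform(lo, hi) for _ in range(max(restarts - 1, 0))]
    best, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            neg_lml, x0, method="L-BFGS-B", bounds=list(zip(lo, hi))
        )
        val = min(res.fun, neg_lml(res.x))
        if np.isfinite(val) and val < best_val:
            best, best_val = res.x, val
    if best is None:
        raise RuntimeError("all hyperparameter restarts failed")
    return unpack(best)
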