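"""Post-hoc voxel-wise back-projection and permutation inference.

The subject-level pipeline is repeated per voxel: scrub high-motion frames,
detrend, fit the full-run GLM, contrast each voxel's block betas against the
reference network's betas, and feed the contrasts into a per-voxel GP
(Type-2 ML hyperparameters) to predict over the candidate tasks.  Voxel
prediction maps are then correlated (Pearson r, Fisher z) with a reference
map — the group-level predictions or the meta-analytic hypothesis — and
summarized per anatomical cluster.  Group inference on cluster means uses
sign-flip permutation with the tmax method: the null is the distribution of
the maximum |t| across clusters, which controls family-wise error; with 10
subjects the 2^10 sign assignments are enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .gp import gp_condition, tune_hyperparams
from .synthetic_bold import SimulatedRun, compute_fd
from .target_measure import build_incremental_design, fit_glm, scrub_frames
from .task_space import TaskSpace

__all__ = [
    "SimilarityMap",
    "PermutationResult",
    "voxelwise_prediction_maps",
    "spatial_similarity",
    "cluster_summaries",
    "tmax_permutation",
    "compare_with_hypothesis",
]

R_CLIP = 1.0 - 1e-7
EXHAUSTIVE_LIMIT = 2**16


@dataclass(frozen=True)
class SimilarityMap:
    r: np.ndarray            # per-voxel Pearson r; NaN where undefined
    z: np.ndarray            # Fisher z with |r| clipped at 1 - 1e-7
    valid: np.ndarray        # False where the voxel map had zero variance


@dataclass(frozen=True)
class PermutationResult:
    cluster_ids: tuple[str, ...]
    observed_t: np.ndarray
    critical_t: float
    corrected_p: np.ndarray
    n_permutations: int
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class VoxelMaps:
    """Per-voxel GP predictions over the candidate tasks."""

    predictions: np.ndarray          # (n_voxels, n_candidates)
    candidate_ids: tuple[str, ...]
    voxel_clusters: tuple[str, ...]
    noise_sd: np.ndarray             # fitted per-voxel GP noise SD


def voxelwise_prediction_maps(
    run: SimulatedRun,
    reference_roi: str,
    space: TaskSpace,
    fd_threshold: float = 1.5,
    restarts: int = 3,
    seed: int = 0,
) -> VoxelMaps:
    """Back-project the optimizer's model onto every voxel.

    Contrasts each voxel's per-block betas against `reference_roi`'s betas
    (computed on identically preprocessed data) and fits a per-voxel GP.
    """
    if run.voxel_data is None:
        raise ValueError("run carries no voxel data")
    design = run.design
    lead = design.lead_in_frames
    frames = design.n_frames
    keep = scrub_frames(compute_fd(run.motion), fd_threshold)[lead:lead + frames]
    if not keep.any():
        raise ValueError("all frames scrubbed")
    gdes = build_incremental_design(design, run.motion, frames)
    X = gdes.matrix[keep]
    t = np.arange(frames, dtype=float)[keep]

    def detrend(y: np.ndarray) -> np.ndarray:
        A = np.column_stack([t - t.mean(), np.ones_like(t)])
        return y - A @ np.linalg.lstsq(A, y, rcond=None)[0]

    from .target_measure import GLMDesign  # local: rebuild with scrubbed rows
    sdes = GLMDesign(X, gdes.roles)
    ref = np.asarray(run.roi_timecourses[reference_roi], dtype=float)[lead:lead + frames][keep]
    ref_betas = fit_glm(detrend(ref), sdes).block_betas()

    coords = np.array([space[e.condition].coords for e in design.block_events])
    Xc = space.coords
    n_vox = run.voxel_data.shape[0]
    preds = np.empty((n_vox, Xc.shape[0]))
    noise = np.empty(n_vox)
    for v in range(n_vox):
        y = run.voxel_data[v, lead:lead + frames][keep]
        betas = fit_glm(detrend(y), sdes).block_betas()
        contrasts = betas - ref_betas
        hyper = tune_hyperparams(coords, contrasts, restarts=restarts, seed=seed)
        post = gp_condition(coords, contrasts, hyper)
        preds[v] = post.mean(Xc)
        noise[v] = hyper.noise_sd
    return VoxelMaps(
        predictions=preds,
        candidate_ids=tuple(space.ids),
        voxel_clusters=run.voxel_clusters or tuple("" for _ in range(n_vox)),
        noise_sd=noise,
    )


def spatial_similarity(voxel_maps: VoxelMaps, reference_map: np.ndarray) -> SimilarityMap:
    """Pearson r of each voxel's candidate predictions against a reference
    map over the same candidates, Fisher z-transformed (r clipped to keep z
    finite).  Zero-variance voxels are flagged invalid."""
    ref = np.asarray(reference_map, dtype=float)
    P = voxel_maps.predictions
    if ref.size != P.shape[1] or ref.size < 3:
        raise ValueError("reference map must cover >= 3 candidates")
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0.0:
        raise ValueError("reference map has zero variance")
    Pc = P - P.mean(axis=1, keepdims=True)
    ss = np.sum(Pc * Pc, axis=1)
    valid = ss > 0
    r = np.full(P.shape[0], np.nan)
    r[valid] = (Pc[valid] @ ref_c) / np.sqrt(ss[valid] * ref_ss)
    z = np.full_like(r, np.nan)
    z[valid] = np.arctanh(np.clip(r[valid], -R_CLIP, R_CLIP))
    return SimilarityMap(r=r, z=z, valid=valid)


def cluster_summaries(
    z_maps: np.ndarray,
    voxel_clusters: Sequence[str],
    min_voxels: int = 200,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Mean Fisher z per surviving cluster per subject.

    `z_maps` is (subjects, voxels); clusters with fewer than `min_voxels`
    voxels are dropped.  Returns (subjects x clusters matrix, cluster ids).
    """
    Z = np.atleast_2d(np.asarray(z_maps, dtype=float))
    labels = np.asarray(voxel_clusters)
    if Z.shape[1] != labels.size:
        raise ValueError("z map / cluster label length mismatch")
    ids = sorted({l for l in labels if l})
    kept = [cid for cid in ids if np.sum(labels == cid) >= min_voxels]
    if not kept:
        raise ValueError("no cluster survives the size threshold")
    out = np.column_stack([
        np.nanmean(Z[:, labels == cid], axis=1) for cid in kept
    ])
    return out, tuple(kept)


def _sign_matrix(n: int, exhaustive: bool, n_permutations: int, seed: int | None) -> np.ndarray:
    if exhaustive:
        return np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    rng = np.random.default_rng(seed)
    S = rng.choice([1.0, -1.0], size=(n_permutations, n))
    S[0] = 1.0  # identity assignment always in the null
    return S


def tmax_permutation(
    data: np.ndarray,
    cluster_ids: Sequence[str] | None = None,
    test: str = "one_sample",
    alpha: float = 0.05,
    exhaustive: bool | None = None,
    n_permutations: int = 10000,
    seed: int | None = 0,
    two_tailed: bool = True,
) -> PermutationResult:
    """Sign-flip permutation test with max-statistic FWER correction.

    `data` is (subjects, clusters); for `test='paired'` pass the per-subject
    difference matrix.  The null distribution is the maximum of |t| (or t)
    over clusters across sign assignments; exhaustive enumeration (2^n) is
    used whenever feasible, otherwise seeded Monte-Carlo.  Corrected p is the
    rank of the observed statistic in the null, so p >= 2^-n always.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if test not in ("one_sample", "paired"):
        raise ValueError(f"unknown test {test!r}")
    ids = tuple(cluster_ids) if cluster_ids is not None else tuple(
        f"cluster{j}" for j in range(k)
    )

    var_ok = X.var(axis=0, ddof=1) > 0
    excluded = tuple(cid for cid, ok in zip(ids, var_ok) if not ok)
    if excluded:
        warnings.warn(f"zero-variance clusters excluded: {excluded}")
    X = X[:, var_ok]
    ids = tuple(cid for cid, ok in zip(ids, var_ok) if ok)
    if X.shape[1] == 0:
        # fully degenerate input (e.g. identically-zero paired differences):
        # nothing is testable and nothing is rejected
        return PermutationResult(
            cluster_ids=(), observed_t=np.array([]), critical_t=np.inf,
            corrected_p=np.array([]), n_permutations=0, excluded=excluded,
        )

    if exhaustive is None:
        exhaustive = 2**n <= EXHAUSTIVE_LIMIT
    S = _sign_matrix(n, exhaustive, n_permutations, seed)
    n_perm = S.shape[0]

    sumsq = np.sum(X * X, axis=0)                      # invariant to sign flips
    means = (S @ X) / n                                # (n_perm, clusters)
    var = (sumsq[None, :] - n * means**2) / (n - 1)
    var = np.clip(var, 1e-300, None)
    T = means / np.sqrt(var / n)
    null = np.max(np.abs(T) if two_tailed else T, axis=1)

    t_obs = T[0]                                       # first row is the identity
    stat_obs = np.abs(t_obs) if two_tailed else t_obs
    corrected_p = np.array([
        float(np.mean(null >= s - 1e-12)) for s in stat_obs
    ])
    critical_t = float(np.quantile(null, 1.0 - alpha))
    return PermutationResult(
        cluster_ids=ids,
        observed_t=t_obs,
        critical_t=critical_t,
        corrected_p=corrected_p,
        n_permutations=n_perm,
        excluded=excluded,
    )


def compare_with_hypothesis(
    subject_voxel_maps: Sequence[VoxelMaps],
    hypothesized_scores: Mapping[str, float],
    group_map: np.ndarray,
    min_voxels: int = 200,
    alpha: float = 0.05,
) -> tuple[np.ndarray, tuple[str, ...], PermutationResult]:
    """Do voxels resemble the obtained group map more than the hypothesis?

    Per subject and voxel, two similarity values (vs the group-level map and
    vs the meta-analytic prediction map) are Fisher-z transformed; their
    per-cluster mean difference (group - hypothesis) enters a paired
    two-tailed tmax permutation test.
    """
    diffs = []
    clusters = None
    for vm in subject_voxel_maps:
        hyp = np.array([hypothesized_scores[t] for t in vm.candidate_ids])
        z_group = spatial_similarity(vm, group_map).z
        z_hyp = spatial_similarity(vm, hyp).z
        diffs.append(z_group - z_hyp)
        clusters = vm.voxel_clusters
    D = np.vstack(diffs)
    mat, ids = cluster_summaries(D, clusters, min_voxels=min_voxels)
    res = tmax_permutation(mat, ids, test="paired", alpha=alpha)
    return mat, ids, res
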