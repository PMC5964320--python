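"""Human-readable summaries of closed-loop runs and analysis maps."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np

from .bayesopt import RunRecord, euclidean_distance_trajectory, sampling_frequency
from .synthetic_bold import SimulatedRun
from .task_space import TaskSpace

__all__ = ["report", "save_voxels_nifti", "save_run_tables"]


def save_voxels_nifti(run: SimulatedRun, outdir) -> tuple[Path, Path]:
    """Write the run's voxel data as a 4D NIfTI plus an integer-labeled ROI
    mask volume (voxels arranged on a flat grid; identity affine — synthetic
    volumes carry no anatomical registration)."""
    if run.voxel_data is None:
        raise ValueError("run carries no voxel data")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    n_vox, n_frames = run.voxel_data.shape
    nx = int(np.ceil(np.sqrt(n_vox)))
    ny = int(np.ceil(n_vox / nx))
    vol = np.zeros((nx, ny, 1, n_frames), dtype=np.float32)
    mask = np.zeros((nx, ny, 1), dtype=np.int16)
    for label, roi in enumerate(sorted(run.voxel_rois), start=1):
        for v in run.voxel_rois[roi]:
            i, j = divmod(int(v), ny)
            vol[i, j, 0, :] = run.voxel_data[v]
            mask[i, j, 0] = label
    affine = np.eye(4)
    data_path = out / "voxels.nii"
    mask_path = out / "roi_mask.nii"
    nib.save(nib.Nifti1Image(vol, affine), data_path)
    nib.save(nib.Nifti1Image(mask, affine), mask_path)
    return data_path, mask_path


def save_run_tables(run: SimulatedRun, outdir) -> None:
    """ROI timecourses (`frame, roi, value`), motion parameters and the block
    design as plain-text artifacts."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"frame": f, "roi": roi, "value": float(v)}
        for roi in run.rois
        for f, v in enumerate(run.roi_timecourses[roi])
    ]
    pd.DataFrame(rows).to_csv(out / "roi_timecourses.csv", index=False)
    pd.DataFrame(
        run.motion.params,
        columns=["trans_x_mm", "trans_y_mm", "trans_z_mm",
                 "rot_x_rad", "rot_y_rad", "rot_z_rad"],
    ).to_csv(out / "motion.csv", index=False)
    design = {
        "tr_seconds": run.design.tr_seconds,
        "lead_in_frames": run.design.lead_in_frames,
        "total_seconds": run.design.total_seconds,
        "events": [
            {"onset": e.onset, "duration": e.duration,
             "condition": e.condition, "role": e.role}
            for e in run.design.events
        ],
    }
    (out / "design.json").write_text(json.dumps(design, indent=2))


def _prediction_figure(space: TaskSpace, group_map, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    if space.dim == 2:
        res = space.grid_resolution
        img = group_map.grid_mean.reshape(res, res)
        (x0, x1), (y0, y1) = space.bounds
        im = ax.imshow(img.T, origin="lower", extent=(x0, x1, y0, y1), aspect="auto",
                       cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="predicted contrast")
        xs = space.coords
        ax.scatter(xs[:, 0], xs[:, 1], c="k", s=12)
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
    else:
        ax.plot(group_map.grid_coords[:, 0], group_map.grid_mean, "-", color="C0")
        ax.fill_between(
            group_map.grid_coords[:, 0],
            group_map.grid_mean - group_map.grid_std,
            group_map.grid_mean + group_map.grid_std,
            alpha=0.3, color="C0",
        )
        ax.set_xlabel("difficulty (normalized)")
        ax.set_ylabel("predicted contrast")
    ax.set_title("group-level GP predictions")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(
    records: Sequence[RunRecord],
    space: TaskSpace,
    outdir,
    group_map=None,
    permutation=None,
) -> dict:
    """Write a JSON summary (+ figures) of one or more closed-loop runs.

    The summary carries the pooled post-burn-in sampling frequencies, the
    mean +/- SD Euclidean-distance trajectory, and — when provided — the
    group prediction map and permutation-test table.
    """
    if not records:
        raise ValueError("no run records to report")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    freqs = sampling_frequency(records, space, exclude_burn_in=True)
    eds = [euclidean_distance_trajectory(r, space) for r in records if r.n_iterations >= 2]
    ed_matrix = np.array([e for e in eds if e.size == eds[0].size]) if eds else np.empty((0, 0))
    summary: dict = {
        "n_records": len(records),
        "seeds": [r.seed for r in records],
        "sampling_frequency": freqs,
        "modal_task": max(freqs, key=freqs.get),
        "ed_mean": ed_matrix.mean(axis=0).tolist() if ed_matrix.size else [],
        "ed_sd": ed_matrix.std(axis=0).tolist() if ed_matrix.size else [],
    }
    if group_map is not None:
        summary["group_predictions"] = group_map.candidate_map()
        summary["group_hyperparams"] = {
            "signal_sd": group_map.hyper.signal_sd,
            "lengthscales": list(group_map.hyper.lengthscales),
            "noise_sd": group_map.hyper.noise_sd,
        }
        _prediction_figure(space, group_map, out / "group_predictions.png")
    if permutation is not None:
        summary["permutation"] = {
            "clusters": list(permutation.cluster_ids),
            "observed_t": [float(t) for t in permutation.observed_t],
            "critical_t": permutation.critical_t,
            "corrected_p": [float(p) for p in permutation.corrected_p],
            "n_permutations": permutation.n_permutations,
        }

    fig, ax = plt.subplots(figsize=(6, 3))
    names = list(freqs)
    ax.bar(range(len(names)), [freqs[t] for t in names])
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=90, fontsize=6)
    ax.set_ylabel("sampling proportion")
    ax.set_title("post-burn-in sampling frequency")
    fig.tight_layout()
    fig.savefig(out / "sampling_frequency.png", dpi=120)
    plt.close(fig)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
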