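"""Synthetic block-design BOLD generator.

Stands in for the scanner in the closed loop: given a task space and a
ground-truth activation surface per region of interest (ROI), it produces
per-ROI (and optionally per-voxel) timecourses at TR = 2 s containing

* HRF-convolved block responses with known per-block amplitudes,
* white observation noise and a linear drift,
* occasional large additive signal spikes (to exercise the despiker),
* a smooth random-walk six-parameter motion trace with rare large jumps
  (to exercise framewise-displacement scrubbing), and
* a 10-frame T1-equilibration lead-in that consumers discard.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "Event",
    "BlockDesign",
    "GroundTruthSurface",
    "MotionTrace",
    "SimulatedRun",
    "make_block_design",
    "hrf_double_gamma",
    "convolve_events",
    "convolve_design",
    "simulate_run",
    "compute_fd",
    "SyntheticScanner",
    "PROTOCOLS",
]

TASK_ROLE = "task_of_interest"
NUISANCE_ROLE = "nuisance"

# Per-protocol block anatomy (seconds). exp1/exp3: 5 s instruction + 3 s rest
# + 35 s task + 19 s rest = 62 s. exp2: 30 s problem + 5 s response + 19 s
# rest = 54 s. 20 blocks therefore last 1240 s (20.67 min) and 1080 s (18 min).
PROTOCOLS = {
    "exp1": {"segments": [(5.0, "instruction", NUISANCE_ROLE), (3.0, None, None),
                          (35.0, "__task__", TASK_ROLE), (19.0, None, None)]},
    "exp2": {"segments": [(30.0, "__task__", TASK_ROLE), (5.0, "response", NUISANCE_ROLE),
                          (19.0, None, None)]},
}
PROTOCOLS["exp3"] = PROTOCOLS["exp1"]

LEAD_IN_FRAMES = 10


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    condition: str
    role: str


@dataclass(frozen=True)
class BlockDesign:
    """Timing of one run: ordered events plus the discarded lead-in."""

    tr_seconds: float
    events: tuple[Event, ...]
    lead_in_frames: int
    total_seconds: float

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("event onsets must be nondecreasing")
        blocks = self.block_events
        for a, b in zip(blocks, blocks[1:]):
            if b.onset < a.onset + a.duration:
                raise ValueError("task blocks must not overlap")

    @property
    def block_events(self) -> list[Event]:
        return [e for e in self.events if e.role == TASK_ROLE]

    @property
    def n_blocks(self) -> int:
        return len(self.block_events)

    @property
    def n_frames(self) -> int:
        """Frames after the lead-in."""
        return int(round(self.total_seconds / self.tr_seconds))

    def truncated(self, n_blocks: int) -> "BlockDesign":
        """Design of the first `n_blocks` blocks (full block periods)."""
        if n_blocks > self.n_blocks:
            raise ValueError("cannot truncate to more blocks than present")
        if n_blocks == self.n_blocks:
            return self
        # protocol runs are uniform block periods, so the k-block prefix ends
        # at k/n of the total duration (task + nuisance + rest all included)
        cut = self.total_seconds * n_blocks / self.n_blocks
        kept = tuple(e for e in self.events if e.onset < cut - 1e-9)
        return BlockDesign(self.tr_seconds, kept, self.lead_in_frames, float(cut))


@dataclass(frozen=True)
class GroundTruthSurface:
    """Latent task -> activation mapping plus the run's noise model."""

    roi_means: Mapping[str, Mapping[str, float]]
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    spike_rate: float = 0.0
    spike_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(
            self,
            "roi_means",
            {str(r): {str(t): float(a) for t, a in m.items()} for r, m in self.roi_means.items()},
        )

    @property
    def rois(self) -> list[str]:
        return sorted(self.roi_means)


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body parameters per frame: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("motion trace must be (frames, 6)")
        object.__setattr__(self, "params", p)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class SimulatedRun:
    roi_timecourses: Mapping[str, np.ndarray]
    motion: MotionTrace
    design: BlockDesign
    true_block_betas: Mapping[tuple[int, str], float]
    voxel_data: np.ndarray | None = None          # (n_voxels, frames)
    voxel_rois: Mapping[str, np.ndarray] | None = None   # roi -> voxel indices
    voxel_clusters: tuple[str, ...] | None = None        # per-voxel sub-cluster label

    @property
    def n_frames(self) -> int:
        return self.motion.n_frames

    @property
    def rois(self) -> list[str]:
        return sorted(self.roi_timecourses)


def make_block_design(
    protocol: str,
    block_conditions: Sequence[str],
    tr_seconds: float = 2.0,
) -> BlockDesign:
    """Lay out a run of task blocks under one of the three protocols.

    Onset 0 is the first frame *after* the 10-TR equilibration lead-in; the
    lead-in is carried on the design so simulators can prepend it.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    segments = PROTOCOLS[protocol]["segments"]
    events: list[Event] = []
    t = 0.0
    for cond in block_conditions:
        for dur, label, role in segments:
            if label is not None:
                name = str(cond) if label == "__task__" else label
                events.append(Event(t, dur, name, role))
            t += dur
    return BlockDesign(
        tr_seconds=tr_seconds,
        events=tuple(events),
        lead_in_frames=LEAD_IN_FRAMES,
        total_seconds=t,
    )


@lru_cache(maxsize=8)
def _hrf_peak(peak_delay: float, under_delay: float, peak_disp: float,
              under_disp: float, ratio: float) -> float:
    t = np.arange(0.0, 32.0, 1e-3)
    raw = (gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
           - gamma_dist.pdf(t, under_delay / under_disp, scale=under_disp) / ratio)
    return float(raw.max())


def hrf_double_gamma(
    time_grid: np.ndarray,
    peak_delay: float = 6.0,
    under_delay: float = 16.0,
    peak_disp: float = 1.0,
    under_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, scaled to unit peak.

    Difference of two gamma densities: a positive lobe peaking near 5 s and a
    shallow undershoot near 15 s, the standard fMRI response kernel.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be nonnegative and strictly increasing")
    raw = (gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
           - gamma_dist.pdf(t, under_delay / under_disp, scale=under_disp) / ratio)
    return raw / _hrf_peak(peak_delay, under_delay, peak_disp, under_disp, ratio)


def convolve_events(
    design: BlockDesign,
    events: Sequence[Event],
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar regressor for each event, sampled at the TR.

    Boxcars are laid out on a `dt`-resolution microtime grid, convolved with
    the unit-peak HRF (Riemann-sum convention: the result carries a factor
    `dt`), then sampled at frame onsets.  Returns (n_frames, n_events).
    """
    n_frames = design.n_frames
    n_micro = int(np.ceil(design.total_seconds / dt)) + 1
    hrf = hrf_double_gamma(np.arange(0.0, 32.0 + dt, dt))
    out = np.zeros((n_frames, len(events)))
    frame_idx = np.round(np.arange(n_frames) * design.tr_seconds / dt).astype(int)
    for j, ev in enumerate(events):
        box = np.zeros(n_micro)
        i0 = int(np.round(ev.onset / dt))
        i1 = int(np.round((ev.onset + ev.duration) / dt))
        box[i0:min(i1, n_micro)] = 1.0
        reg = np.convolve(box, hrf)[:n_micro] * dt
        out[:, j] = reg[np.clip(frame_idx, 0, n_micro - 1)]
    return out


def convolve_design(
    design: BlockDesign,
    condition_ids: Sequence[str],
    dt: float = 0.1,
) -> np.ndarray:
    """Per-condition regressors (events of the same condition pooled).

    A condition with no events yields an all-zero column.  Linear in the
    underlying boxcars by construction.
    """
    if not design.events:
        raise ValueError("design has no events")
    cols = np.zeros((design.n_frames, len(condition_ids)))
    for j, cond in enumerate(condition_ids):
        evs = [e for e in design.events if e.condition == cond]
        if evs:
            cols[:, j] = convolve_events(design, evs, dt=dt).sum(axis=1)
    return cols


def compute_fd(motion: MotionTrace, radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement: summed absolute backward differences of the six
    parameters, rotations converted to arc length on a `radius_mm` sphere.
    The first frame has FD 0 by convention."""
    p = motion.params
    fd = np.zeros(p.shape[0])
    if p.shape[0] > 1:
        d = np.abs(np.diff(p, axis=0))
        fd[1:] = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return fd


class SyntheticScanner:
    """Deterministic run factory whose noise streams are drawn up front.

    Drawing motion/noise/spikes once for `max_blocks` blocks makes the run for
    k blocks a strict prefix of the run for k+1 blocks (plus the new block's
    frames), which is what a real scanner provides to the closed loop.
    """

    def __init__(
        self,
        space,
        truth: GroundTruthSurface,
        protocol: str = "exp1",
        tr_seconds: float = 2.0,
        max_blocks: int = 20,
        voxels_per_roi: int = 0,
        seed: int = 0,
        voxel_noise_sd: float | None = None,
        motion_step_sd: float = 0.02,
        rotation_step_sd: float = 4e-4,
        motion_jump_rate: float = 0.0,
        motion_jump_mm: float = 2.5,
    ) -> None:
        self.space = space
        self.truth = truth
        self.protocol = protocol
        self.tr = tr_seconds
        self.voxels_per_roi = int(voxels_per_roi)
        for roi, amps in truth.roi_means.items():
            for tid in space.ids:
                if tid not in amps:
                    raise KeyError(f"truth for roi {roi!r} lacks task {tid!r}")

        block_secs = sum(d for d, _, _ in PROTOCOLS[protocol]["segments"])
        n_total = LEAD_IN_FRAMES + int(round(max_blocks * block_secs / tr_seconds))
        rng = np.random.default_rng(seed)
        # fixed draw order => determinism regardless of later truncation
        steps = rng.normal(size=(n_total, 6))
        kernel = np.ones(5) / 5.0
        smooth = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 0, steps)
        smooth[:, :3] *= motion_step_sd
        smooth[:, 3:] *= rotation_step_sd
        params = np.cumsum(smooth, axis=0)
        if motion_jump_rate > 0:
            jumps = rng.random(n_total) < motion_jump_rate
            jump_sizes = rng.choice([-1.0, 1.0], size=n_total) * motion_jump_mm
            params[:, 0] += np.where(jumps, jump_sizes, 0.0)
        self._motion = params
        self._noise = {
            roi: truth.noise_sd * rng.normal(size=n_total) for roi in truth.rois
        }
        if truth.spike_rate > 0 and truth.spike_sd > 0:
            mask = rng.random((len(truth.rois), n_total)) < truth.spike_rate
            vals = truth.spike_sd * rng.normal(size=(len(truth.rois), n_total))
            self._spikes = {roi: mask[i] * vals[i] for i, roi in enumerate(truth.rois)}
        else:
            self._spikes = {roi: np.zeros(n_total) for roi in truth.rois}
        if self.voxels_per_roi > 0:
            vsd = truth.noise_sd if voxel_noise_sd is None else voxel_noise_sd
            self._voxel_noise = vsd * rng.normal(
                size=(len(truth.rois) * self.voxels_per_roi, n_total)
            )
        else:
            self._voxel_noise = None

    def run_for(self, block_conditions: Sequence[str]) -> SimulatedRun:
        """Assemble the run observed after the given blocks have been played."""
        design = make_block_design(self.protocol, block_conditions, self.tr)
        lead = design.lead_in_frames
        n = lead + design.n_frames
        if n > self._motion.shape[0]:
            raise ValueError("scanner was sized for fewer blocks")
        blocks = design.block_events
        regs = convolve_events(design, blocks) if blocks else np.zeros((design.n_frames, 0))
        drift = self.truth.drift_slope * np.arange(n)

        clean: dict[str, np.ndarray] = {}
        tcs: dict[str, np.ndarray] = {}
        betas: dict[tuple[int, str], float] = {}
        for roi in self.truth.rois:
            amps = self.truth.roi_means[roi]
            sig = np.zeros(n)
            for b, ev in enumerate(blocks):
                betas[(b, roi)] = amps[ev.condition]
                sig[lead:] += amps[ev.condition] * regs[:, b]
            clean[roi] = sig + drift
            tcs[roi] = clean[roi] + self._noise[roi][:n] + self._spikes[roi][:n]

        voxel_data = voxel_rois = voxel_clusters = None
        if self._voxel_noise is not None:
            vpr = self.voxels_per_roi
            rois = self.truth.rois
            voxel_data = np.empty((len(rois) * vpr, n))
            voxel_rois = {}
            labels: list[str] = []
            for i, roi in enumerate(rois):
                idx = np.arange(i * vpr, (i + 1) * vpr)
                voxel_rois[roi] = idx
                voxel_data[idx] = clean[roi] + self._voxel_noise[idx, :n]
                half = vpr // 2
                labels += [f"{roi}/c1"] * half + [f"{roi}/c2"] * (vpr - half)
            voxel_clusters = tuple(labels)

        return SimulatedRun(
            roi_timecourses=tcs,
            motion=MotionTrace(self._motion[:n].copy()),
            design=design,
            true_block_betas=betas,
            voxel_data=voxel_data,
            voxel_rois=voxel_rois,
            voxel_clusters=voxel_clusters,
        )


def simulate_run(
    space,
    truth: GroundTruthSurface,
    design: BlockDesign,
    voxels_per_roi: int = 0,
    seed: int = 0,
    protocol: str | None = None,
    **scanner_kwargs,
) -> SimulatedRun:
    """One-shot simulation of a complete run (see `SyntheticScanner`)."""
    blocks = [e.condition for e in design.block_events]
    proto = protocol
    if proto is None:
        # infer from block anatomy: exp2 blocks are 30 s, exp1/exp3 are 35 s
        proto = "exp2" if blocks and design.block_events[0].duration == 30.0 else "exp1"
    scanner = SyntheticScanner(
        space, truth, protocol=proto, tr_seconds=design.tr_seconds,
        max_blocks=max(len(blocks), 1), voxels_per_roi=voxels_per_roi,
        seed=seed, **scanner_kwargs,
    )
    return scanner.run_for(blocks)
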