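"""Rigid-body motion estimation, framewise displacement, DVARS, and the
real-time good-frame accumulation used during acquisition monitoring.

Framewise displacement (FD) follows the Power convention: the sum of the
absolute frame-to-frame changes of the three translations (mm) plus the
three rotations converted to arc length on a sphere (default radius
50 mm).  FD of the first frame is zero by convention, so the first frame
is never censored on motion grounds alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import Run, resample_rigid

__all__ = [
    "MotionTrace",
    "FDSeries",
    "DvarsSeries",
    "GoodTimeReport",
    "estimate_rigid_motion",
    "apply_rigid_motion",
    "compute_fd",
    "compute_dvars",
    "accumulate_good_time",
    "read_par",
    "write_par",
]

DEFAULT_ROTATION_RADIUS = 50.0  # mm; sphere radius for rotation -> displacement


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters.

    ``params`` has one row per frame: ``(rx, ry, rz, tx, ty, tz)`` with
    rotations in radians and translations in mm, relative to the
    reference frame (whose own row is all zeros when estimated).
    """

    params: np.ndarray
    tr: float
    reference_frame: int = 0
    flags: np.ndarray | None = None  # frames where optimization hit bounds

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("params must be (n_frames, 6)")
        if self.params.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class FDSeries:
    """Framewise displacement in mm; ``fd[0] == 0`` by convention."""

    fd: np.ndarray
    tr: float
    rotation_radius: float = DEFAULT_ROTATION_RADIUS

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=np.float64)
        if self.fd.ndim != 1:
            raise ValueError("fd must be 1-D")

    @property
    def n_frames(self) -> int:
        return self.fd.size

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fd_mm\n")
            for v in self.fd:
                fh.write(f"{v:.10f}\n")


@dataclass
class DvarsSeries:
    """Root-mean-square frame-to-frame intensity change; ``dvars[0] == 0``."""

    dvars: np.ndarray
    mask_size: int

    def __post_init__(self) -> None:
        self.dvars = np.asarray(self.dvars, dtype=np.float64)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("dvars\n")
            for v in self.dvars:
                fh.write(f"{v:.10f}\n")


@dataclass
class GoodTimeReport:
    """Real-time monitoring summary: accumulated sub-threshold scan time."""

    good_frames: int
    good_seconds: float
    target_met: bool
    threshold: float
    target: float


# ---------------------------------------------------------------------------
# FD / DVARS
# ---------------------------------------------------------------------------

def compute_fd(trace: MotionTrace, rotation_radius: float = DEFAULT_ROTATION_RADIUS) -> FDSeries:
    """Framewise displacement: sum |Δtranslation| + radius × sum |Δrotation|."""
    p = trace.params
    if not np.all(np.isfinite(p)):
        raise ValueError("motion parameters must be finite")
    d = np.abs(np.diff(p, axis=0))
    fd = np.zeros(trace.n_frames)
    if trace.n_frames > 1:
        fd[1:] = d[:, 3:6].sum(axis=1) + rotation_radius * d[:, 0:3].sum(axis=1)
    return FDSeries(fd, trace.tr, rotation_radius)


def compute_dvars(run: Run, brain_mask: np.ndarray) -> DvarsSeries:
    """DVARS: RMS over mask voxels of the intensity difference between
    consecutive volumes; first frame is zero by convention."""
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    if run.n_frames < 2:
        raise ValueError("need at least two frames")
    x = run.data[mask]  # (n_voxels, n_frames)
    diff = np.diff(x, axis=1)
    dvars = np.zeros(run.n_frames)
    dvars[1:] = np.sqrt(np.mean(diff * diff, axis=0))
    return DvarsSeries(dvars, int(mask.sum()))


def accumulate_good_time(fd: FDSeries, threshold: float, target: float) -> GoodTimeReport:
    """Emulate real-time monitoring: seconds of data with FD strictly below
    the threshold, and whether the session target has been reached."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    good = int(np.sum(fd.fd < threshold))
    seconds = good * fd.tr
    return GoodTimeReport(good, seconds, seconds >= target, threshold, target)


# ---------------------------------------------------------------------------
# Rigid-body estimation / application
# ---------------------------------------------------------------------------

def apply_rigid_motion(
    run: Run, trace: MotionTrace, invert: bool = False, order: int = 1
) -> Run:
    """Resample every frame under its rigid-body parameters.

    ``invert=True`` undoes the recorded motion (realignment to the
    reference); ``invert=False`` imposes it.  ``order`` selects the
    interpolation (1 = trilinear, 3 = cubic spline).
    """
    if trace.n_frames != run.n_frames:
        raise ValueError(
            f"trace has {trace.n_frames} frames, run has {run.n_frames}"
        )
    out = np.empty_like(run.data)
    for t in range(run.n_frames):
        out[..., t] = resample_rigid(run.data[..., t], trace.params[t],
                                     run.voxel_size, invert=invert, order=order)
    return Run(out, run.tr, run.voxel_size, dict(run.meta))


def _masked_mse(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    d = a[mask] - b[mask]
    return float(np.mean(d * d))


def estimate_rigid_motion(
    run: Run,
    brain_mask: np.ndarray,
    reference: int = 0,
    rotation_radius: float = DEFAULT_ROTATION_RADIUS,
    search_bound_mm: float = 10.0,
) -> MotionTrace:
    """Estimate per-frame rigid-body motion relative to a reference frame.

    Minimizes the masked mean squared intensity difference between each
    frame and the reference rendered under candidate parameters, using a
    coarse translation search followed by Powell refinement of all six
    parameters (rotations internally scaled by the rotation radius so the
    search space is isotropic in mm).  Frames whose solution lies at the
    search bound are flagged, not rejected.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    if run.n_frames < 2:
        raise ValueError("need at least two frames")
    ref = run.data[..., reference]

    def cost(q: np.ndarray, frame: np.ndarray) -> float:
        p = np.concatenate([q[:3] / rotation_radius, q[3:]])
        moved = resample_rigid(ref, p, run.voxel_size)
        return _masked_mse(moved, frame, mask)

    n = run.n_frames
    params = np.zeros((n, 6))
    flags = np.zeros(n, dtype=bool)
    prev = np.zeros(6)
    coarse = np.array([-2.0, 0.0, 2.0])
    for t in range(n):
        if t == reference:
            prev = np.zeros(6)
            continue
        frame = run.data[..., t]
        # candidate starts: previous frame's solution, zero, coarse translations
        starts = [prev.copy(), np.zeros(6)]
        best = min(starts, key=lambda q: cost(q, frame))
        best_cost = cost(best, frame)
        for dx in coarse:
            for dy in coarse:
                for dz in coarse:
                    q = np.array([0.0, 0.0, 0.0, dx, dy, dz])
                    c = cost(q, frame)
                    if c < best_cost:
                        best, best_cost = q, c
        res = optimize.minimize(
            cost, best, args=(frame,), method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
        )
        q = res.x
        if np.any(np.abs(q) >= search_bound_mm):
            flags[t] = True
        params[t] = np.concatenate([q[:3] / rotation_radius, q[3:]])
        prev = q
    if flags.any():
        warnings.warn(f"{int(flags.sum())} frame(s) hit the rigid search bound")
    return MotionTrace(params, run.tr, reference_frame=reference, flags=flags)


# ---------------------------------------------------------------------------
# FSL-dialect .par I/O (rotations rad in columns 1-3, translations mm in 4-6)
# ---------------------------------------------------------------------------

def write_par(trace: MotionTrace, path) -> None:
    np.savetxt(path, trace.params, fmt="%.10f")


def read_par(path, tr: float) -> MotionTrace:
    params = np.loadtxt(path, ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(f"expected 6 columns in {path}, got {params.shape[1]}")
    return MotionTrace(params, tr)
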