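"""Volume censoring, run concatenation, field-of-view outlier rejection
and trimming to the analysis duration.

Frames whose framewise displacement exceeds the threshold are removed;
adjacent frames are not, and no minimum length is imposed on retained
segments by default.  Censored runs are concatenated into a single long
run with full per-frame provenance.  Frames in which the head has partly
left the field of view are detected afterwards by their anomalously low
brain-voxel count (|count − mean| > z·sd over all frames).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Run
from .motion import FDSeries, MotionTrace, compute_fd

__all__ = [
    "CensorPlan",
    "BrainVolumeSeries",
    "InsufficientDataError",
    "discard_dummies",
    "censor_by_fd",
    "concatenate_runs",
    "brain_voxel_counts",
    "detect_fov_outliers",
    "trim_to_duration",
    "subject_retention",
]


class InsufficientDataError(RuntimeError):
    """Raised when a subject does not retain enough data for analysis;
    this is the normal subject-exclusion event, not a pipeline failure."""


@dataclass
class CensorPlan:
    """Per-frame bookkeeping for the concatenated sequence.

    ``table`` has one row per *original* acquisition frame, in order:
    columns ``source_run``, ``source_frame``, ``kept`` (bool), ``reason``
    (empty string for kept frames; one of ``dummy|fd|fov|trim`` for
    dropped frames) and ``out_frame`` (index in the surviving sequence,
    -1 if dropped).
    """

    table: pd.DataFrame
    threshold_fd: float | None = None

    def __post_init__(self) -> None:
        kept = self.table["kept"].to_numpy()
        reasons = self.table["reason"].to_numpy()
        if np.any(kept & (reasons != "")):
            raise ValueError("kept frames must have an empty reason")
        if np.any(~kept & (reasons == "")):
            raise ValueError("every dropped frame needs exactly one reason")

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def run_boundaries(self) -> np.ndarray:
        """Start index (in the surviving sequence) of each run that
        contributes at least one kept frame; first boundary is 0."""
        kept = self.table[self.table["kept"]]
        bounds = kept.groupby("source_run", sort=True)["out_frame"].min().to_numpy()
        return np.sort(bounds)

    def reindex_output(self) -> None:
        kept = self.table["kept"].to_numpy()
        out = np.full(len(self.table), -1, dtype=int)
        out[kept] = np.arange(int(kept.sum()))
        self.table["out_frame"] = out

    def drop_output_frames(self, out_indices: np.ndarray, reason: str) -> None:
        """Mark currently-kept output frames as dropped and renumber."""
        out_indices = np.asarray(out_indices, dtype=int)
        sel = self.table["out_frame"].isin(out_indices) & self.table["kept"]
        self.table.loc[sel, "kept"] = False
        self.table.loc[sel, "reason"] = reason
        self.reindex_output()

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "frame", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, threshold_fd: float | None = None) -> "CensorPlan":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        df = df.drop(columns=["frame"])
        df["kept"] = df["kept"].astype(bool)
        return cls(df, threshold_fd)


@dataclass
class BrainVolumeSeries:
    """Per-frame brain-voxel counts with the outlier statistics."""

    counts: np.ndarray
    mean: float
    sd: float
    z_cut: float = 4.0


# ---------------------------------------------------------------------------


def discard_dummies(run: Run, trace: MotionTrace, n_dummy: int = 3) -> tuple[Run, MotionTrace]:
    """Drop the initial pre-steady-state volumes from the image and trace."""
    if n_dummy < 0:
        raise ValueError("n_dummy must be >= 0")
    if run.n_frames < n_dummy + 2:
        raise InsufficientDataError(
            f"run has {run.n_frames} frames; needs more than {n_dummy + 1}"
        )
    if trace.n_frames != run.n_frames:
        raise ValueError("trace length must match run length")
    if n_dummy == 0:
        return run, trace
    # views: downstream stages never mutate run data in place
    new_run = Run(run.data[..., n_dummy:], run.tr, run.voxel_size, dict(run.meta))
    new_trace = MotionTrace(trace.params[n_dummy:].copy(), trace.tr)
    return new_run, new_trace


def censor_by_fd(
    fd: FDSeries, threshold: float, min_segment_frames: int | None = None
) -> np.ndarray:
    """Keep mask: frame kept iff fd <= threshold (frames whose FD
    *exceeds* the threshold are removed; boundary frames are kept, and no
    neighbor expansion is applied).

    ``min_segment_frames``, off by default, additionally drops kept
    segments shorter than the given length.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = fd.fd <= threshold
    if min_segment_frames:
        keep = keep.copy()
        n = keep.size
        t = 0
        while t < n:
            if keep[t]:
                s = t
                while t < n and keep[t]:
                    t += 1
                if t - s < min_segment_frames:
                    keep[s:t] = False
            else:
                t += 1
    return keep


def concatenate_runs(
    runs: list[Run],
    keep_masks: list[np.ndarray],
    dummy_counts: list[int] | None = None,
    threshold_fd: float | None = None,
) -> tuple[Run, CensorPlan]:
    """Concatenate the kept frames of each run, in acquisition order.

    ``keep_masks`` refer to the runs as passed (i.e. after dummy
    discard); ``dummy_counts`` lets the plan also account for dummy
    frames already removed upstream, so that every acquired frame appears
    exactly once in the provenance table.
    """
    if not runs:
        raise ValueError("need at least one run")
    if len(keep_masks) != len(runs):
        raise ValueError("one keep mask per run required")
    ref = runs[0]
    for r in runs[1:]:
        if r.shape != ref.shape:
            raise ValueError("all runs must share grid shape")
        if r.voxel_size != ref.voxel_size:
            raise ValueError("all runs must share voxel size")
        if not math.isclose(r.tr, ref.tr, rel_tol=1e-9):
            raise ValueError("all runs must share tr")
    if dummy_counts is None:
        dummy_counts = [0] * len(runs)

    rows = []
    blocks = []
    for i, (r, keep) in enumerate(zip(runs, keep_masks)):
        keep = np.asarray(keep, dtype=bool)
        if keep.size != r.n_frames:
            raise ValueError(f"keep mask length mismatch for run {i}")
        for d in range(dummy_counts[i]):
            rows.append((i, d, False, "dummy"))
        for f in range(r.n_frames):
            rows.append((i, f + dummy_counts[i], bool(keep[f]), "" if keep[f] else "fd"))
        blocks.append(r.data[..., keep])
    data = np.concatenate(blocks, axis=3)
    table = pd.DataFrame(rows, columns=["source_run", "source_frame", "kept", "reason"])
    table["out_frame"] = -1
    plan = CensorPlan(table, threshold_fd)
    plan.reindex_output()
    out = Run(data, ref.tr, ref.voxel_size)
    return out, plan


# ---------------------------------------------------------------------------
# Field-of-view outliers
# ---------------------------------------------------------------------------


def brain_voxel_counts(run: Run, threshold_frac: float = 0.35) -> np.ndarray:
    """Per-volume brain-voxel count via a simple intensity extraction:
    voxels above ``threshold_frac`` of the volume's robust maximum (98th
    percentile), restricted to the largest connected component."""
    counts = np.zeros(run.n_frames, dtype=int)
    for t in range(run.n_frames):
        vol = run.data[..., t]
        rmax = np.percentile(vol, 98)
        if rmax <= 0:
            counts[t] = 0
            continue
        mask = vol > threshold_frac * rmax
        labels, n = ndimage.label(mask)
        if n == 0:
            counts[t] = 0
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        counts[t] = int(sizes.max())
    return counts


def detect_fov_outliers(
    run: Run,
    z_cut: float = 4.0,
    threshold_frac: float = 0.35,
    iterative: bool = False,
) -> tuple[BrainVolumeSeries, np.ndarray]:
    """Flag frames whose brain-voxel count deviates from the mean by more
    than ``z_cut`` standard deviations (computed over all frames in a
    single pass; ``iterative=True`` recomputes the statistics once after
    excluding the first-pass outliers)."""
    if run.n_frames < 8:
        raise ValueError("need at least 8 frames for a meaningful sd")
    counts = brain_voxel_counts(run, threshold_frac)
    mean = float(counts.mean())
    sd = float(counts.std())
    if sd == 0:
        warnings.warn("all brain-voxel counts identical; no FOV outliers flagged")
        return BrainVolumeSeries(counts, mean, sd, z_cut), np.zeros(run.n_frames, dtype=bool)
    outliers = np.abs(counts - mean) > z_cut * sd
    if iterative and outliers.any():
        inl = counts[~outliers]
        mean = float(inl.mean())
        sd = float(inl.std())
        if sd > 0:
            outliers = np.abs(counts - mean) > z_cut * sd
    return BrainVolumeSeries(counts, mean, sd, z_cut), outliers


# ---------------------------------------------------------------------------


def trim_to_duration(run: Run, plan: CensorPlan, duration: float) -> tuple[Run, CensorPlan]:
    """Keep the first ``floor(duration / tr)`` frames of the surviving
    sequence; the rest are tagged ``trim``.  Raises
    :class:`InsufficientDataError` when the retained data is shorter than
    the requested duration — the subject-exclusion event."""
    n_keep = int(math.floor(duration / run.tr))
    if run.n_frames < n_keep:
        raise InsufficientDataError(
            f"retained {run.n_frames * run.tr:.1f}s < required {duration:.1f}s"
        )
    if run.n_frames == n_keep:
        return run, plan
    out = Run(run.data[..., :n_keep], run.tr, run.voxel_size, dict(run.meta))
    plan.drop_output_frames(np.arange(n_keep, run.n_frames), "trim")
    return out, plan


def subject_retention(
    fd_by_subject: dict[str, np.ndarray],
    thresholds: list[float],
    min_duration: float,
    tr: float,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Retention table: a subject is retained at a threshold iff
    ``tr × count(fd <= threshold) >= min_duration``.

    Returns one row per threshold with overall and per-group retained
    counts; counts are monotonically nondecreasing in the threshold.
    """
    rows = []
    group_levels = sorted(set(groups.values())) if groups else []
    for th in thresholds:
        row = {"threshold": th, "n_retained": 0}
        for g in group_levels:
            row[f"n_{g}"] = 0
        for sid, fd in fd_by_subject.items():
            fd = np.asarray(fd, dtype=float)
            if tr * np.sum(fd <= th) >= min_duration:
                row["n_retained"] += 1
                if groups:
                    row[f"n_{groups[sid]}"] += 1
        row["pct_retained"] = 100.0 * row["n_retained"] / max(len(fd_by_subject), 1)
        rows.append(row)
    return pd.DataFrame(rows)
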