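"""Quality-control metrics and group-level QC-FD diagnostics.

Per subject: temporal SNR and parcel-wise Pearson connectivity.  Across
subjects: the correlation of each connectivity edge (and of tSNR) with
mean framewise displacement, the proportion of edges significantly
correlated with motion (chance benchmark 5 %), its dependence on
internodal distance (lowess), and per-subject/pooled DVARS-FD
regressions.  A pipeline that removes motion artifact should drive all
of these toward their null values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .core import Run

__all__ = [
    "ConnectivityMatrix",
    "QcFdEdgeResult",
    "DvarsFdRegression",
    "compute_tsnr",
    "parcel_timeseries",
    "connectivity_matrix",
    "qcfd_edges",
    "tsnr_fd_correlation",
    "dvars_fd_regression",
    "group_fd_stats",
    "binomial_null_band",
]


@dataclass
class ConnectivityMatrix:
    matrix: np.ndarray          # (n_nodes, n_nodes) Pearson r
    node_distances: np.ndarray  # (n_nodes, n_nodes) centroid distance, mm
    node_ids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle edge values and distances, row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.matrix[iu], self.node_distances[iu]


@dataclass
class QcFdEdgeResult:
    r: np.ndarray                     # per-edge correlation with mean FD
    p: np.ndarray
    proportion_significant: float     # fraction with p < 0.05 (uncorrected)
    distances: np.ndarray
    lowess_curve: np.ndarray          # (m, 2): distance, smoothed r

    @property
    def profile_range(self) -> float:
        ys = self.lowess_curve[:, 1]
        return float(ys.max() - ys.min())


@dataclass
class DvarsFdRegression:
    per_subject: pd.DataFrame  # slope, intercept, r2 per subject
    pooled_slope: float
    pooled_intercept: float
    pooled_r2: float


# ---------------------------------------------------------------------------


def compute_tsnr(
    run: Run, brain_mask: np.ndarray, mode: str = "voxelwise"
) -> tuple[float, np.ndarray]:
    """Temporal SNR: mean signal divided by standard deviation over time.

    ``voxelwise`` (primary): per-voxel mean/sd averaged over the mask.
    ``global``: mean/sd of the spatially-averaged in-mask time series.
    Returns the scalar and the voxelwise map (zeros where sd is zero).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    if run.n_frames < 8:
        raise ValueError("need at least 8 frames")
    x = run.data[mask]
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    tsnr_map = np.zeros(run.shape)
    ok = sd > 0
    if not ok.any():
        raise ValueError("all in-mask voxels are temporally constant")
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance voxel(s) from tSNR")
    vals = np.zeros(mask.sum())
    vals[ok] = mean[ok] / sd[ok]
    tsnr_map[mask] = vals
    if mode == "voxelwise":
        scalar = float(vals[ok].mean())
    elif mode == "global":
        g = x.mean(axis=0)
        gsd = g.std()
        if gsd == 0:
            raise ValueError("global time series is constant")
        scalar = float(g.mean() / gsd)
    else:
        raise ValueError(f"unknown tSNR mode {mode!r}")
    return scalar, tsnr_map


def parcel_timeseries(
    run: Run, parcellation: np.ndarray, min_voxels: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean time series.

    Nodes (labels >= 1) with fewer than ``min_voxels`` voxels are dropped
    and reported via the returned kept-label array.
    Returns ``(series, kept_labels)`` with series shaped (n_nodes, n_frames).
    """
    labels = np.asarray(parcellation)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    series = []
    kept = []
    for lab in ids:
        sel = labels == lab
        if int(sel.sum()) < min_voxels:
            continue
        series.append(run.data[sel].mean(axis=0))
        kept.append(lab)
    if not kept:
        raise ValueError("no parcel has enough voxels")
    return np.asarray(series), np.asarray(kept)


def connectivity_matrix(
    node_series: np.ndarray, centroids: np.ndarray
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between node time series, with
    centroid Euclidean distances in mm."""
    series = np.asarray(node_series, dtype=float)
    n, nt = series.shape
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if nt < 3:
        raise ValueError("need at least 3 frames")
    sds = series.std(axis=1)
    if np.any(sds == 0):
        warnings.warn(
            f"{int((sds == 0).sum())} constant node series; their edges are NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(series)
    mat = (mat + mat.T) / 2.0  # exact symmetry despite float rounding
    np.fill_diagonal(mat, 1.0)
    c = np.asarray(centroids, dtype=float)
    dist = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    return ConnectivityMatrix(mat, dist, np.arange(1, n + 1))


def _pearson_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Pearson r of X (n × m) with y (n), plus two-sided t-test p."""
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def qcfd_edges(
    edge_values: np.ndarray,
    mean_fd: np.ndarray,
    distances: np.ndarray,
    lowess_frac: float = 2.0 / 3.0,
) -> QcFdEdgeResult:
    """Edge-wise QC-FD analysis across subjects.

    ``edge_values`` is (n_subjects, n_edges); each edge is correlated with
    subject mean FD (Pearson, two-sided t-test p, uncorrected).  The
    proportion of edges with p < 0.05 has a chance benchmark of 5 %.
    The (distance, r) relationship is smoothed with lowess.
    """
    E = np.asarray(edge_values, dtype=float)
    fd = np.asarray(mean_fd, dtype=float)
    if E.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if np.ptp(fd) == 0:
        raise ValueError("zero variance in mean FD across subjects")
    r, p = _pearson_with_p(E, fd)
    finite = np.isfinite(r)
    prop = float(np.mean(p[finite] < 0.05)) if finite.any() else float("nan")
    d = np.asarray(distances, dtype=float)
    sm = sm_lowess(r[finite], d[finite], frac=lowess_frac, return_sorted=True)
    return QcFdEdgeResult(r, p, prop, d, sm)


def tsnr_fd_correlation(qc_table: pd.DataFrame, stage: str = "pre") -> tuple[float, float]:
    """Pearson correlation of per-subject tSNR (pre- or post-cleanup)
    with mean FD, with two-sided p."""
    col = {"pre": "tsnr_pre", "post": "tsnr_post"}[stage]
    df = qc_table[["mean_fd", col]].dropna()
    if len(df) < 5:
        raise ValueError("need at least 5 subjects with finite values")
    x, y = df["mean_fd"].to_numpy(), df[col].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in FD or tSNR")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def dvars_fd_regression(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]]
) -> DvarsFdRegression:
    """Per-subject and pooled OLS of DVARS on FD.

    ``pairs[subject] = (fd, dvars)``, paired per frame; frame 0 (where
    both are zero by convention) is dropped.  Subjects with constant FD
    are skipped with a warning.
    """
    rows = []
    all_fd, all_dv = [], []
    for sid, (fd, dv) in pairs.items():
        fd = np.asarray(fd, dtype=float)[1:]
        dv = np.asarray(dv, dtype=float)[1:]
        if fd.size != dv.size:
            raise ValueError(f"subject {sid}: fd/dvars length mismatch")
        if fd.size < 9:
            raise ValueError(f"subject {sid}: need at least 10 paired frames")
        if np.ptp(fd) == 0:
            warnings.warn(f"subject {sid}: constant FD, skipped")
            continue
        res = stats.linregress(fd, dv)
        rows.append({"subject": sid, "slope": res.slope,
                     "intercept": res.intercept, "r2": res.rvalue ** 2})
        all_fd.append(fd)
        all_dv.append(dv)
    if not rows:
        raise ValueError("no usable subjects")
    pooled = stats.linregress(np.concatenate(all_fd), np.concatenate(all_dv))
    return DvarsFdRegression(
        pd.DataFrame(rows),
        float(pooled.slope),
        float(pooled.intercept),
        float(pooled.rvalue ** 2),
    )


def group_fd_stats(
    qc_table: pd.DataFrame,
    group_field: str = "group",
    covariate_field: str | None = "age",
) -> dict:
    """Group mean ± sd of mean FD, Welch two-sample test between the two
    groups, and the Pearson correlation of mean FD with a covariate."""
    out: dict = {"groups": {}}
    levels = sorted(qc_table[group_field].dropna().unique())
    for g in levels:
        vals = qc_table.loc[qc_table[group_field] == g, "mean_fd"].to_numpy()
        if vals.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
        out["groups"][str(g)] = {"n": int(vals.size),
                                 "mean_fd": float(vals.mean()),
                                 "sd_fd": float(vals.std(ddof=1))}
    if len(levels) == 2:
        a = qc_table.loc[qc_table[group_field] == levels[0], "mean_fd"]
        b = qc_table.loc[qc_table[group_field] == levels[1], "mean_fd"]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["welch_t"] = float(t)
        out["welch_p"] = float(p)
        out["offset"] = float(b.mean() - a.mean())
    if covariate_field and covariate_field in qc_table:
        df = qc_table[["mean_fd", covariate_field]].dropna()
        if len(df) >= 5 and df[covariate_field].std() > 0:
            r, p = stats.pearsonr(df["mean_fd"], df[covariate_field])
            out["covariate_r"] = float(r)
            out["covariate_p"] = float(p)
    return out


def binomial_null_band(n_edges: int, p0: float = 0.05, level: float = 0.99) -> tuple[float, float]:
    """Central binomial band for the proportion of significant edges
    expected by chance."""
    alpha = (1.0 - level) / 2.0
    lo = stats.binom.ppf(alpha, n_edges, p0) / n_edges
    hi = stats.binom.ppf(1.0 - alpha, n_edges, p0) / n_edges
    return float(lo), float(hi)
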