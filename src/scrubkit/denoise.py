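"""Intensity normalization, spatial ICA, component scoring and
"aggressive" noise regression.

Components are scored against the hand-labeling guidelines used for
signal/noise triage of single-subject ICA: noise components live in the
brain-rim, show slice-periodic spatial structure tied to the multiband
acquisition, carry predominantly high-frequency power, or have sudden
temporal jumps; signal components overlap grey matter and have smooth,
low-frequency time courses.  "Aggressive" cleanup regresses every noise
time course out of every voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.decomposition import FastICA

from .core import Run

__all__ = [
    "ComponentSet",
    "ComponentFeatures",
    "ComponentLabels",
    "ClassifierThresholds",
    "normalize_intensity",
    "decompose_ica",
    "extract_component_features",
    "classify_components",
    "aggressive_cleanup",
    "rim_mask",
    "write_fix_labels",
    "read_fix_labels",
]


@dataclass
class ComponentSet:
    """Spatial-ICA decomposition.

    ``spatial_maps`` is (nx, ny, nz, k); ``timecourses`` is (n_frames, k)
    with unit-variance columns (amplitude lives in the maps).  The
    decomposition satisfies ``data ≈ mean + maps ⊗ timecourses + residual``
    over the analysis mask.
    """

    spatial_maps: np.ndarray
    timecourses: np.ndarray
    mask: np.ndarray
    explained_variance: np.ndarray
    voxel_means: np.ndarray
    frame_means: np.ndarray
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[1]


@dataclass
class ComponentFeatures:
    """Per-component scalar features used by the rule-based classifier."""

    edge_fraction: np.ndarray       # |weight| mass in the brain-rim mask
    gm_overlap: np.ndarray          # |weight| mass in grey matter
    highfreq_fraction: np.ndarray   # temporal power above f_cut
    slice_periodicity: np.ndarray   # slice-profile power at the slice period
    jump_score: np.ndarray          # max |Δtc| / robust sd of the timecourse


@dataclass
class ClassifierThresholds:
    """Rule thresholds; defaults tuned on the synthetic labeled set."""

    edge: float = 0.35
    slice_periodicity: float = 0.30
    highfreq: float = 0.50
    jump: float = 6.0
    gm_override: float = 0.5


@dataclass
class ComponentLabels:
    labels: np.ndarray              # array of "signal" / "noise"
    rule_trace: list = field(default_factory=list)

    @property
    def noise_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "noise")

    @property
    def signal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == "signal")


# ---------------------------------------------------------------------------


def normalize_intensity(
    run: Run, brain_mask: np.ndarray, target: float = 10_000.0, inplace: bool = False
) -> Run:
    """Scale each volume so its mean over brain voxels equals ``target``
    (accounts for the arbitrary intensity scale of different runs)."""
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    means = run.data[mask].mean(axis=0)
    if np.any(means <= 0):
        bad = np.flatnonzero(means <= 0)
        raise ValueError(f"non-positive in-mask mean at frame(s) {bad[:5].tolist()}")
    if inplace:
        run.data *= target / means
        return run
    out = run.data * (target / means)
    return Run(out, run.tr, run.voxel_size, dict(run.meta))


def decompose_ica(
    run: Run,
    brain_mask: np.ndarray,
    n_components: int = 60,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ComponentSet:
    """Spatial ICA of the in-mask data.

    The voxel × time matrix is reduced to ``n_components`` dimensions and
    unmixed by fixed-point independence maximization over space; time
    courses are returned with unit variance.  Deterministic for a fixed
    seed.  Non-convergence does not raise: the partial result is returned
    with ``converged=False``.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_components >= run.n_frames:
        raise ValueError("n_components must be smaller than the number of frames")
    if n_components >= n_vox:
        raise ValueError("n_components must be smaller than the number of mask voxels")
    X = run.data[mask]  # (n_vox, n_frames)
    voxel_means = X.mean(axis=1)
    Xc = X - voxel_means[:, None]

    ica = FastICA(
        n_components=n_components,
        random_state=seed,
        whiten="unit-variance",
        whiten_solver="eigh",
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S = ica.fit_transform(Xc)          # (n_vox, k) spatial sources
        converged = not any("did not converge" in str(w.message) for w in caught)
    A = ica.mixing_                        # (n_frames, k) time courses
    frame_means = ica.mean_                # per-frame centering over voxels

    sd = A.std(axis=0)
    sd[sd == 0] = 1.0
    A = A / sd
    S = S * sd

    total_var = float(np.sum(Xc.var(axis=1))) or 1.0
    ev = np.array([np.sum(S[:, k] ** 2) / total_var for k in range(S.shape[1])])

    order = np.argsort(ev)[::-1]
    S, A, ev = S[:, order], A[:, order], ev[order]

    maps = np.zeros(run.shape + (S.shape[1],))
    maps[mask] = S
    return ComponentSet(maps, A, mask, ev, voxel_means, frame_means, converged)


def reconstruct(components: ComponentSet) -> np.ndarray:
    """In-mask reconstruction ``mean + maps @ timecourses'`` (voxels × frames)."""
    S = components.spatial_maps[components.mask]
    X = S @ components.timecourses.T + components.frame_means[None, :]
    return X + components.voxel_means[:, None]


def rim_mask(brain_mask: np.ndarray, thickness: int = 2) -> np.ndarray:
    """Brain-edge shell: brain voxels within ``thickness`` erosions of the
    surface."""
    brain = np.asarray(brain_mask, dtype=bool)
    interior = ndimage.binary_erosion(brain, iterations=thickness)
    return brain & ~interior


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def extract_component_features(
    components: ComponentSet,
    brain_mask: np.ndarray,
    gm_mask: np.ndarray,
    tr: float,
    f_cut: float = 0.1,
    slice_period: int = 4,
    rim_thickness: int = 2,
) -> ComponentFeatures:
    """Score each component's spatial and spectral structure.

    Fractions are of absolute spatial weight mass within the brain mask;
    spectral quantities come from the discrete Fourier transform of the
    unit-variance time course (high-frequency fraction) and of the
    slice-wise mean |weight| profile (slice periodicity, as the share of
    off-DC power at the slice-period frequency).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    brain = np.asarray(brain_mask, dtype=bool)
    gm = np.asarray(gm_mask, dtype=bool)
    if brain.shape != components.spatial_maps.shape[:3]:
        raise ValueError("masks must align with the spatial maps")
    rim = rim_mask(brain, rim_thickness)
    k = components.n_components
    nz = brain.shape[2]

    edge = np.zeros(k)
    gmov = np.zeros(k)
    hff = np.zeros(k)
    slp = np.zeros(k)
    jump = np.zeros(k)

    freqs = np.fft.rfftfreq(components.timecourses.shape[0], d=tr)
    zfreqs = np.fft.rfftfreq(nz, d=1.0)  # cycles per slice
    target_zf = 1.0 / slice_period
    zbin = int(np.argmin(np.abs(zfreqs - target_zf)))

    for i in range(k):
        m = np.abs(components.spatial_maps[..., i])
        total = m[brain].sum()
        if total > 0:
            edge[i] = m[rim].sum() / total
            gmov[i] = m[gm].sum() / total
        # slice-wise mean |weight| over in-brain voxels
        prof = np.array([
            m[..., z][brain[..., z]].mean() if brain[..., z].any() else 0.0
            for z in range(nz)
        ])
        spec = np.abs(np.fft.rfft(prof - prof.mean())) ** 2
        off_dc = spec[1:].sum()
        if off_dc > 0 and zbin >= 1:
            # a slice-periodic comb carries its power at the fundamental
            # slice frequency and its harmonics
            harmonics = np.arange(zbin, spec.size, zbin)
            slp[i] = spec[harmonics].sum() / off_dc

        tc = components.timecourses[:, i]
        pspec = np.abs(np.fft.rfft(tc - tc.mean())) ** 2
        ptot = pspec[1:].sum()
        if ptot > 0:
            hff[i] = pspec[1:][freqs[1:] > f_cut].sum() / ptot
        d = np.diff(tc)
        if d.size:
            # normalized by the timecourse's robust sd: a spiky course has a
            # small robust sd, so genuine sudden jumps score high, while the
            # frame-to-frame wiggle of a smooth course does not
            rsd = _robust_sd(tc)
            if rsd == 0:
                rsd = float(tc.std())
            jump[i] = float(np.max(np.abs(d)) / rsd) if rsd > 0 else 0.0
    return ComponentFeatures(edge, gmov, hff, slp, jump)


def classify_components(
    features: ComponentFeatures,
    thresholds: ClassifierThresholds | None = None,
) -> ComponentLabels:
    """Rule-based signal/noise labeling.

    A component is noise iff any noise rule fires (edge fraction, slice
    periodicity, high-frequency fraction, or jump score above threshold)
    AND its grey-matter overlap stays below the override threshold;
    components with nothing suspicious default to signal.
    """
    th = thresholds or ClassifierThresholds()
    arrs = [features.edge_fraction, features.gm_overlap, features.highfreq_fraction,
            features.slice_periodicity, features.jump_score]
    if not all(np.all(np.isfinite(a)) for a in arrs):
        raise ValueError("features must be finite")
    k = features.edge_fraction.size
    labels = np.full(k, "signal", dtype=object)
    trace: list = []
    for i in range(k):
        fired = []
        if features.edge_fraction[i] > th.edge:
            fired.append("edge")
        if features.slice_periodicity[i] > th.slice_periodicity:
            fired.append("slice")
        if features.highfreq_fraction[i] > th.highfreq:
            fired.append("highfreq")
        if features.jump_score[i] > th.jump:
            fired.append("jump")
        if fired and features.gm_overlap[i] < th.gm_override:
            labels[i] = "noise"
            trace.append(fired)
        else:
            trace.append(["gm_override"] if fired else [])
    return ComponentLabels(np.array(labels, dtype=object), trace)


def aggressive_cleanup(
    run: Run,
    components: ComponentSet,
    labels: ComponentLabels,
) -> Run:
    """Regress all noise time courses (plus an intercept) out of every
    voxel; the residual plus the fitted intercept is returned.  With no
    noise components labeled this is the identity."""
    noise = labels.noise_indices
    if noise.size == 0:
        return run.copy()
    T = components.timecourses[:, noise]  # (n_frames, k_noise)
    if T.shape[0] != run.n_frames:
        raise ValueError("timecourse length must match the run's frame count")

    # drop collinear columns (rank-deficient noise design)
    D = np.column_stack([np.ones(T.shape[0]), T])
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * diag.max()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear noise timecourse(s)")
        D = D[:, keep]

    nx, ny, nzv, nt = run.data.shape
    Y = run.data.reshape(-1, nt).T  # (n_frames, n_vox)
    # normal equations are safe: collinear columns were dropped above
    beta = np.linalg.solve(D.T @ D, D.T @ Y)
    fitted_noise = D[:, 1:] @ beta[1:]
    cleaned = (Y - fitted_noise).T.reshape(nx, ny, nzv, nt)
    return Run(cleaned, run.tr, run.voxel_size, dict(run.meta))


# ---------------------------------------------------------------------------
# FIX-style label file: a bracketed, comma-separated, 1-based index list
# on the last line.
# ---------------------------------------------------------------------------

def write_fix_labels(labels: ComponentLabels, path) -> None:
    idx = (labels.noise_indices + 1).tolist()
    with open(path, "w") as fh:
        for i, lab in enumerate(labels.labels):
            fh.write(f"{i + 1}\t{lab}\n")
        fh.write("[" + ", ".join(str(i) for i in idx) + "]\n")


def read_fix_labels(path, n_components: int) -> ComponentLabels:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    last = lines[-1]
    if not (last.startswith("[") and last.endswith("]")):
        raise ValueError("last line must be a bracketed index list")
    body = last[1:-1].strip()
    idx = [int(s) - 1 for s in body.split(",") if s.strip()] if body else []
    labels = np.full(n_components, "signal", dtype=object)
    for i in idx:
        if not 0 <= i < n_components:
            raise ValueError(f"component index {i + 1} out of range")
        labels[i] = "noise"
    return ComponentLabels(labels, [["file"]] * n_components)
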