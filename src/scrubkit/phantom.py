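"""Synthetic multi-run, multi-subject BOLD phantoms with known ground truth.

The generator emulates the data properties of a high-motion pediatric
resting-state cohort so that every pipeline stage can be tested against
exact ground truth:

* an ellipsoidal "brain" with a grey-matter shell carrying disjoint
  parcels (nodes), at 2.5 mm resolution by default;
* rigid-body motion whose framewise-displacement series is a mixture of
  low-amplitude jitter and sparse large jump events, right-skewed like
  the cohort it emulates (per-frame mean FD ≈ 0.50 mm, median ≈ 0.22 mm
  at the default target);
* motion-locked artifacts: a brain-edge rim whose intensity scales
  linearly with FD, and a slice-periodic pattern (every 4th slice) active
  when FD exceeds a trigger — the spatial morphologies that single-subject
  ICA triage keys on;
* occasional field-of-view dropout frames in which a large translation
  pushes a stated fraction of brain voxels off the grid while the motion
  trace stays quiet (the frames only a brain-voxel-count check can catch);
* low-frequency (0.01–0.1 Hz) network signals painted on the parcels, and
  an optional motion-coupled confound that inflates connectivity between
  nearby nodes in proportion to subject-level motion — the QC-FD
  inflation the pipeline exists to remove.

Everything is deterministic under fixed seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import Run, resample_rigid
from .motion import DEFAULT_ROTATION_RADIUS, MotionTrace, write_par

__all__ = [
    "PhantomTemplate",
    "GroundTruth",
    "SubjectRecord",
    "Cohort",
    "NodeCohort",
    "make_phantom",
    "simulate_motion_trace",
    "render_run",
    "simulate_subject",
    "simulate_cohort",
    "simulate_node_cohort",
    "save_cohort",
]

# Default artifact/signal scales (image intensity is ~600-1000 units).
NETWORK_AMP = 50.0       # network signal amplitude at parcel voxels
NETWORK_LENGTH_MM = 20.0  # spatial decay of network weight away from its nodes
NODE_SIGNAL_AMP = 18.0   # idiosyncratic per-node activity (keeps edges off the r=1 ceiling)
RIM_AMP = 80.0           # rim artifact intensity per mm of FD
SLICE_AMP = 60.0         # slice artifact intensity per mm of FD
SLICE_TRIGGER = 0.5      # mm FD above which the slice artifact switches on
SLICE_PERIOD = 4         # every 4th slice
NOISE_SD = 10.0          # thermal noise sd (per-subject level varies around this)
NOISE_SMOOTH_SIGMA = 0.6  # voxels; reconstruction noise is slightly correlated
CONFOUND_AMP = 60.0      # confound intensity per (supra-floor FD mm × mean-FD mm)
CONFOUND_FD_FLOOR = 0.2  # mm; confound driven by max(FD - floor, 0)
CONFOUND_SIGMA_MM = 12.0  # spatial correlation length of the confound field
N_NETWORKS = 7           # resting-state parcellations carry ~7 canonical networks


@dataclass
class PhantomTemplate:
    """Static anatomy: intensity grid, brain/grey-matter masks, parcels."""

    intensity: np.ndarray
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    parcellation: np.ndarray
    node_centroids: np.ndarray  # (n_nodes, 3) mm
    voxel_size: tuple[float, float, float]

    @property
    def n_nodes(self) -> int:
        return self.node_centroids.shape[0]

    @property
    def node_labels(self) -> np.ndarray:
        labs = np.unique(self.parcellation)
        return labs[labs > 0]

    def validate(self) -> None:
        if np.any(self.gm_mask & ~self.brain_mask):
            raise ValueError("gm_mask must be inside brain_mask")
        if np.any((self.parcellation > 0) & ~self.gm_mask):
            raise ValueError("parcels must lie inside gm_mask")
        for lab in self.node_labels:
            if int((self.parcellation == lab).sum()) < 5:
                raise ValueError(f"parcel {lab} has fewer than 5 voxels")

    def node_distances(self) -> np.ndarray:
        c = self.node_centroids
        return np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))


@dataclass
class GroundTruth:
    """Everything the generator knows about one rendered run."""

    trace: MotionTrace
    fd: np.ndarray                       # internal FD bookkeeping, mm
    network_timecourses: np.ndarray      # (n_networks, n_frames), unit sd
    network_assignment: np.ndarray       # parcel index -> network index
    network_maps: np.ndarray | None = None  # (n_networks, nx, ny, nz) weights
    node_timecourses: np.ndarray | None = None  # (n_nodes, n_frames), unit sd
    node_signal_amp: float = NODE_SIGNAL_AMP
    dropout_frames: set = field(default_factory=set)
    dropout_fraction: float = 0.3
    noise_sd: float = NOISE_SD
    subject_mean_fd_target: float = 0.5
    network_amp: float = NETWORK_AMP
    rim_amp: float = RIM_AMP
    rim_noise_frac: float = 0.5
    slice_amp: float = SLICE_AMP
    slice_trigger: float = SLICE_TRIGGER
    noise_smooth_sigma: float = NOISE_SMOOTH_SIGMA
    motion_noise_amp: float = 10.0       # brain-wide unstructured residue per mm FD
    confound_amp: float = 0.0            # subject-level confound amplitude
    confound_fd_floor: float = CONFOUND_FD_FLOOR
    confound_sigma_mm: float = CONFOUND_SIGMA_MM

    @property
    def n_frames(self) -> int:
        return self.trace.n_frames

    @property
    def artifact_timecourses(self) -> dict[str, np.ndarray]:
        """Deterministic functions of FD: rim ∝ FD, slice ∝ FD above trigger."""
        rim = self.rim_amp * self.fd
        slc = self.slice_amp * self.fd * (self.fd > self.slice_trigger)
        return {"rim": rim, "slice": slc}


@dataclass
class SubjectRecord:
    subject_id: str
    runs: list
    truths: list
    covariates: dict


@dataclass
class Cohort:
    template: PhantomTemplate
    subjects: list
    covariates: pd.DataFrame


@dataclass
class NodeCohort:
    """Lightweight node-level cohort for statistical calibration studies."""

    template: PhantomTemplate
    node_series: np.ndarray   # (n_subjects, n_nodes, n_frames)
    mean_fd: np.ndarray       # (n_subjects,)
    tsnr: np.ndarray          # (n_subjects,) from motion-free rendered runs
    tr: float


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------


def make_phantom(
    grid_shape: tuple[int, int, int] = (32, 32, 24),
    voxel_size: float | tuple[float, float, float] = 2.5,
    n_nodes: int = 10,
    seed: int = 0,
    parcel_radius_mm: float | None = None,
    max_tries: int = 50,
) -> PhantomTemplate:
    """Ellipsoidal brain with a grey-matter shell and disjoint parcels.

    The in-plane semi-axes are unequal so rotations are identifiable, and
    a smooth seeded texture is added inside the brain to give the
    realignment cost function sharp gradients.  Raises when the requested
    number of parcels (each >= 5 voxels) cannot be placed disjointly.
    """
    if any(s < 16 for s in grid_shape):
        raise ValueError("grid_shape must be at least 16 along each axis")
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    voxel_size = tuple(float(v) for v in voxel_size)
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    c = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    semi = np.array([0.44 * nx, 0.38 * ny, 0.42 * nz])
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    rho = np.sqrt(((ii - c[0]) / semi[0]) ** 2 + ((jj - c[1]) / semi[1]) ** 2
                  + ((kk - c[2]) / semi[2]) ** 2)
    brain = rho <= 1.0
    gm = (rho >= 0.60) & (rho <= 0.85)

    intensity = np.zeros(grid_shape)
    intensity[brain] = 600.0 + 400.0 * (1.0 - rho[brain] ** 2)
    texture = ndimage.gaussian_filter(rng.normal(size=grid_shape), sigma=1.5)
    intensity[brain] += 60.0 * texture[brain]
    intensity = np.clip(intensity, 0.0, None)

    if parcel_radius_mm is None:
        parcel_radius_mm = 2.2 * min(voxel_size)
    gm_idx = np.argwhere(gm)
    gm_mm = gm_idx * np.asarray(voxel_size)
    min_sep = 2.4 * parcel_radius_mm

    parcellation = None
    for _ in range(max_tries):
        order = rng.permutation(len(gm_idx))
        seeds: list[int] = []
        for cand in order:
            if len(seeds) == n_nodes:
                break
            if all(np.linalg.norm(gm_mm[cand] - gm_mm[s]) >= min_sep for s in seeds):
                seeds.append(cand)
        if len(seeds) < n_nodes:
            continue
        seed_mm = gm_mm[seeds]
        d = np.linalg.norm(gm_mm[:, None, :] - seed_mm[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        within = d[np.arange(len(gm_idx)), nearest] <= parcel_radius_mm
        labels = np.zeros(grid_shape, dtype=np.int32)
        ok = True
        for k in range(n_nodes):
            vox = gm_idx[within & (nearest == k)]
            if len(vox) < 5:
                ok = False
                break
            labels[tuple(vox.T)] = k + 1
        if ok:
            parcellation = labels
            break
    if parcellation is None:
        raise ValueError(
            f"cannot place {n_nodes} disjoint parcels (>=5 voxels each) "
            f"on grid {grid_shape}"
        )

    centroids = np.zeros((n_nodes, 3))
    for k in range(n_nodes):
        vox = np.argwhere(parcellation == k + 1)
        centroids[k] = vox.mean(axis=0) * np.asarray(voxel_size)

    tpl = PhantomTemplate(intensity, brain, gm, parcellation, centroids, voxel_size)
    tpl.validate()
    return tpl


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------


def simulate_motion_trace(
    n_frames: int,
    tr: float = 0.78,
    target_mean_fd: float = 0.5,
    event_rate: float = 0.12,
    event_amplitude: tuple[float, float] | None = None,
    jitter_sd: float | None = None,
    seed: int = 0,
    rotation_radius: float = DEFAULT_ROTATION_RADIUS,
) -> MotionTrace:
    """Six-parameter trace whose FD series mixes jitter and sparse events.

    Per-frame FD is half-normal jitter plus Poisson-thinned jumps with
    log-normal amplitudes (``event_amplitude = (mean_mm, log_sd)``); the
    defaults are calibrated so the realized mean tracks
    ``target_mean_fd`` with mean > median (right skew).  The generated
    displacement is split across the six parameters with mean-reverting
    signs so the head never drifts far from the reference.  The exact
    per-frame FD the generator produced is attached as ``fd_internal``.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if target_mean_fd <= 0:
        raise ValueError("target_mean_fd must be positive")
    rng = np.random.default_rng(seed)

    if event_amplitude is None:
        event_amplitude = (4.0 * target_mean_fd, 0.8)
    amp_mean, amp_logsd = event_amplitude
    if jitter_sd is None:
        jitter_mean = max(target_mean_fd - event_rate * amp_mean, 0.02 * target_mean_fd)
        jitter_sd = jitter_mean / np.sqrt(2.0 / np.pi)

    delta = np.zeros(n_frames)
    if jitter_sd > 0:
        delta[1:] += np.abs(rng.normal(0.0, jitter_sd, n_frames - 1))
    if event_rate > 0 and amp_mean > 0:
        hits = rng.random(n_frames - 1) < event_rate
        mu = np.log(amp_mean) - 0.5 * amp_logsd ** 2
        amps = rng.lognormal(mu, amp_logsd, n_frames - 1)
        delta[1:] += hits * amps

    params = np.zeros((n_frames, 6))
    for t in range(1, n_frames):
        w = rng.dirichlet(np.ones(6))
        cur = params[t - 1]
        signs = np.where(
            rng.random(6) < 0.7,
            np.where(cur == 0, np.where(rng.random(6) < 0.5, 1.0, -1.0), -np.sign(cur)),
            np.where(rng.random(6) < 0.5, 1.0, -1.0),
        )
        step = np.empty(6)
        step[:3] = signs[:3] * w[:3] * delta[t] / rotation_radius
        step[3:] = signs[3:] * w[3:] * delta[t]
        params[t] = cur + step

    trace = MotionTrace(params, tr)
    trace.fd_internal = delta  # generator's own FD bookkeeping
    return trace


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _bandpass_noise(n_frames: int, tr: float, rng: np.random.Generator,
                    band: tuple[float, float] = (0.01, 0.1)) -> np.ndarray:
    """Unit-sd noise band-limited to the resting-state band."""
    x = rng.normal(size=n_frames)
    nyq = 0.5 / tr
    lo, hi = band[0] / nyq, min(band[1] / nyq, 0.99)
    b, a = signal.butter(2, [lo, hi], btype="bandpass")
    y = signal.filtfilt(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _dropout_shift_mm(brain: np.ndarray, voxel_size, fraction: float) -> float:
    """Translation along +x pushing >= ``fraction`` of brain voxels off-grid."""
    xs = np.argwhere(brain)[:, 0].astype(float)
    nx = brain.shape[0]
    edge = np.quantile(xs, 1.0 - fraction)
    dvox = (nx - 1.0) - edge + 1.0  # +1 voxel margin past the boundary
    return float(dvox * voxel_size[0])


def render_run(
    template: PhantomTemplate,
    truth: GroundTruth,
    tr: float,
    seed: int = 0,
) -> Run:
    """Render one run: template + network (and confound) signals on the
    parcels, resampled under each frame's rigid-body motion, plus the
    FD-locked rim and slice-periodic artifacts, thermal noise, and the
    FOV dropout shift on the designated frames."""
    n = truth.n_frames
    if truth.network_timecourses.shape[1] != n:
        raise ValueError("network timecourses must match the trace length")
    if truth.dropout_frames and max(truth.dropout_frames) >= n:
        raise ValueError("dropout_frames outside the run")
    rng = np.random.default_rng(seed)
    shape = template.intensity.shape
    labels = template.node_labels
    parcel_vox = [np.nonzero(template.parcellation == lab) for lab in labels]

    from .denoise import rim_mask  # local import to avoid cycles at import time

    rim = rim_mask(template.brain_mask)
    brain_vox = template.brain_mask
    n_brain = int(brain_vox.sum())
    slice_pattern = template.brain_mask.copy()
    slice_pattern[:, :, np.arange(shape[2]) % SLICE_PERIOD != 0] = False

    shift = None
    if truth.dropout_frames:
        shift = _dropout_shift_mm(template.brain_mask, template.voxel_size,
                                  truth.dropout_fraction)

    data = np.empty(shape + (n,))
    gm_vox = np.nonzero(template.gm_mask)
    gm_mask = template.gm_mask
    net_w = None
    if truth.network_maps is not None:
        net_w = np.stack([m[gm_vox] for m in truth.network_maps])  # (K, n_gm)
    drive = truth.confound_amp * np.maximum(truth.fd - truth.confound_fd_floor, 0.0)

    # frame-specific smooth artifact fields, generated in one batch:
    # they inflate connectivity between nearby nodes on motion-corrupted
    # frames only, and are not low-rank, so component regression cannot
    # remove them
    conf_fields = None
    active = np.flatnonzero(drive > 0)
    if active.size:
        conf_sigma_vox = truth.confound_sigma_mm / min(template.voxel_size)
        white = rng.normal(size=shape + (active.size,))
        fields = ndimage.gaussian_filter(white, sigma=(conf_sigma_vox,) * 3 + (0,))
        sds = fields[gm_mask].std(axis=0)
        sds[sds == 0] = 1.0
        conf_fields = fields[gm_vox] / sds  # (n_gm, n_active)

    # thermal noise, slightly spatially correlated, batched over frames
    noise_block = None
    if truth.noise_sd > 0:
        noise_block = rng.normal(size=shape + (n,))
        if truth.noise_smooth_sigma > 0:
            noise_block = ndimage.gaussian_filter(
                noise_block, sigma=(truth.noise_smooth_sigma,) * 3 + (0,))
            sds = noise_block.reshape(-1, n).std(axis=0)
            sds[sds == 0] = 1.0
            noise_block /= sds
        noise_block *= truth.noise_sd

    active_pos = {int(f): i for i, f in enumerate(active)}
    for t in range(n):
        vol = template.intensity.copy()
        if net_w is not None:
            vol[gm_vox] += truth.network_amp * (
                truth.network_timecourses[:, t] @ net_w)
        else:
            for i, vox in enumerate(parcel_vox):
                vol[vox] += truth.network_amp * truth.network_timecourses[
                    truth.network_assignment[i], t]
        if truth.node_timecourses is not None:
            for i, vox in enumerate(parcel_vox):
                vol[vox] += truth.node_signal_amp * truth.node_timecourses[i, t]
        if t in active_pos:
            vol[gm_vox] += drive[t] * conf_fields[:, active_pos[t]]
        p = truth.trace.params[t].copy()
        if t in truth.dropout_frames:
            p[3] += shift
        vol = resample_rigid(vol, p, template.voxel_size)
        fdt = truth.fd[t]
        if fdt > 0:
            if truth.motion_noise_amp > 0:
                # spin-history-like unstructured residue across the brain
                vol[brain_vox] += rng.normal(
                    0.0, truth.motion_noise_amp * fdt, n_brain)
            vol[rim] += truth.rim_amp * fdt
            if truth.rim_noise_frac > 0:
                # unstructured (frame-specific) artifact residue: motion
                # artifact is not perfectly low-rank, so ICA regression
                # cannot remove all of it — as with real FIX cleanup
                vol[rim] += rng.normal(
                    0.0, truth.rim_noise_frac * truth.rim_amp * fdt, int(rim.sum()))
            if fdt > truth.slice_trigger:
                vol[slice_pattern] += truth.slice_amp * fdt
        if noise_block is not None:
            vol += noise_block[..., t]
        data[..., t] = vol
    return Run(data, tr, template.voxel_size)


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------


def network_weight_maps(
    template: PhantomTemplate,
    assignment: np.ndarray,
    length_mm: float = NETWORK_LENGTH_MM,
) -> np.ndarray:
    """Smooth grey-matter-wide weight field per network.

    Resting-state networks are spatially extended, so each network
    covers the grey-matter voxels nearest to its member nodes (the
    networks partition grey matter, mirroring a network atlas), with
    weight decaying exponentially with distance to the nearest node
    (weight 1 at the nodes).  Disjoint supports keep the spatial sources
    independent, which is what a spatial decomposition of the whole
    brain relies on.
    """
    gm_idx = np.argwhere(template.gm_mask)
    gm_mm = gm_idx * np.asarray(template.voxel_size)
    assignment = np.asarray(assignment)
    n_networks = int(np.max(assignment)) + 1
    dmin = np.full((len(gm_idx), n_networks), np.inf)
    for k in range(n_networks):
        cents = template.node_centroids[assignment == k]
        dmin[:, k] = np.linalg.norm(
            gm_mm[:, None, :] - cents[None, :, :], axis=2).min(axis=1)
    owner = dmin.argmin(axis=1)
    maps = np.zeros((n_networks,) + template.gm_mask.shape)
    for k in range(n_networks):
        sel = owner == k
        w = np.exp(-dmin[sel, k] / length_mm)
        # zero-mean over the territory (positive core, negative surround,
        # as in real ICA network maps); rescaled so nodes keep weight 1.
        m = w.mean()
        if m < 1.0:
            w = (w - m) / (1.0 - m)
        maps[k][tuple(gm_idx[sel].T)] = w
    return maps


def confound_node_covariance(template: PhantomTemplate,
                             sigma_mm: float = CONFOUND_SIGMA_MM) -> np.ndarray:
    """Node-level covariance implied by the smooth confound field: two
    nodes sample the same Gaussian random field, so their confound values
    correlate as exp(-d² / 4σ²) with internodal distance d."""
    d = template.node_distances()
    return np.exp(-(d ** 2) / (4.0 * sigma_mm ** 2))


def simulate_subject(
    template: PhantomTemplate,
    runs_per_subject: int = 2,
    n_frames: int = 330,
    tr: float = 0.78,
    target_mean_fd: float = 0.5,
    confound_strength: float = 1.0,
    artifact_scale: float = 1.0,
    dropout_rate: float = 0.005,
    noise_sd: float | None = None,
    n_networks: int = N_NETWORKS,
    seed: int = 0,
    render: bool = True,
) -> SubjectRecord:
    """Generate one subject's runs with known motion, artifacts, networks
    and motion-coupled confound.

    ``noise_sd=None`` draws a subject-level thermal noise level from
    Uniform(8, 12): real cohorts show between-subject tSNR variation
    unrelated to motion (coil loading, head size), which keeps the
    QC-FD correlations from degenerating into a pure-systematic limit.
    """
    rng = np.random.default_rng(seed)
    n_nodes = template.n_nodes
    n_networks = min(n_networks, n_nodes)
    assignment = np.arange(n_nodes) % n_networks
    net_maps = network_weight_maps(template, assignment)
    if noise_sd is None:
        noise_sd = float(rng.uniform(0.8, 1.2) * NOISE_SD)
    conf_amp = CONFOUND_AMP * confound_strength * target_mean_fd
    runs, truths = [], []
    for r in range(runs_per_subject):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        trace = simulate_motion_trace(
            n_frames, tr, target_mean_fd, seed=sub_seed)
        fd = trace.fd_internal
        rng_r = np.random.default_rng(sub_seed + 1)
        net_tcs = np.vstack([
            _bandpass_noise(n_frames, tr, rng_r) for _ in range(n_networks)])
        node_tcs = np.vstack([
            _bandpass_noise(n_frames, tr, rng_r) for _ in range(n_nodes)])
        n_drop = rng_r.binomial(n_frames - 1, dropout_rate)
        dropout = set(int(i) for i in
                      rng_r.choice(np.arange(1, n_frames), size=n_drop, replace=False))
        truth = GroundTruth(
            trace=trace, fd=fd, network_timecourses=net_tcs,
            network_assignment=assignment, network_maps=net_maps,
            node_timecourses=node_tcs,
            dropout_frames=dropout,
            noise_sd=noise_sd, subject_mean_fd_target=target_mean_fd,
            rim_amp=RIM_AMP * artifact_scale,
            slice_amp=SLICE_AMP * artifact_scale,
            rim_noise_frac=0.5 * artifact_scale,
            motion_noise_amp=10.0 * artifact_scale,
            confound_amp=conf_amp,
        )
        truths.append(truth)
        if render:
            runs.append(render_run(template, truth, tr, seed=sub_seed + 2))
    return SubjectRecord("sub", runs, truths, {"target_mean_fd": target_mean_fd})


def simulate_cohort(
    n_subjects: int = 30,
    runs_per_subject: int = 2,
    n_frames: int = 330,
    tr: float = 0.78,
    fd_range: tuple[float, float] = (0.15, 0.65),
    group_offset: float = 0.08,
    confound_strength: float = 1.0,
    artifact_scale: float = 1.0,
    dropout_rate: float = 0.005,
    n_nodes: int = 16,
    grid_shape: tuple[int, int, int] = (32, 32, 24),
    voxel_size: float = 2.5,
    seed: int = 0,
    template: PhantomTemplate | None = None,
    render: bool = True,
) -> Cohort:
    """Multi-subject cohort in a common (template) space.

    Per-subject target mean FD is drawn uniformly from ``fd_range`` and
    spans the censoring thresholds of interest; subjects are assigned to
    two groups balanced by motion rank, with group "B" receiving a
    constant FD offset (emulating a group-wise motion difference).  The
    motion-coupled connectivity confound scales with subject target FD ×
    ``confound_strength``.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    if template is None:
        template = make_phantom(grid_shape, voxel_size, n_nodes,
                                seed=int(rng.integers(0, 2**31 - 1)))
    base = rng.uniform(fd_range[0], fd_range[1], n_subjects)
    ranks = np.argsort(np.argsort(base))
    groups = np.where(ranks % 2 == 0, "A", "B")
    targets = base + np.where(groups == "B", group_offset, 0.0)
    ages = rng.uniform(6.0, 8.0, n_subjects)

    subjects = []
    rows = []
    for s in range(n_subjects):
        rec = simulate_subject(
            template, runs_per_subject, n_frames, tr,
            target_mean_fd=float(targets[s]),
            confound_strength=confound_strength,
            artifact_scale=artifact_scale,
            dropout_rate=dropout_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            render=render,
        )
        sid = f"sub-{s + 1:03d}"
        rec.subject_id = sid
        rec.covariates = {"subject": sid, "group": str(groups[s]),
                          "age": float(ages[s]),
                          "target_mean_fd": float(targets[s])}
        subjects.append(rec)
        rows.append(rec.covariates)
    return Cohort(template, subjects, pd.DataFrame(rows))


def simulate_node_cohort(
    n_subjects: int = 30,
    n_frames: int = 307,
    tr: float = 0.78,
    n_nodes: int = 16,
    confound_strength: float = 0.0,
    fd_range: tuple[float, float] = (0.15, 0.65),
    node_noise_sd: float = 2.5,
    seed: int = 0,
    template: PhantomTemplate | None = None,
) -> NodeCohort:
    """Node-level cohort for calibration of the group-level statistics.

    Each subject gets network time series plus node noise (and, if
    requested, the motion-coupled confound) directly at node level,
    together with a simulated motion trace for the FD covariate and a
    tSNR value computed from a motion-free rendered run.  With
    ``confound_strength=0`` the node data carry no motion dependence at
    all, which is the null the QC statistics are calibrated against.
    """
    from .qc import compute_tsnr

    rng = np.random.default_rng(seed)
    if template is None:
        template = make_phantom((32, 32, 24), 2.5, n_nodes,
                                seed=int(rng.integers(0, 2**31 - 1)))
    n_nodes = template.n_nodes
    Sigma = confound_node_covariance(template)
    L = np.linalg.cholesky(Sigma + 1e-9 * np.eye(n_nodes))
    n_networks = min(N_NETWORKS, n_nodes)
    assignment = np.arange(n_nodes) % n_networks

    # small motion-free run for per-subject tSNR, shared geometry
    tsnr_tpl = make_phantom((16, 16, 16), 2.5, 2, seed=int(rng.integers(0, 2**31 - 1)))

    series = np.empty((n_subjects, n_nodes, n_frames))
    mean_fd = np.empty(n_subjects)
    tsnr = np.empty(n_subjects)
    targets = rng.uniform(fd_range[0], fd_range[1], n_subjects)
    for s in range(n_subjects):
        sseed = int(rng.integers(0, 2**31 - 1))
        trace = simulate_motion_trace(n_frames, tr, float(targets[s]), seed=sseed)
        fd = trace.fd_internal
        mean_fd[s] = fd.mean()
        rng_s = np.random.default_rng(sseed + 1)
        nets = np.vstack([_bandpass_noise(n_frames, tr, rng_s)
                          for _ in range(n_networks)])
        x = NETWORK_AMP * nets[assignment]
        x = x + NODE_SIGNAL_AMP * np.vstack(
            [_bandpass_noise(n_frames, tr, rng_s) for _ in range(n_nodes)])
        if confound_strength > 0:
            drive = (CONFOUND_AMP * confound_strength * targets[s]
                     * np.maximum(fd - CONFOUND_FD_FLOOR, 0.0))
            field = L @ rng_s.normal(size=(n_nodes, n_frames))
            x = x + drive[None, :] * field
        x = x + rng_s.normal(0.0, node_noise_sd, x.shape)
        series[s] = x
        noise_sd = rng_s.uniform(0.8, 1.2) * NOISE_SD
        noise = rng_s.normal(0.0, noise_sd, tsnr_tpl.intensity.shape + (60,))
        small = Run(tsnr_tpl.intensity[..., None] + noise, tr, tsnr_tpl.voxel_size)
        tsnr[s], _ = compute_tsnr(small, tsnr_tpl.brain_mask)
    return NodeCohort(template, series, mean_fd, tsnr, tr)


# ---------------------------------------------------------------------------
# Disk output: NIfTI runs, FSL-dialect .par traces, TSV/JSON ground truth
# ---------------------------------------------------------------------------


def save_template(template: PhantomTemplate, outdir) -> None:
    import nibabel as nib
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.diag(list(template.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(template.intensity.astype(np.float32), aff),
             str(outdir / "template.nii.gz"))
    nib.save(nib.Nifti1Image(template.brain_mask.astype(np.uint8), aff),
             str(outdir / "brain_mask.nii.gz"))
    nib.save(nib.Nifti1Image(template.gm_mask.astype(np.uint8), aff),
             str(outdir / "gm_mask.nii.gz"))
    nib.save(nib.Nifti1Image(template.parcellation.astype(np.int16), aff),
             str(outdir / "parcellation.nii.gz"))
    np.savetxt(outdir / "node_centroids_mm.tsv", template.node_centroids,
               delimiter="\t", header="x\ty\tz", comments="")


def save_cohort(cohort: Cohort, outdir) -> None:
    """One directory per subject: run NIfTIs, .par traces, ground-truth
    TSVs and a JSON sidecar; covariates at the top level."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_template(cohort.template, outdir / "template")
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    for rec in cohort.subjects:
        sdir = outdir / rec.subject_id
        sdir.mkdir(exist_ok=True)
        for i, (run, truth) in enumerate(zip(rec.runs, rec.truths)):
            stem = f"run-{i + 1:02d}"
            run.save(sdir / f"{stem}_bold.nii.gz")
            write_par(truth.trace, sdir / f"{stem}.par")
            pd.DataFrame({"fd_mm": truth.fd}).to_csv(
                sdir / f"{stem}_fd.tsv", sep="\t", index=False)
            pd.DataFrame(truth.network_timecourses.T,
                         columns=[f"network_{k}" for k in
                                  range(truth.network_timecourses.shape[0])]
                         ).to_csv(sdir / f"{stem}_networks.tsv", sep="\t", index=False)
            meta = {
                "tr": run.tr,
                "dropout_frames": sorted(int(f) for f in truth.dropout_frames),
                "noise_sd": truth.noise_sd,
                "subject_mean_fd_target": truth.subject_mean_fd_target,
                "rim_amp": truth.rim_amp,
                "rim_noise_frac": truth.rim_noise_frac,
                "slice_amp": truth.slice_amp,
                "slice_trigger": truth.slice_trigger,
                "noise_smooth_sigma": truth.noise_smooth_sigma,
                "confound_amp": truth.confound_amp,
                "network_assignment": truth.network_assignment.tolist(),
            }
            with open(sdir / f"{stem}_truth.json", "w") as fh:
                json.dump(meta, fh, indent=1, sort_keys=True)
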