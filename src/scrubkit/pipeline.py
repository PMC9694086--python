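"""End-to-end orchestration: dummy discard → FD censoring → concatenation
→ FOV-outlier rejection → motion correction → intensity normalization →
ICA → component classification → aggressive cleanup → trim, plus
cohort-level sweeps over censoring thresholds and the group QC report.

Every acquired frame is accounted for exactly once in the final censor
plan (kept, or dropped as dummy/fd/fov/trim), and all randomness funnels
through the configuration seed, so a rerun with the same configuration
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import censoring, denoise, motion, qc
from .censoring import CensorPlan, InsufficientDataError
from .core import Run
from .motion import MotionTrace
from .phantom import Cohort, PhantomTemplate

__all__ = [
    "PipelineConfig",
    "SubjectResult",
    "CohortResult",
    "run_subject",
    "run_cohort",
    "sweep_thresholds",
]


@dataclass
class PipelineConfig:
    """All pipeline parameters; serializes losslessly to/from YAML."""

    fd_threshold: float | None = 0.3     # mm; None disables FD censoring
    n_dummy: int = 3
    duration: float = 240.0              # s of data retained for analysis
    z_cut: float = 4.0                   # FOV outlier cut, in sd of brain count
    n_components: int = 60
    rotation_radius: float = 50.0        # mm
    seed: int = 0
    tsnr_mode: str = "voxelwise"
    min_voxels: int = 5                  # node inclusion rule
    f_cut: float = 0.1                   # Hz, high-frequency feature cut
    slice_period: int = 4
    lowess_frac: float = 2.0 / 3.0
    ica_max_iter: int = 200
    ica_tol: float = 1e-3
    reestimate: bool = False             # re-estimate motion even if traces given
    min_segment_frames: int | None = None
    thresholds: tuple = (0.25, 0.3, 0.4, 0.5)

    def __post_init__(self) -> None:
        for name in ("duration", "z_cut", "n_components", "rotation_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fd_threshold is not None and self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be positive or None")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)


@dataclass
class SubjectResult:
    subject_id: str
    status: str                          # completed | excluded | failed
    reason: str = ""
    qc_row: dict = field(default_factory=dict)
    plan: CensorPlan | None = None
    cleaned: Run | None = None
    pre_cleanup: Run | None = None
    labels: denoise.ComponentLabels | None = None
    node_series_post: np.ndarray | None = None
    node_series_pre: np.ndarray | None = None
    kept_nodes: np.ndarray | None = None
    dvars_pairs: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)


@dataclass
class CohortResult:
    qc_table: pd.DataFrame
    edge_post: np.ndarray | None         # (n_completed, n_edges)
    edge_pre: np.ndarray | None
    edge_distances: np.ndarray | None
    qcfd_post: qc.QcFdEdgeResult | None
    qcfd_pre: qc.QcFdEdgeResult | None
    retention: pd.DataFrame
    group_stats: dict | None
    dvars_precensor: qc.DvarsFdRegression | None
    dvars_postcensor: qc.DvarsFdRegression | None
    subject_results: list
    report: dict


# ---------------------------------------------------------------------------


def run_subject(
    config: PipelineConfig,
    runs: list[Run],
    traces: list[MotionTrace],
    template: PhantomTemplate,
    subject_id: str = "sub",
    keep_images: bool = False,
    dvars_pre: tuple | None = None,
) -> SubjectResult:
    """Process one subject end to end.

    Insufficient retained data is a normal ``excluded`` status; geometry
    mismatches and other contract violations raise.
    """
    log: list = []
    if len(runs) != len(traces):
        raise ValueError("one motion trace per run required")
    if not runs:
        raise ValueError("need at least one run")
    log.append(("input", int(sum(r.n_frames for r in runs))))

    # 1. dummy discard, per run
    trimmed, ttraces = [], []
    for r, tr_ in zip(runs, traces):
        rr, tt = censoring.discard_dummies(r, tr_, config.n_dummy)
        trimmed.append(rr)
        ttraces.append(tt)
    log.append(("post_dummy", int(sum(r.n_frames for r in trimmed))))

    if config.reestimate:
        ttraces = [
            motion.estimate_rigid_motion(r, template.brain_mask,
                                         rotation_radius=config.rotation_radius)
            for r in trimmed
        ]

    # 2. FD + censoring per run
    fds = [motion.compute_fd(t, config.rotation_radius) for t in ttraces]
    if config.fd_threshold is None:
        keeps = [np.ones(r.n_frames, dtype=bool) for r in trimmed]
    else:
        keeps = [censoring.censor_by_fd(f, config.fd_threshold,
                                        config.min_segment_frames) for f in fds]

    # 3. concatenate
    concat, plan = censoring.concatenate_runs(
        trimmed, keeps, dummy_counts=[config.n_dummy] * len(runs),
        threshold_fd=config.fd_threshold)
    log.append(("post_censor", concat.n_frames))
    kept_params = np.concatenate(
        [t.params[k] for t, k in zip(ttraces, keeps)], axis=0)
    kept_fd = np.concatenate([f.fd[k] for f, k in zip(fds, keeps)])

    # pre-censoring DVARS diagnostic: per-run, on normalized uncensored
    # data, with field-of-view dropout frames excised (their intensity
    # collapse swamps the motion-variance relation being diagnosed).
    # Independent of the censoring threshold, so it can be supplied from
    # a previous run over the same subject.
    if dvars_pre is None:
        dv_pre_parts, fd_pre_parts = [], []
        for r, f in zip(trimmed, fds):
            _, fov_out = censoring.detect_fov_outliers(r, config.z_cut)
            sub = Run(r.data[..., ~fov_out], r.tr, r.voxel_size)
            norm_r = denoise.normalize_intensity(sub, template.brain_mask)
            dv_pre_parts.append(
                motion.compute_dvars(norm_r, template.brain_mask).dvars)
            fd_pre_parts.append(f.fd[~fov_out])
        dvars_pre = (np.concatenate(fd_pre_parts), np.concatenate(dv_pre_parts))
    full_fd, dv_pre = dvars_pre

    res = SubjectResult(subject_id, "running", plan=plan, stage_log=log)
    if concat.n_frames * concat.tr < config.duration:
        res.status = "excluded"
        res.reason = (f"retained {concat.n_frames * concat.tr:.1f}s "
                      f"< {config.duration:.1f}s")
        res.qc_row = {"subject": subject_id, "status": "excluded"}
        return res

    # 4. FOV outliers on the censored, concatenated data
    _, outliers = censoring.detect_fov_outliers(concat, config.z_cut)
    if outliers.any():
        plan.drop_output_frames(np.flatnonzero(outliers), "fov")
        concat = Run(concat.data[..., ~outliers], concat.tr, concat.voxel_size)
        kept_params = kept_params[~outliers]
        kept_fd = kept_fd[~outliers]
    log.append(("post_fov", concat.n_frames))
    if concat.n_frames * concat.tr < config.duration:
        res.status = "excluded"
        res.reason = "insufficient data after FOV rejection"
        res.qc_row = {"subject": subject_id, "status": "excluded"}
        return res

    # post-censoring DVARS on uncorrected data (so pre/post differ only by
    # censoring), paired with the original FD of the retained frames
    norm_cens = denoise.normalize_intensity(concat, template.brain_mask)
    dv_post = motion.compute_dvars(norm_cens, template.brain_mask)
    res.dvars_pairs = {
        "precensor": (full_fd, dv_pre),
        "postcensor": (kept_fd, dv_post.dvars),
    }
    del norm_cens

    # 5. motion correction of the surviving frames (cubic interpolation)
    corrected = motion.apply_rigid_motion(
        concat, MotionTrace(kept_params, concat.tr), invert=True, order=3)

    # 6. per-volume intensity normalization (in place on the fresh copy)
    normalized = denoise.normalize_intensity(
        corrected, template.brain_mask, inplace=True)

    # 7. ICA + classification + aggressive cleanup
    n_comp = min(config.n_components, normalized.n_frames - 1,
                 int(template.brain_mask.sum()) - 1)
    if n_comp < config.n_components:
        warnings.warn(f"reducing n_components to {n_comp}")
    comps = denoise.decompose_ica(
        normalized, template.brain_mask, n_comp, seed=config.seed,
        max_iter=config.ica_max_iter, tol=config.ica_tol)
    feats = denoise.extract_component_features(
        comps, template.brain_mask, template.gm_mask, normalized.tr,
        f_cut=config.f_cut, slice_period=config.slice_period)
    labels = denoise.classify_components(feats)
    cleaned = denoise.aggressive_cleanup(normalized, comps, labels)
    res.labels = labels

    # 8. trim both streams to the analysis duration
    cleaned_t, plan = censoring.trim_to_duration(cleaned, plan, config.duration)
    n_keep = cleaned_t.n_frames
    pre_t = Run(normalized.data[..., :n_keep], normalized.tr,
                normalized.voxel_size)
    kept_fd = kept_fd[:n_keep]
    log.append(("post_trim", n_keep))

    # QC row on the trimmed data
    tsnr_pre, _ = qc.compute_tsnr(pre_t, template.brain_mask, config.tsnr_mode)
    tsnr_post, _ = qc.compute_tsnr(cleaned_t, template.brain_mask, config.tsnr_mode)
    series_post, kept_nodes = qc.parcel_timeseries(
        cleaned_t, template.parcellation, config.min_voxels)
    series_pre, _ = qc.parcel_timeseries(
        pre_t, template.parcellation, config.min_voxels)

    res.status = "completed"
    res.qc_row = {
        "subject": subject_id,
        "status": "completed",
        "mean_fd": float(kept_fd.mean()),
        "tsnr_pre": tsnr_pre,
        "tsnr_post": tsnr_post,
        "retained_seconds": n_keep * cleaned_t.tr,
        "n_noise_components": int(labels.noise_indices.size),
    }
    res.node_series_post = series_post
    res.node_series_pre = series_pre
    res.kept_nodes = kept_nodes
    if keep_images:
        res.cleaned = cleaned_t
        res.pre_cleanup = pre_t
    return res


# ---------------------------------------------------------------------------


def _edge_matrix(series_list, centroids):
    edges = []
    dist = None
    for s in series_list:
        cm = qc.connectivity_matrix(s, centroids)
        e, d = cm.edges()
        edges.append(e)
        dist = d
    return np.asarray(edges), dist


def run_cohort(
    config: PipelineConfig,
    cohort: Cohort,
    fd_threshold: float | None = "config",
    dvars_cache: dict | None = None,
) -> CohortResult:
    """Run every subject at one censoring threshold and assemble the
    group-level QC-FD report."""
    if fd_threshold == "config":
        fd_threshold = config.fd_threshold
    cfg = dataclasses.replace(config, fd_threshold=fd_threshold)
    template = cohort.template
    results = []
    qc_rows = []
    fd_by_subject = {}
    groups = {}
    for rec in cohort.subjects:
        traces = [t.trace for t in rec.truths]
        r = run_subject(cfg, rec.runs, traces, template, rec.subject_id,
                        dvars_pre=(dvars_cache or {}).get(rec.subject_id))
        if dvars_cache is not None and "precensor" in r.dvars_pairs:
            dvars_cache.setdefault(rec.subject_id, r.dvars_pairs["precensor"])
        row = dict(r.qc_row)
        row.update({k: v for k, v in rec.covariates.items() if k != "subject"})
        qc_rows.append(row)
        results.append(r)
        # per-subject FD pooled over runs (post-dummy) for the retention sweep
        fd_all = []
        for t in rec.truths:
            tt = MotionTrace(t.trace.params[cfg.n_dummy:], t.trace.tr)
            fd_all.append(motion.compute_fd(tt, cfg.rotation_radius).fd)
        fd_by_subject[rec.subject_id] = np.concatenate(fd_all)
        groups[rec.subject_id] = rec.covariates.get("group", "A")

    qc_table = pd.DataFrame(qc_rows)
    completed = [r for r in results if r.status == "completed"]
    tr = cohort.subjects[0].runs[0].tr if cohort.subjects[0].runs else 0.78

    retention = censoring.subject_retention(
        fd_by_subject, list(cfg.thresholds), cfg.duration, tr, groups)

    edge_post = edge_pre = dist = None
    qcfd_post = qcfd_pre = None
    group_stats = None
    dv_pre = dv_post = None
    if len(completed) >= 5:
        centroids = template.node_centroids
        edge_post, dist = _edge_matrix([r.node_series_post for r in completed],
                                       centroids)
        edge_pre, _ = _edge_matrix([r.node_series_pre for r in completed],
                                   centroids)
        mean_fd = np.array([r.qc_row["mean_fd"] for r in completed])
        qcfd_post = qc.qcfd_edges(edge_post, mean_fd, dist, cfg.lowess_frac)
        qcfd_pre = qc.qcfd_edges(edge_pre, mean_fd, dist, cfg.lowess_frac)
        comp_table = qc_table[qc_table["status"] == "completed"]
        try:
            group_stats = qc.group_fd_stats(comp_table)
        except (ValueError, KeyError):
            group_stats = None
        dv_pre = qc.dvars_fd_regression(
            {r.subject_id: r.dvars_pairs["precensor"] for r in completed})
        dv_post = qc.dvars_fd_regression(
            {r.subject_id: r.dvars_pairs["postcensor"] for r in completed})
    else:
        warnings.warn("fewer than 5 completed subjects; group statistics skipped")

    n_edges = edge_post.shape[1] if edge_post is not None else 0
    band = qc.binomial_null_band(n_edges) if n_edges else (float("nan"),) * 2
    report = {
        "threshold": fd_threshold,
        "n_subjects": len(cohort.subjects),
        "n_completed": len(completed),
        "null_band_99": list(band),
        "proportion_significant_post": (
            qcfd_post.proportion_significant if qcfd_post else None),
        "proportion_significant_pre": (
            qcfd_pre.proportion_significant if qcfd_pre else None),
        "retention": retention.to_dict(orient="records"),
        "group_stats": group_stats,
        "manifest": {"config": cfg.to_dict(), "seed": cfg.seed},
    }
    if qcfd_post is not None:
        report["tsnr_fd_r_pre"] = qc.tsnr_fd_correlation(qc_table, "pre")[0]
        report["tsnr_fd_r_post"] = qc.tsnr_fd_correlation(qc_table, "post")[0]
        report["dvars_r2_precensor"] = dv_pre.pooled_r2
        report["dvars_r2_postcensor"] = dv_post.pooled_r2
        report["null_calibration_pass"] = bool(
            band[0] <= qcfd_post.proportion_significant <= band[1])
    return CohortResult(qc_table, edge_post, edge_pre, dist, qcfd_post, qcfd_pre,
                        retention, group_stats, dv_pre, dv_post, results, report)


def sweep_thresholds(
    config: PipelineConfig,
    cohort: Cohort,
    thresholds: list | None = None,
    include_uncensored: bool = True,
) -> dict:
    """Run the cohort at several censoring thresholds (optionally with no
    censoring at all) and collect one report per variant."""
    ths: list = list(thresholds if thresholds is not None else config.thresholds)
    variants: dict = {}
    cache: dict = {}
    if include_uncensored:
        variants["none"] = run_cohort(config, cohort, fd_threshold=None,
                                      dvars_cache=cache)
    for th in ths:
        variants[f"{th}"] = run_cohort(config, cohort, fd_threshold=th,
                                       dvars_cache=cache)
    add_stringent_proportions(variants, config)
    return variants


def add_stringent_proportions(variants: dict, config: PipelineConfig) -> None:
    """Cross-threshold edge comparison on a common subject set.

    Different thresholds retain different subjects, which confounds the
    comparison of significant-edge proportions with sample composition.
    Restricting every variant to the subjects that survive the strictest
    threshold (the "stringent sample") makes the comparison paired; each
    variant's report gains ``proportion_significant_stringent``.
    """
    numeric = [k for k in variants if k != "none"]
    if not numeric:
        return
    strictest = min(numeric, key=float)
    ref = variants[strictest]
    ref_ids = [r.subject_id for r in ref.subject_results
               if r.status == "completed"]
    if len(ref_ids) < 5:
        return
    for name, res in variants.items():
        completed = [r for r in res.subject_results if r.status == "completed"]
        ids = [r.subject_id for r in completed]
        sel = [i for i, sid in enumerate(ids) if sid in set(ref_ids)]
        if len(sel) < 5 or res.edge_post is None:
            continue
        mean_fd = np.array([completed[i].qc_row["mean_fd"] for i in sel])
        sub = qc.qcfd_edges(res.edge_post[sel], mean_fd, res.edge_distances,
                            config.lowess_frac)
        res.report["proportion_significant_stringent"] = (
            sub.proportion_significant)
        res.report["stringent_sample_n"] = len(sel)


def report_json(variants: dict, path=None) -> str:
    """Serialize a sweep's reports deterministically (sorted keys)."""
    payload = {name: res.report for name, res in variants.items()}
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
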