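# Methods

`scrubkit` implements a preprocessing strategy for resting-state fMRI in
populations that move a lot (young children, clinical cohorts): censor
individual volumes by framewise displacement, concatenate the surviving
frames across acquisition runs, reject frames in which the head has
partly left the field of view, and remove the remaining motion artifact
by regressing out noise components from a spatial ICA ("aggressive"
cleanup).  Its effectiveness is judged by quality-control-versus-motion
(QC-FD) statistics at the group level.  Because suitable pediatric data
cannot be redistributed, the package includes a synthetic cohort
generator with exact ground truth; every claim the test suite makes is a
claim about that generator's data.

## Motion metrics

**Framewise displacement.** For rigid-body parameters
(rotations rx, ry, rz in radians; translations tx, ty, tz in mm),

    FD(t) = |Δtx| + |Δty| + |Δtz| + R · (|Δrx| + |Δry| + |Δrz|),

with sphere radius R = 50 mm by default, FD(0) = 0.  Rotations are
applied about the volume center in x, y, z order; motion-parameter text
files use the FSL column layout (three rotation columns in radians, then
three translation columns in mm).

**DVARS.** Root mean square, over brain voxels, of the intensity
difference between consecutive volumes; zero at the first frame.

**Good-time monitoring.** Emulating real-time acquisition monitoring,
`accumulate_good_time` counts seconds of data with FD strictly below a
threshold (default 0.4 mm) toward a session target (default 240 s).
Strict inequality here; censoring itself removes frames whose FD
*exceeds* the threshold, i.e. keeps the boundary frame.  Both comparisons
are deliberate and are not interchangeable.

## Pipeline

Per subject: discard `n_dummy` (3) pre-steady-state volumes per run;
compute FD; drop frames with FD > threshold (0.25 / 0.3 / 0.4 / 0.5 mm
are the thresholds of interest, 0.3 the default; no neighbor expansion,
no minimum segment length by default); concatenate runs; reject frames
whose brain-voxel count deviates from the mean by more than 4 sd
(single-pass statistics; an iterative variant exists behind a flag);
motion-correct the survivors (cubic-spline resampling); normalize each
volume to a mean of 10,000 over brain voxels; decompose with spatial
ICA (fixed order, default 60); label components signal/noise by rule;
regress all noise time courses plus an intercept out of every voxel;
trim to the first floor(240/TR) frames.  A subject that cannot supply
240 s of surviving data is *excluded* — a normal status, not an error.
Brain extraction for the voxel-count check thresholds each volume at
0.35 × its 98th percentile and keeps the largest connected component.

Subjects with fewer retained seconds than the target are detected before
the expensive ICA stage.  Every acquired frame appears exactly once in
the censor plan with a reason (`dummy | fd | fov | trim`) or as kept.

## Component triage

Features per component (time courses normalized to unit variance):

* `edge_fraction` — share of absolute spatial weight in the brain-rim
  shell (outermost 2 voxels).
* `gm_overlap` — share in grey matter.
* `highfreq_fraction` — share of temporal power above 0.1 Hz.
* `slice_periodicity` — share of the slice-profile's off-DC power at the
  slice period (default every 4th slice) and its harmonics.
* `jump_score` — max |Δ time course| divided by the robust sd (1.4826 ×
  MAD) of the time course.  Normalizing by the course's own robust sd,
  rather than by the sd of its differences, makes a genuinely spiky
  course score high while an ordinary smooth course does not.

A component is noise iff any rule fires (edge > 0.35, slice > 0.30,
high-frequency > 0.50, jump > 6) *and* grey-matter overlap stays below
0.5.  The thresholds were calibrated once on generator output with known
labels (both censored and uncensored processing stages); they are
configuration, not constants.  Aggressive cleanup is full multiple
regression of all noise courses; residuals are exactly orthogonal to the
regressors, so cleanup can only reduce per-voxel temporal variance.

ICA is FastICA (whitening by eigendecomposition, fixed-point updates,
fixed seed); the order is a parameter rather than estimated.  Note that
regressing k nuisance courses out of n frames removes about k/n of *any*
signal's variance by chance alone; at the default 60 components on
~300-650 frames this is the same regressor-to-frame ratio as the
real-data setting the defaults mirror.  Tests that quantify network
preservation use an order matched to the phantom's true complexity
(~20 for seven networks plus artifacts), because an order far above the
true dimensionality measures this chance-removal floor, not
classification quality, while an order below it folds artifact residue
into the network components.

## QC-FD statistics

* tSNR: per-voxel mean/sd over time averaged over the brain mask
  (primary, `tsnr_mode="voxelwise"`); a global-time-series mode exists
  because the verbal definition is ambiguous.  All comparisons use one
  mode.
* Connectivity: per-parcel mean time series (parcels under 5 voxels
  dropped), Pearson correlations for all node pairs, centroid Euclidean
  distances.
* Edge-wise QC-FD: each edge's value correlated with subject mean FD
  across subjects (raw r, two-sided t-test, uncorrected); the reported
  proportion of edges with p < 0.05 has a 5 % chance benchmark, with a
  99 % binomial band used as the null reference.  Lowess (frac = 2/3)
  summarizes r against internodal distance.  Threshold sweeps
  additionally report the proportion on the "stringent sample" (the
  subjects surviving the strictest threshold), so cross-threshold
  comparisons are paired rather than confounded with sample
  composition.  Once censoring has driven the proportion to the chance
  floor, differences between thresholds are sampling noise of a
  binomial-like statistic and should not be over-read.
* Mean FD per subject is computed over the retained frames of the
  trimmed data.
* DVARS-FD: per-subject and pooled OLS.  The pre-censoring series is
  computed per run on normalized, uncorrected data with field-of-view
  dropout frames excised (their intensity collapse is a different
  phenomenon than the motion-variance relation being measured); the
  post-censoring series is computed on the spliced concatenated data,
  and each retained frame keeps its *original* FD value, so splice
  boundaries appear as high-DVARS / low-FD points, as in real spliced
  data.  Pre and post therefore differ only by censoring, not by
  interpolation.

## The synthetic cohort

The generator produces what the pipeline needs to be tested against:
multi-run sessions with exact ground truth for motion, artifacts,
networks and corrupted frames.

* **Anatomy.** Ellipsoidal brain (unequal in-plane semi-axes so
  rotations are identifiable) with smooth seeded texture, grey-matter
  shell, and ≥ 5-voxel parcels placed disjointly on the shell; default
  grid 32×32×24 at 2.5 mm.
* **Motion.** Per-frame FD = half-normal jitter + Bernoulli jump events
  (rate 0.12/frame, log-normal amplitudes with mean 4 × the subject
  target), split across the six parameters with mean-reverting signs.
  Defaults are calibrated so a target of 0.5 mm produces mean ≈ 0.50 mm
  and median ≈ 0.25 mm per frame — the right-skewed profile of a
  high-motion pediatric cohort.
* **Networks.** Seven networks (the canonical resting-state count) partition grey matter (each voxel joins
  the network of its nearest node) with weight decaying away from the
  nodes and a zero-mean profile per territory (positive core, negative
  surround, like real ICA maps; this also keeps the per-volume
  normalization from coupling network activity into the global scale).
  Band-limited (0.01-0.1 Hz) unit-variance time courses at amplitude 50;
  each node additionally carries idiosyncratic band-limited activity
  (amplitude 18) so within-network edges sit near r ≈ 0.8 rather than at
  the degenerate r = 1 ceiling.
* **Artifacts**, all deterministic functions of FD(t): a brain-rim rim
  artifact (80 × FD intensity units) plus an *unstructured* rim residue
  (sd 0.5 × 80 × FD), brain-wide unstructured residue (sd 10 × FD), and
  an every-4th-slice pattern (60 × FD) active above a 0.5 mm trigger.
  The unstructured parts make the artifact not perfectly low-rank:
  component regression removes the structured part (as FIX does) but a
  motion-scaled residue remains, which is what keeps post-cleanup tSNR
  negatively related to motion, as observed in real cohorts.
* **FOV dropouts.** Designated frames are rendered with a translation
  pushing ≥ 25-30 % of brain voxels off the grid while the motion trace
  stays quiet — exactly the frames only a brain-voxel-count check can
  catch.
* **Connectivity confound.** On frames with FD > 0.2 mm, a
  frame-specific Gaussian random field (correlation length 12 mm,
  amplitude ∝ supra-threshold FD × subject target FD × strength) is
  added to grey matter.  Being frame-specific it is not low-rank, so ICA
  cleanup cannot remove it; being smooth it inflates connectivity
  between nearby nodes preferentially (the short-distance QC-FD
  signature); being gated on supra-threshold FD, censoring removes it.
* **Between-subject variation.** Per-subject thermal noise level ~
  Uniform(8, 12) intensity units (real cohorts vary in tSNR for reasons
  unrelated to motion; without this, post-cleanup correlations would
  degenerate into whatever tiny systematic effect remains).  Thermal
  noise is slightly spatially correlated (Gaussian σ = 0.6 voxel),
  as reconstructed scanner noise is.
* **Cohorts.** Per-subject target mean FD ~ Uniform(0.15, 0.65) mm
  (spanning the censoring thresholds of interest), two groups balanced
  by motion rank with a +0.08 mm offset for group B (emulating a
  group-wise motion difference), ages ~ Uniform(6, 8) years.

What the generator does **not** emulate: real anatomy, EPI distortion,
physiological (cardiac/respiratory) signal, slice-timing effects,
scanner drift, or between-session registration error.  Passing tests
demonstrate that the pipeline's logic and statistics behave correctly
when the data match the generator's assumptions; they do not certify
performance on real data.

## Null calibration

The null hypothesis behind the QC-FD statistics is "data unaffected by
motion".  Null cohorts are therefore generated at node level (network +
node + noise series with no motion coupling; motion traces simulated
only to supply the FD covariate; per-subject tSNR computed from a
motion-free rendered run).  Rendering motion into null images would
introduce genuine motion effects — interpolation smoothing raises tSNR
with motion, misalignment lowers it — which are not false positives of
the statistics being calibrated.  With 30 subjects the null sampling sd
of a correlation is ≈ 0.19, so |r| < 0.3 is expected to fail in roughly
one seed in ten even under a perfect null; the pooled significant-edge
proportion is the sharper calibration check.

## Problem sizes and numerical choices

Test and acceptance scales, chosen to keep the whole suite comfortably
runnable on a single CPU: cohort experiments use 30 subjects × 2 runs ×
330 frames (TR 0.78 s; ~64 s per run longer than the 4-minute analysis
target, so mid-motion subjects retain enough frames at 0.3 mm);
determinism is demonstrated on a 6-subject cohort; component-recovery
checks use single runs of ~220 frames.  Rigid-body estimation is a
coarse translation search plus Powell refinement on a cost with
rotations scaled by the sphere radius; the recovery tolerances
(0.25 mm / 0.005 rad) are a tenth of the voxel size.  Trilinear
interpolation is used for rendering and estimation, cubic spline for the
final motion correction.  Constant series are detected with exact
range checks (`ptp == 0`), not floating-point standard deviations.
Collinear noise regressors are dropped by QR diagnostics before the
cleanup regression; normal equations are safe afterwards.

## Known limitations

* The rule-based component classifier is calibrated to this generator's
  artifact morphology; real data would require re-tuning or a trained
  classifier.
* Aggressive cleanup at order 60 removes ~20 % of any genuine signal's
  variance by chance (regressor-to-frame ratio); this is inherent to
  the approach, not a defect of the implementation.
* The FOV brain-count extractor is an intensity heuristic, not a brain
  extraction tool; it is adequate for phantom geometry.
* Distances are Euclidean in the common synthetic space; no nonlinear
  template registration is performed.
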