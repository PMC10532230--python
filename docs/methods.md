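# Methods

## Problem setting

Given a cohort of in-distribution (ID) 3D scans — the data a downstream
model was trained on — the task is to emit one scalar OOD score per test
scan, higher meaning more likely out-of-distribution, without assuming
anything about the anomaly source. Evaluation treats accepted-ID as the
positive class: FPR@TPR95 is the fraction of OOD scans accepted at the
score threshold that accepts 95 % of ID scans (random guessing ≈ 0.95),
and AUROC is the probability a random OOD scan outscores a random ID scan
(ties ½).

## The detector

**Preprocessing.** All volumes are trilinearly resampled to a common
spacing (default 1×1×1.5 mm, a typical cohort-median spacing), intensity-
clipped — CT to the fixed [−1350, 300] HU lung window, MRI to the per-image
[1st, 99th] percentiles since MRI units are scanner-arbitrary — and MinMax-
scaled to [0, 1]. The stage order is fixed; clipping before scaling makes
the [0, 1] output range unconditional. Masks are resampled with
nearest-neighbor interpolation. Output shape follows
round(n·s_in/s_target), half away from zero, minimum one voxel; the
interpolation grid aligns voxel centers at physical position i·s and
extends edge values where the output grid overshoots. A constant image
scales to all zeros so the histogram stays defined. MinMax uses the
image's own post-clip extrema rather than the window bounds: one rule
serves both modalities, and whenever the window endpoints are realized in
the image (air and bone in CT) the two choices coincide up to an affine
map, which the downstream histogram treats identically.

**Embedding.** The intensity probability density over m equal bins on
[0, 1] (left-closed/right-open, last bin closed), stored as densities
count·m/N so that sum/m = 1 exactly. Default m = 150; quality is fairly
flat in m, with a mild preference for more bins.

**Reduction.** PCA is fitted once on the training embeddings, keeping the
smallest k whose cumulative explained-variance ratio reaches v (default
99.99 %), capped at min(n−1, m); v = 1 keeps the numerical rank. It is
implemented directly via the SVD of the centered embedding matrix, which
makes the ≥-v selection rule and the v = 1 rank case explicit; tests
cross-check the retained variance against an independent
eigendecomposition. With zero-variance training data a single arbitrary
orthonormal direction is kept.

**Scoring.** Mahalanobis distance to the training mean under the
divisor-n (population) covariance of the reduced embeddings, or Euclidean
distance to the nearest reduced training embedding. The covariance gets a
ridge ε·(trace Σ̂/k)·I with ε = 1e−6 (pure ε·I for a zero-variance
cohort) and is Cholesky-factorized once; scores use triangular solves,
never an explicit inverse. Both the fit and scoring paths are
deterministic.

## Predicted-volume baseline

The only feature is the physical volume (mm³) of a downstream model's
binary prediction. The two-sided decision flags a scan whose volume falls
strictly below the q/2-th or strictly above the (100−q/2)-th percentile of
the ID volumes (linear-interpolation percentiles), retaining ≈100−q % TPR.
For ranking metrics the rule is scalarized as |F̂(vol) − ½| under the
mid-rank empirical CDF F̂(v) = (#{x<v} + ½·#{x=v})/n — continuous in the
tails, zero at the median, and consistent with the two-sided decision away
from percentile boundary ties.

## Synthetic corruptions

Six seeded, deterministic corruption families emulate acquisition
artifacts at five perceptual severity levels. The per-level parameter
tables live in `ihf3d.anomalies.SEVERITY_TABLES`; they are this package's
own calibration (level 1 barely visible against the phantom noise floor,
level 5 heavily distorted), chosen once and fixed:

| kind | parameter(s) | levels 1 → 5 |
|---|---|---|
| local_noise | blur σ (vox) / gamma / noise sd (× range) | 0.5→8 / 1.3→4.5 / 0.02→0.4 |
| elastic | max control-point displacement (vox, 8³ grid) | 1, 2, 4, 8, 16 |
| kspace | spike count / sinusoid amplitude (× mean) | 1→16 / 0.05→0.8 |
| anisotropy | down/upsampling factor (one random axis) | 2, 3, 4, 6, 8 |
| ghosting | ghost weight w / ghost count G | 0.05→0.5 / 2→4 |
| motion | rigid copies T / rotation (°) / translation (vox) | 1→3 / 1→15 / 0.5→8 |

Implementation notes: local corruptions confine all changes to one random
axis-aligned crop (0.1–0.5 of each axis); for a constant input the
intensity range degenerates and the noise sd falls back to a unit range so
the corruption remains meaningful. Elastic displacements are trilinearly
upsampled from the control grid, which bounds the dense field by the
control magnitude. K-space spikes avoid the DC bin, so the mean intensity
is preserved; the inverse transform's real part is kept. Anisotropy
downsamples by slicing (every f-th sample) and upsamples linearly
(floor-nearest optionally). Ghosting blends G circularly shifted copies at
weight w/G with shift round(n/(G+1)). Motion replaces T k-space segments
along one axis with spectra of rigidly perturbed copies (rotation about
the center around a random axis pair, plus translation). Outputs are not
clipped to the input intensity range: noise and spike corruptions
legitimately exceed it, and clipping would silently null them on
low-contrast inputs. Mean absolute deviation from the input is
non-decreasing in the severity level for every kind (averaged over seeds);
this is enforced by test.

## Phantom generator

Phantoms emulate the *statistics* of a homogeneous imaging cohort, not
anatomy: an ellipsoidal body (level 100, MRI-like arbitrary units) on a
darker background (level 20), 2–6 small Gaussian lesions (peak 160 ± 10,
σ 1.5–2.5 vox), voxel noise sd 5, default grid 64×64×48 at 1×1×1.5 mm.
Body semi-axes jitter by ±2 % and lesions stay well below 1 % of the
volume; both bounds matter because the per-image 99th-percentile clip
makes the embedding sensitive to the bright-tail mass — with these
defaults the ID embedding cloud is at least 5× tighter (mean pairwise L2)
than its distance to the shifted arms, which is what makes the end-to-end
detection checks stable.

Three shift families emulate clinically motivated OOD axes:
`intensity_shift` adds a constant to the tissue levels only (body +
lesions, not the air background — a truly global offset would be removed
exactly by per-image MinMax scaling); `contrast_change` applies a gamma
curve to the normalized intensities; `anatomy_change` swaps the ellipsoid
for a box-like superellipsoid. The default shift magnitude is 3× the
noise sd. Fixtures derive per-volume seeds from one base seed via a seed
sequence, so train and test arms never share a stream.

What phantom experiments do **not** show: real scanner physics, anatomy,
pathology variability, or inter-site protocol diversity. Passing here
demonstrates the pipeline's correctness and its sensitivity to controlled
intensity-distribution shifts — not clinical performance.

## Benchmark harness

A run fits the detector exactly once on the ID training cohort, scores the
ID test cohort once, and evaluates every challenge against that single
score set — one acceptance threshold governs all challenges. Severity
sweeps corrupt copies of the ID test volumes per (kind, level) cell. The
cross-method audit computes pairwise Fechner correlations — mean sign
agreement of deviations from the mean, with zero deviations neutral —
over per-challenge FPR vectors (per-sample scores would be an alternative;
the per-challenge convention is what the harness documents and tests).

## Numerical and statistical choices

- FPR threshold: τ is the smallest ID score with acceptance fraction ≥
  the target TPR; scores exactly at τ are accepted, guaranteeing ID
  acceptance ≥ TPR on finite samples.
- AUROC via average ranks (ties ½), equivalent to all-pairs enumeration.
- With a 30-scan ID test set, τ is the 29th order statistic, so the FPR of
  an identically distributed arm follows a Beta(29, 2) distribution (mean
  ≈ 0.935, sd ≈ 0.044). The control-arm check therefore averages 10
  independently re-drawn (ID test, control) replicates; a single
  replicate would violate a ±0.05 band around 0.95 about one time in
  five for *any* correct implementation.
- Problem sizes in tests and the reproduction script (50/30/30 cohorts,
  full-size 64×64×48 phantoms for end-to-end checks, 32×32×24 for unit
  fixtures) keep the whole suite at desk scale while leaving the
  statistical conclusions stable across seeds.

## Known limitations

- The MRI percentile clip is per-image; cohort-level normalization
  (e.g. histogram matching to a template) is out of scope.
- No DICOM input, no anatomical reorientation, no 4D support; NIfTI only,
  with spacing the only header field used by computation.
- The Volume baseline requires externally produced prediction masks; this
  package does not train or ship a segmentation model.
- Corruption parameterizations are perceptual calibrations, not physical
  simulations of MRI sequences or CT reconstruction.
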