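# Methods

## The transition-matrix model

Two feature representations of the same m samples are given: a latent
matrix A (m × k, typically activations of a trained network's penultimate
layer) and an interpretable matrix B (m × l, expert-defined measurements).
The model assumes an approximately linear relation A T ≈ B and estimates the
k × l transition matrix T as the Frobenius-optimal least-squares solution

T = A⁺ B,

with A⁺ the Moore–Penrose pseudo-inverse computed from the thin SVD
A = U Σ Vᵀ.  Row-vector, right-multiplication orientation is used
throughout: a single latent observation is a row a, and its translation is
b = a T.  (The square, invertible case T = B A⁻¹ is the motivating special
case; the pseudo-inverse generalizes it to arbitrary m, k, l and rank.)

Because T is the minimum-norm least-squares solution, it is exact whenever
B actually is a linear image of A of admissible rank, and otherwise the
best linear surrogate; the fit records the residual ‖AT − B‖_F and the
effective rank rather than imposing a pass/fail threshold, since no
universal "good enough" residual exists across feature systems.

Numerical choices:

* **Singular-value cutoff.** Exact zeros do not occur in floating point;
  σᵢ ≤ rcond · σ₁ are treated as zero, with rcond defaulting to
  max(m, k) · ε (machine epsilon).  The cutoff, kept mask, and spectrum are
  exposed on the result object.
* **Never materialize A⁺ for fitting.** T is formed directly from the SVD
  factors as V_r ((U_rᵀ B) / s_r), identical to the naive product within
  rounding but O(mkl) rather than O(mk·m) in memory for the explicit A⁺
  route.
* **Optional column standardization** (off by default): latent activations
  and expert features live on incommensurate scales; when enabled, both
  matrices are z-scored before the fit and the stored moments are re-applied
  on mapping, so callers always see original units.  Raw fitting is the
  default because the plain least-squares solution is already
  scale-equivariant in B.
* **Pairing is enforced, not assumed.** A fit refuses matrices whose sample
  identifier sequences differ — both matrices must come from the same
  samples in the same order, which is the one precondition the method
  cannot verify from the numbers themselves.

## Agreement evaluation

Explanation fidelity is measured with Cohen's kappa between two label
sequences (e.g. decisions from mapped features vs decisions from true
features): κ = (Pₒ − Pₑ)/(1 − Pₑ), with Pₒ the observed agreement
(trace of the confusion matrix over N) and Pₑ the chance agreement from
the marginals (Σᵢ rᵢcᵢ/N²).  The generic K-class form reduces exactly to
the familiar TP/FP/TN/FN expressions at K = 2.

The 95% CI uses the Fleiss–Cohen–Everitt large-sample standard error
(deterministic, standard); a percentile bootstrap over label pairs (B =
2,000, seeded) is available for sparse tables.  The p-value is a two-sided
Wald test of κ = 0 using the null-hypothesis standard error.  CI endpoints
are clamped to [−1, 1].  When both raters are constant and identical,
Pₑ = 1 and κ is undefined; this is raised as a distinct degenerate-case
error rather than returned as NaN.

## ECG expert features (PVC)

The unit of analysis is a beat triad: the beat under examination plus its
neighbours.  Three features, all deterministic threshold rules with every
constant configurable:

* **Absent P wave** — search window [r − 0.28 s, r − 0.06 s] before the
  main R peak, 20 ms moving-average smoothing; "present" iff a local
  maximum with prominence ≥ 8% of the R amplitude exists.  The fraction is
  relative, so the rule is amplitude-scale invariant.
* **QRS duration** — onset/offset are the threshold crossings at 15% of the
  R envelope amplitude on the smoothed signal within ±200 ms of the peak;
  the signal is smoothed *before* rectification so zero-mean noise averages
  out instead of inflating the envelope floor.  Wide iff ≥ 120 ms
  (inclusive, the clinical guideline boundary).  QRS "deformity" is
  operationalized as width alone; morphology scoring is out of scope.
* **Compensatory pause** — full iff |2·RRn − (RRprev + RRnext)| <
  tolerance (strict inequality).  RRn is the mean RR over *consecutive
  pairs of normal beats*.  The default tolerance is relative, 10% of
  2·RRn, which adapts across heart rates; an absolute override exists.
  When an extrasystole is immediately followed by another extrasystole the
  pause cannot be read from the rhythm; the feature is "not evaluated" and
  only the last extrasystole of a run is assessed.

The numeric encoding in matrix B keeps the tri-state pause real-valued:
full = 1, not full = 0, not evaluated = 0.5.  The default PVC rule is the
conjunction: P absent AND QRS ≥ 120 ms AND pause ∈ {full, not evaluated},
expressed as per-feature intervals so the 0.5 encoding makes run-interior
extrasystoles pass the pause criterion by construction.  Rules are fully
configurable interval sets combined by AND or majority.

When beat labels are absent, RRn is estimated by a two-pass scheme: a
provisional pass with the all-beats mean RR tags PVC-like beats, and RRn is
re-estimated over the remainder.  R-peak annotations are authoritative when
present; the built-in detector (rectified-signal peaks with a refractory
distance) exists only for unannotated synthetic records.

ECG I/O is plain CSV (one sample per line) plus a JSON annotation file
{fs, r_peaks, labels}; MIT-BIH-style single-letter symbols are mapped to
beat classes through a configurable table.

## MRI geometric features

From ED/ES integer label volumes (ACDC convention by default: 1 = RV
cavity, 2 = myocardium, 3 = LV cavity) with voxel spacing in mm:

* volumes are voxel counts × voxel volume (mL);
* EF = (EDV − ESV)/EDV × 100%;
* myocardial mass = volume × density, 1.05 g/mL default (standard tissue
  density, configurable);
* wall thickness per short-axis slice = 2 × the Euclidean distance
  transform of the myocardium mask sampled at its medial-axis voxels
  (anisotropic in-plane sampling respected; the skeletonization uses a
  fixed tie-break seed because the protocol must be deterministic).  A
  radial ray-casting variant is available behind a switch.  Per-slice means
  and population SDs are aggregated with equal slice weights into max/mean/
  SD combinations; population SD with equal weights is a protocol choice,
  stated rather than hidden.

The 20-feature vector uses straight quotients for the ratios; ratios with
an empty denominator structure propagate as missing values and such rows
are dropped (and counted) before fitting, since the pseudo-inverse requires
finite entries.  The DCM rule is LVEF < 45% (strict) AND LVEDV above an
absolute threshold, default 190 mL — body-surface-area indexing would be
clinically preferable but requires patient height/weight, which
segmentation masks do not carry, so absolute volumes are used and the
threshold is exposed.

## Synthetic data: what it emulates and what it does not

* **Paired matrices** (`gen_latent_pair`): expert rows cluster around
  class-specific centers (center spread 3.0, within-class sd 0.5 by
  default, 2 classes); latent rows are a random full-rank expansion
  A = B W_r + noise, with an optional mild tanh mix to probe nonlinearity.
  This preserves exactly the structure the method assumes — a recoverable
  (approximately) linear relation — and records W_true = pinv(W_r), the
  exact minimum-norm map in the noise-free case.  It does *not* emulate a
  trained network's feature geometry: real penultimate layers are only
  locally linear at best, so passing tests show correctness of the
  estimator, not that any particular network is linearly explainable.
* **ECG rhythms** (`gen_ecg_triads`): each beat is a sum of Gaussian bumps
  (P at −160 ms, R, T at +250 ms); PVCs have no P bump, a wide R (planted
  width defined as the full width at 15% of peak, matching the
  measurement's 15% threshold), premature timing at 0.8·RRn and a
  following interval of (2 − 0.8)·RRn, so the planted pause is exactly
  full.  Defaults: fs 360 Hz, RR 0.8 s, normal/PVC widths 80/150 ms,
  P amplitude 0.15, additive Gaussian noise sd 0.05 (relative to unit R).
  No baseline wander, muscle artifact, or morphology variability — the
  generator tests the rules' logic and noise robustness, not clinical
  detector performance.
* **Mask phantoms** (`gen_cardiac_phantom`): LV cavity as a digitized
  cylinder per phase, myocardium as a concentric shell (scalar or per-slice
  thickness), RV as a disjoint ellipsoid scaled to a target volume;
  defaults plant LV 150/60 mL (EF 60%), wall 10 mm, RV 120 mL with RVEF
  50%.  All truths are closed-form.  Real ventricles are neither cylinders
  nor constant-walled; the phantoms validate the measurement operators, not
  anatomical realism.

All generators are pure functions of their spec (one seeded RNG per call);
repeated calls are bit-identical.

## Embedding alignment check

Before fitting, the class structure of A and B can be compared visually and
numerically: exact PCA (deterministic, sign-fixed so the largest-magnitude
loading of each component is positive) or seeded t-SNE (perplexity 30
default) to 2–3 dimensions, per-embedding silhouette over the class labels,
and orthogonal Procrustes disparity between the two point clouds
(similarity-invariant).  The report is advisory only; no threshold gates
the fit, because the judgment "relative positions match" has no canonical
cutoff.

## Problem sizes and defaults used in the shipped evaluations

The test suite and `scripts/acceptance.py` run entirely on synthetic data
at desk scale, chosen to exercise every code path with comfortable
statistical margins: 50 random matrices up to 40 × 40 with mixed ranks for
pseudo-inverse identities; ~500 beats (334 normal, 167 PVC, noise sd 0.05)
for rule recovery; a 512 × 320 × 10 phantom at 0.5 mm in-plane spacing for
volumetrics; and 10 simulations of m = 500, k = 64, l = 6 at noise sd 0.1
for the end-to-end mapped-decision kappa (80/20 train/test split, interval
rule thresholding the most class-separating expert feature at the midpoint
between cluster centers).

## Known limitations

* The mapping is linear by design; systematically nonlinear
  latent-to-expert relations surface only as a large residual, not as a
  better model.  Ridge or kernel variants are deliberately out of scope.
* Feature extraction constants (P-window, thresholds, tolerance) are
  guideline-shaped defaults validated on synthetic morphology; clinical
  deployment would require tuning against annotated recordings.
* The QRS width measurement carries a small systematic bias relative to the
  planted analytic width (smoothing and discrete crossings); it is well
  inside the ±15 ms envelope the tests assert, and identical for all beats,
  so downstream wide/narrow decisions are unaffected.
* Wall thickness via medial-axis EDT underestimates near skeleton spurs at
  voxel scale; agreement with annulus truth is within one voxel diagonal.
* WFDB-format ECG input is not supported; records are ingested as CSV +
  JSON annotations.
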