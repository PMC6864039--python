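# Methods

`mpmap` implements a voxel-wise multiscale mapping pipeline that predicts four
binary microscopic/molecular tumor properties — IDH1-R132H mutation (IDH1),
MGMT promoter methylation (MGMT), cellular necrosis (CNEC) and microvascular
proliferation (MVP) — at every brain voxel from five co-registered MR
contrasts (T1w, T1w post-gadolinium, T2w, T2-FLAIR, ADC), and a seeded
synthetic phantom cohort that exercises every stage against known ground
truth.

## Data model and normalization

All volumes of one patient live on a single axis-aligned grid
(`x_world = origin + index * spacing`, voxel-center convention, units mm).
Each contrast is divided by its mean inside a spherical "uninvolved white
matter" reference ROI, so tissue intensities are expressed as fractions of
white matter (WM mean = 1 exactly after normalization; the operation is
idempotent and invariant to positive rescaling of the raw data). Biopsy cores
are modeled as spheres around the needle tip with radius `(3V/4π)^(1/3)` from
the pathology-reported core volume `V`; a voxel belongs to a core iff its
center lies within the closed ball. Outcomes a pathologist elected not to
test ("triage") are recorded as negative, with provenance kept per row.

## Feature matrices and background distributions

Every in-sphere voxel of every core contributes one row: five normalized
contrast values, the patient id, four binary outcome flags, and per-outcome
tested/triaged provenance. Voxels covered by overlapping cores appear once
per core, preserving the specimen-to-voxel mapping. Cohort background
distributions `q = (q_pos, q_neg)` per outcome are voxel-count fractions over
the pooled matrix (tested + triaged rows), computed once on the full cohort —
not per cross-validation fold — mirroring the study design; this is a mild,
deliberate information leak, documented here.

## Sub-hypothesis 1: weighted logistic screen

Each outcome is regressed on the five contrasts by maximum-likelihood logit
with rows weighted by the inverse of their class's sample fraction (weighted
class masses equal), fit via IRLS (statsmodels GLM, ≤100 iterations,
tolerance 1e-8). Reported per outcome: the joint 5-df Wald chi-square of the
contrast coefficients under an HC0 (Huber-White) sandwich covariance,
McFadden's pseudo R² = 1 − llf/llnull against an intercept-only weighted
fit, and per-contrast coefficients with robust SEs. Perfect separation is
flagged, never silently truncated.

*Caveat (clustering).* Voxel rows within a patient are strongly dependent:
they share the patient's WM-normalization factor (whose sampling noise is a
few percent) and spatially smooth noise. A voxel-level logit ignores this, so
even a label-free cohort shows pseudo R² of roughly 0.01–0.05 (worst when an
outcome has only one or two positive patients, which the fit can "identify").
Wald p-values are therefore anti-conservative at the patient level; the
screen is a feasibility check, not confirmatory inference.

## Sub-hypothesis 2: wKNN, Pearson chi-square, per-patient BH

Leave-one-patient-out: for each held-out patient, a weighted k-nearest-
neighbor classifier trained on all other patients' biopsy voxels returns a
two-element class-membership probability per voxel — the class-wise sum of
inverse Euclidean distances over the k nearest neighbors in the 5-D contrast
space, normalized by the total. No feature scaling beyond WM normalization is
applied. Determinism rules: distance ties at the k-th neighbor expand the
neighbor set to the whole tie group (overlapping cores duplicate voxels, so
exact ties are routine); zero-distance neighbors take the inverse-distance
limit (probability mass split uniformly over the zero-distance labels).
One neighbor search serves all outcomes and the entire k grid via cumulative
weight sums; large searches pre-select candidates in float32 with a 16-
neighbor margin and re-rank them in float64, which is exact in practice and
halves the dominant selection cost.

Predicted probabilities are compared with the cohort background by Pearson's
statistic on pseudo-counts scaled by the neighbor count,

    chi2 = k * [ (p_pos − q_pos)²/q_pos + (p_neg − q_neg)²/q_neg ],  df = 1,

and upper-tail p-values are corrected per patient (the biopsy-voxel family of
one patient) by Benjamini-Hochberg at α = 0.05. The df = 1 pseudo-count
construction is a design choice: it is the Pearson statistic of a 2-cell
observed/expected table built from k effective observations, the only
construction consistent with a binary class vector and an explicit expected
distribution. Note chi-square significance is two-sided in `p_pos − q_pos`: a
confidently *negative* voxel against a rare-positive background is also
"significant"; the argmax class decides the label.

ACC(k) is the mean of per-patient accuracies of the argmax class over
significant voxels, averaged over patients contributing at least one
significant voxel (otherwise 0/0; with no contributing patients ACC is
undefined and reported as no-result). SENS(k) is primarily the per-patient
mean percentage of biopsy voxels passing the threshold; the pooled variant
(total significant / total biopsy voxels) is always co-reported because the
study's printed sensitivities do not pin down the denominator. k_opt
maximizes SENS(k) subject to ACC(k) ≥ 0.95, ties toward smaller k; an empty
qualifying set yields k_opt = none and the outcome is excluded downstream
(the study's CNEC behavior). The default k grid is 100–3000 in steps of 100,
bracketing the study's optimized values (800/700/3000).

## Sub-hypothesis 3: whole-brain maps and RFT cluster correction

For each evaluated held-out patient, the wKNN trained on all other patients
is applied at every brain-mask voxel at k_opt, producing full-brain
chi-square maps. Because the map is a smooth statistical field, family-wise
error is controlled with Gaussian random field theory rather than per-voxel
correction:

1. *Gaussianization*: z = Φ⁻¹(1 − p(chi2, df)), clipped to ±8.2.
2. *Smoothness*: per-axis FWHM from forward differences,
   `FWHM_a = spacing_a * sqrt(4 ln2 * var(field) / var_a(diff))`, estimated on
   the statistical image itself (no residual maps exist in this design);
   RESELs = mask volume / Π FWHM. The estimator recovers a known 6 mm kernel
   within a few percent and white noise at ≈1.18 voxels (forward differences
   slightly overestimate the derivative variance of an unsmoothed field).
3. *Expected Euler characteristic*:
   E[EC](z) = R · (4 ln2)^{3/2} (2π)^{-2} (z²−1) e^{−z²/2} (3-D term only;
   boundary terms omitted).
4. *Cluster inference*: components of {z > z_cf} (26-connectivity by default,
   6 available) receive cluster-size p-values from the classical
   Gaussian-field size distribution P(n ≥ s) = exp(−β s^{2/3}) with
   β = (Γ(5/2)·E[m]/E[N])^{2/3}, E[m] the expected cluster count and E[N]
   the expected supra-threshold volume in RESELs;
   p_cluster = 1 − exp(−E[m]·P(n ≥ s)). Clusters with p ≤ α survive; the
   output map retains the chi-square values of surviving clusters only.

*Cluster-forming threshold.* The default is z_cf = 4.0. The classical size
distribution is an asymptotic (high-threshold) result: on exactly-Gaussian
stationary null fields (FWHM 6 voxels, 64³, periodic boundaries) its tail is
about twice too heavy at z_cf = 2.3, making inference conservative (empirical
FWER ≈ 0.01 at nominal 0.05), while at z_cf = 4.0 the empirical FWER is ≈
0.04. We default to the regime where the theory is calibrated; the threshold
is configurable for users who prefer the lower conventional value and accept
conservatism. Calibration simulations scale null fields by the smoothing
kernel's L2 norm rather than each realization's sample SD — per-field
standardization suppresses the scale fluctuations that drive extreme null
excursions and would bias the measured FWER downward.

RFT-based ACC and SENS are computed over each evaluated patient's biopsy
voxels, counting a voxel significant iff it belongs to a surviving cluster,
with the argmax class from the same probability map.

## Synthetic phantom

Each phantom patient is a 64³ grid at 1 mm isotropic spacing: a spherical
"brain" (radius 28 mm), background tissue at raw white-matter intensity per
contrast, and one spherical tumor (radius 13–17 mm, center within 10 mm of
the grid center). Outcome truth is drawn per patient with prevalences 2/29,
1/29, 9/29, 8/29 (IDH1, MGMT, CNEC, MVP), the recorded-positive patient
counts of the reference cohort. Triage is informative: only truly negative
outcomes are triaged, with P(triage | negative) = 18/27, 24/28, 11/20,
18/21 matching the reference triage counts.

The intensity model separates three components, all in WM-normalized units:

- *scanner/tissue noise*: Gaussian, SD 0.02, smoothed at 1.5 mm FWHM,
  everywhere — small enough that the white-matter reference mean is stable,
  as a hand-placed ROI in genuinely homogeneous white matter would be;
- *generic lesion appearance*: a common offset vector
  (T1w −0.06, T1w-post +0.03, T2w +0.18, FLAIR +0.20, ADC −0.06) modulated
  by a bounded within-tumor heterogeneity field — every tumor looks
  "tumor-like" without revealing any specific outcome;
- *biological variability*: SD 0.12 inside the tumor, spatially finer than
  the voxel grid (microscopic heterogeneity) and soft-bounded at 2 SD
  (tissue composition varies within physiologic limits, not with Gaussian
  tails); damped 3× inside expressing foci, which are comparatively
  homogeneous tissue compartments.

Pathology is modeled at the *specimen* level, following the reference
cohort's gross-volume bookkeeping (positive gross tissue volumes of
531/104/25439.5/6865.5 mm³ are far smaller than patient-level labeling would
imply): each truly positive outcome places one expressing focus toward the
lesion margin (foci of different outcomes head for different sectors),
sized by the cohort's positive voxel counts per specimen (IDH1 180, MGMT
93, CNEC 2827, MVP 390 mm³, capped at the specimen), and carried by a
dedicated positive specimen of 265/104/2827/1271 mm³ respectively. A
specimen tests positive when the focus center lies inside it
(representative sectioning detects the bulk of a focus, not grazing
contact); ordinary cores rejection-sample away from the foci when geometry
allows. Expression adds the outcome's signature — sign structure from the
reported coefficients (IDH1: T1w−/FLAIR+; MGMT: T1w−/ADC−; CNEC: T1w+;
MVP: T1w-post+), dominant contrast 0.5, distinct per outcome so co-positive
lesions stay decodable.
Cores per patient follow a clipped normal (3.24 ± 1.8, min 1); core volume a
clipped normal around 1271 mm³ (the cohort's gross tissue volume divided by
its ~94 cores; at 1 mm isotropic voxels this also reproduces the ~10⁵
feature-row scale). Voxel-level class imbalance then *emerges* in the
direction of the reference cohort's expected distributions (rare positive
voxels for the molecular outcomes), and the pipeline lands in the published
regime: per-patient accuracy near 1 over significant voxels, per-patient
sensitivities of order 1–20%, and a saturated balanced outcome.

What the phantom does **not** emulate: multifocal disease, partial-volume
and motion artifacts, anisotropic voxels, scanner-specific contrast scales,
informative core placement by a surgeon, or biophysical MR simulation.
Passing tests on the phantom show the statistical machinery behaves as
designed under its assumptions; they do not certify clinical performance.

The label-free null variant zeroes all signatures and marks every patient
pathology-positive: balanced specimen labels with no imaging correlate —
exactly the situation the reference cohort's cellular-necrosis outcome
exemplifies. (A rare-positive null would instead force occasional chance
rejections: over thousands of per-patient Benjamini-Hochberg families at
α = 0.05, exactly zero rejections is incompatible with FDR control itself,
which only bounds, not eliminates, false positives.)

## Problem sizes used in the test suite

The acceptance-style checks run the full default cohort: 29 patients,
~1.2×10⁵ feature rows, the complete k grid (100–3000 step 100) for the
leave-one-out sweep (one neighbor search per fold serves all outcomes and
all k), and whole-brain maps for the first truly-positive patient per
outcome (the study itself presents whole-brain maps for exemplar patients).
Calibration suites use 500-replicate simulations (BH false-discovery control
at m = 1000; RFT FWER on 64³ null fields at FWHM 6 voxels) and a 10-seed
smoothness-recovery study. These sizes keep the whole suite at desk scale
while leaving every statistical conclusion at its stated Monte-Carlo
precision.

## Numerical choices and degenerate inputs

- Sphere membership uses the closed ball; discretized sphere volume converges
  to the analytic volume as spacing shrinks (checked at 0.25 mm within 5%).
- Empty biopsy spheres warn (tiny cores on coarse grids are legitimate) and
  contribute no rows; empty WM ROIs, non-positive WM means, grid mismatches
  and missing contrasts raise errors naming the offender.
- wKNN requires k ≤ n_train; the pipeline drops grid values exceeding the
  smallest training fold.
- BH on an empty p-vector returns an empty result; the reported threshold is
  the largest rejected p, or α/m when nothing is rejected.
- Degenerate backgrounds (q_pos ∈ {0, 1}) are rejected — the Pearson
  transform is undefined there.
- Chi-square maps store 0 outside the brain mask; Gaussianized fields clip
  |z| at 8.2.

## Known limitations

- *Two-sided significance.* The chi-square statistic flags any deviation of
  the predicted class vector from the background, so tissue that is
  *confidently non-expressing* is "significant" whenever k·q_pos exceeds the
  threshold (chi-square ≈ k·q for p_pos = 0). For outcomes with
  non-rare backgrounds this drives, at large k, a family-wide cascade of
  Benjamini-Hochberg rejections of correctly-classified negative tissue
  (the step-up cutoff adapts to the rejected fraction), inflating SENS(k)
  and pulling k_opt toward large values; on whole-brain maps the same
  mechanism can push the entire non-expressing bulk above the
  cluster-forming threshold, merging it into a single brain-wide cluster.
  Only outcomes with rare backgrounds (q of order 17/k_opt or less, i.e.
  the molecular outcomes with small positive specimens) are immune.
- *Consequences on the phantom.* On the default seeded cohort the pipeline
  recovers the IDH1 expressing focus almost exactly (Dice ≈ 0.99 between
  surviving clusters and the true expressing region at k_opt), while MGMT's
  sole positive patient is undetectable under leave-one-patient-out (no
  positive training example exists in its fold — its map is constant and
  yields no clusters), and the two balanced outcomes either miss the
  accuracy floor (no k_opt) or saturate. Relatedly, the cluster-corrected
  maps are *more selective* than per-patient BH on biopsy voxels here —
  the reverse of the reference study's finding — because BH's adaptive
  cutoff admits the confident-negative cascade that the z > 4 forming
  threshold excludes; the published advantage of the spatial correction
  arises in the regime where per-voxel evidence is too weak to start BH
  (effective per-voxel thresholds near Bonferroni) while a lenient forming
  threshold plus cluster-size pooling still detects extended signal. These
  behaviors are measured by the test suite and reported as-is.
- *Degenerate folds.* A leave-one-out fold with no positive training
  specimen produces a constant whole-brain statistic; its smoothness is
  undefined and the pipeline records an empty cluster table rather than a
  map.
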