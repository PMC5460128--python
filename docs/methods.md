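# Methods

This note documents the models, conventions and numerical choices behind
`peristroma`, in the order the pipeline runs.

## ADC mapping

With a mono-exponential diffusion model, two co-registered images at
b₀ = 50 and b₁ = 1000 s/mm² give the per-pixel apparent diffusion
coefficient `ADC = −ln(S₁/S₀)/(b₁−b₀)` (mm²/s). Conventions:

* Internal unit is mm²/s; all reporting uses 10⁻³ mm²/s (the scale on which
  breast tumour ADC ≈ 0.9 and normal parenchyma ≈ 1.5–2.0).
* Pixels with nonpositive intensity in either image are invalid.
* A negative raw estimate (S₁ > S₀, possible under noise) is unphysical: it
  is clamped to 0 **and excluded** from all region statistics via the
  validity mask. How such pixels should be treated is a convention of this
  package, not an empirically grounded rule.
* No smoothing, registration or multi-b fitting: inputs are assumed
  co-registered 2-D slices.

## Region decomposition

Fibroglandular tissue is segmented on the b = 50 image by standard fuzzy
C-means on pixel intensity (2 clusters, fuzzifier m = 2, tolerance 1e-5 on
the objective decrease, ≤ 300 iterations, memberships initialised uniformly
at random from the seed; ties in final membership go to the lower-index
cluster). The bright cluster is tissue, the dark one fat. The tumour ROI is
an input (drawn by a radiologist in practice; rendered by the generator
here); if it has several connected components the largest is kept with a
warning.

The signed Euclidean distance d from the tumour edge (distance-transform
based, negative inside) defines six regions: S_I (d ≤ −2 px), S_T (the
tumour mask), S_B (|d| ≤ 2), and 4-px shells S_P (2,6], S_M (6,10],
S_D (10,14]. Choices worth stating:

* Interval endpoints: closed for S_I and S_B, half-open upper for the
  shells so the three shells partition the stromal band. The d = −2 contour
  belongs to both S_I and S_B; regions are analysed independently, so the
  overlap is accepted rather than arbitrated.
* Only the stromal shells are intersected with the fibroglandular mask —
  the boundary band deliberately contains tumour pixels. Shells are not
  clipped at any skin line beyond that intersection.
* Distances are in pixel units of the Euclidean transform; with 1.45 mm
  pixels a 4-px shell is 5.8 mm of stroma.
* A region left empty (thin tumour, shells wiped out by the fibroglandular
  intersection) is flagged and its statistics recorded missing, never zero.

## Features

Eight first-order histogram statistics per region — mean, min, max,
variance (n−1), interquartile range (linear-interpolation / "type 7"
quantiles), range, skewness m₃/m₂^{3/2} and excess kurtosis m₄/m₂²−3, both
uncorrected moment estimators; a constant region has skewness = kurtosis
= 0 — give 48 statistic features, and the ratio of each statistic between
the 15 unordered region pairs, oriented inner-over-outer in the canonical
order (S_I, S_T, S_B, S_P, S_M, S_D), gives 120 ratio features (168 total).
Regions with fewer than 5 valid pixels yield missing statistics (third and
fourth moments are meaningless below that); ratios with missing or ~zero
(|x| < 1e-12) denominators are missing. Missing values are *not* imputed in
the feature table — imputation is a training-fold operation of the
classifier, so no cohort-level statistic ever leaks across folds.

Ratio features also act as an internal normaliser: a case-level change in
overall noise or dispersion affects numerator and denominator together, so
ratios isolate *relative* regional contrast. This is visible in the
synthetic experiments, where ratio features carry much of the selection
frequency.

## Region-correlation graph

Per Ki-67 group, the six regions are nodes; for each of the 15 pairs the
Pearson correlation of per-case mean ADC is computed with the exact
two-sided t-transform p (n−2 df), Bonferroni-corrected by a factor 15
*within the group* (the two group graphs are separate analyses, hence
separate families), and an edge is drawn when corrected p < 0.05. Cases
missing a region mean are dropped pairwise. Pairs with fewer than 4 usable
cases or zero variance have undefined correlation: recorded missing, no
edge. Node degrees and the total degree summarise graph density; a denser
high-Ki-67 graph (longer-range coupling) is the expected signature of a
proliferative tumour influencing distant stroma.

One-way ANOVA (sums-of-squares F test) compares (a) mean ADC across the six
regions and (b) any feature — by default tumour mean ADC — between Ki-67
groups; groups with fewer than 2 observations are excluded with a warning.

## Classification

* **Logistic model.** Maximum likelihood by Newton/IRLS with a small L2
  ridge (λ = 1e-4 on slope coefficients of standardised features, intercept
  unpenalised) so the fit stays identifiable under perfect separation — at
  168 candidate features and ~80 cases, separation is routine. Tests verify
  the fit against scikit-learn's equivalent penalised logistic regression.
* **AUC** uses the rank (Mann–Whitney) formula with mid-rank ties — equal
  to both exhaustive pairwise concordance and the trapezoidal ROC area; its
  95% CI is a 2000-resample case-bootstrap percentile interval.
* **Youden operating point**: the threshold maximising sensitivity +
  specificity − 1 over all midpoints between consecutive distinct scores,
  ties resolved to the lowest threshold.
* **EA feature pool.** A generational binary GA — tournament selection of
  size 2, single-point crossover (rate 0.6), per-bit flip mutation (0.01),
  elitism — scores each chromosome by the mean stratified 5-fold CV AUC of
  the logistic model on the chromosome's features (an empty chromosome
  scores chance, 0.5); the best-ever chromosome is the pool. Full-scale
  defaults are population 500 / 200 generations; pipeline and tests use a
  reduced budget (40 / 30, identical operators) appropriate for an
  80-case problem, with early stop after 30 stagnant generations. Fitness
  is cross-validated rather than resubstitution because resubstitution AUC
  saturates at 1.0 with far more features than cases, making the search
  degenerate.
* **LOOCV + wrapper.** For each held-out case: training-fold medians impute
  missing values, training-fold mean/SD standardise; greedy forward
  selection over the pool maximises internal stratified 5-fold AUC on the
  training cases, stopping when no addition improves it by more than 1e-4;
  a ridge logistic fit on the selected features scores the held-out case
  (a fold selecting nothing scores the training prevalence). Pooled
  held-out scores give the report; per-feature selection frequency over
  folds measures importance. The stratified-fold count is capped at the
  minority-class size for very small inputs.
* **Known bias, by design:** the EA pool is searched once on the full
  dataset *before* LOOCV (the two-stage design the pipeline reproduces), so
  pooled LOOCV estimates inherit a selection optimism even though every
  statistic inside `loocv_evaluate` is strictly training-fold. On pure-noise
  data this two-stage optimism is worth roughly +0.1 AUC at n = 80.
  Accordingly, the leakage tests fix the pool independently of the
  evaluated labels (full pool, or a pool built from unpermuted labels) —
  they verify `loocv_evaluate` itself is leakage-free, which it is. Running
  the EA inside every fold would remove the optimism at ~80× the cost; the
  API permits it trivially (call `ea_feature_pool` per fold) but the
  pipeline does not do it.

## Synthetic cohort generator

The generator exists so every downstream stage is testable end-to-end with
known ground truth. Defaults define the reference study conditions: n = 80
cases, 66% high Ki-67, 96×96 px slices at 1.45 mm, circular tumours of
radius 10–16 px inside an elliptical fibroglandular support surrounded by
fat, b-values 50/1000 s/mm².

* **Latent structure.** Per case, a 6-vector of latent region means (10⁻³
  mm²/s) is drawn from the group's multivariate normal: ascending mean
  profiles (low group (0.84, 0.91, 1.08, 1.30, 1.50, 1.62); high group
  slightly lower, (0.80, 0.87, 1.00, 1.18, 1.40, 1.58), reflecting the
  higher cellularity of proliferative disease), per-region SD 0.15 (close
  to the reference tumour SD of 0.159), and group-specific correlation:
  tridiagonal r = 0.5 for the low group (adjacent regions only; 0.5 sits
  safely under the positive-definiteness limit 1/(2cos(π/7)) ≈ 0.555 of an
  adjacent-only 6×6 band matrix) and AR(1) ρ = 0.7 for the high group
  (adjacent plus longer-range coupling).
* **Rendering.** The six analysis regions overlap (S_T ⊃ S_I and half of
  S_B), so pixels are rendered from five *disjoint* distance bands: core
  (d ≤ −2) ← S_I latent, boundary band (−2 < d ≤ 2) ← S_B latent, three
  shells ← their latents; fibroglandular tissue beyond the distal shell
  holds the S_D plateau and fat a static 0.35. The latent S_T value is
  recorded as ground truth, but the *measured* whole-tumour mean is the
  core/boundary area-weighted mixture; with the default radius range the
  core fraction averages ≈ 0.70, placing the cohort tumour mean near the
  0.888×10⁻³ mm²/s anchor. A side effect is that measured S_T genuinely
  correlates with S_I and S_B in both groups — which is also exactly the
  adjacent-edge pattern expected of the low-Ki-67 graph.
* **Noise.** Pixel ADC is the band latent plus i.i.d. Gaussian noise. The
  per-case noise SD is the configured median (0.12) times a lognormal
  factor (log-SD 0.25): real cohorts vary case-to-case in dispersion, and
  without this heterogeneity the dispersion statistics (IQR, variance,
  range) of a ~300-pixel region are nearly deterministic, which made a
  single feature a perfect classifier — unrealistically easy.
* **Boundary skew.** High-Ki-67 cases add a mean-centred gamma component
  (shape 2, scale 0.12) to boundary-band pixels: one parameter produces the
  elevated boundary skewness expected of aggressive tumours without
  shifting the boundary mean. The low group's boundary skewness comes out
  mildly negative because the S_B mask overlaps one ring of lower-valued
  core pixels.
* **Signal decay.** s₀ is a textured tissue/fat intensity map; s₁ = s₀ ·
  exp(−(b₁−b₀)·ADC). With noise SD 0 the ADC mapper inverts this exactly
  (machine precision), which the tests assert.

What the generator does **not** emulate: MR physics (coil profiles, EPI
distortion, fat-suppression failure), partial-volume and motion effects,
3-D anatomy, irregular tumour margins, and any real covariance between
tumour size and biology. Passing the pipeline's recovery tests therefore
demonstrates correctness of the *computational chain* under the stated
statistical model — not clinical-grade performance; the near-perfect
synthetic AUC (~0.99) is a property of the clean simulation, and published
real-data analyses of this design report substantially lower discrimination
(AUC ≈ 0.9 at n = 82).

## Problem sizes used by the test suite

Tests run the reference conditions end-to-end: 20 seeded 80-case cohorts
for classifier parameter recovery, 100 seeds for the graph-degree contrast,
200 seeds (40 cases, latent means) for the null edge rate, 500 cases for
correlation recovery, 3 permutations for the leakage null — all at the
reduced EA budget. `scripts/acceptance.py` runs one full 80-case analysis.

## Degenerate inputs and tie-breaks (summary)

Constant image → segmentation error; constant region → zero-valued
dispersion/shape statistics; empty/small region → missing statistics;
zero-variance region mean → missing correlation, no edge; all-zero
chromosome → fitness 0.5; wrapper selecting nothing → prevalence score;
identical scores → Youden J = 0; Youden ties → lowest threshold; FCM
membership ties → lower cluster index; equal GA fitness in a tournament →
first contestant wins. All randomness flows from explicit integer seeds;
repeated runs are bit-identical.
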