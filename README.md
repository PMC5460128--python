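# peristroma

Analysis pipeline for predicting **Ki-67 proliferation status** (high vs low,
14% cut) in ER-positive breast cancer from the heterogeneity of **apparent
diffusion coefficient (ADC)** values in the tumour *and the stroma around
it*, measured on two-b-value diffusion-weighted MRI (DWI).

The biological idea: an aggressively proliferating tumour remodels its
microenvironment, so the diffusion signature of the *peritumoural stroma* —
not just the tumour — carries predictive information. The pipeline
quantifies that signature and feeds it to a classifier.

## What the pipeline computes

1. **ADC mapping** — per pixel, from images at b₀ = 50 and b₁ = 1000 s/mm²:
   `ADC = −ln(S₁/S₀) / (b₁ − b₀)` (mm²/s; reported in 10⁻³ mm²/s).
2. **Region decomposition** — fibroglandular tissue is segmented on the b=50
   image by fuzzy C-means (excluding fat); the signed Euclidean distance *d*
   from the tumour edge defines six regions: inner tumour S_I (d ≤ −2 px),
   whole tumour S_T, boundary S_B (|d| ≤ 2), and three 4-px stromal shells
   S_P, S_M, S_D (d ∈ (2,6], (6,10], (10,14]); at 1.45 mm pixels each shell
   is 5.8 mm wide. Shells are clipped to fibroglandular tissue.
3. **Features** — per region, 8 first-order histogram statistics of ADC
   (mean, min, max, variance, IQR, range, skewness, excess kurtosis) → 48
   features; plus the ratio of each statistic between all 15 region pairs →
   120 features; 168 per case.
4. **Region-correlation graph** — per Ki-67 group, a 6-node undirected graph
   with an edge wherever the Pearson correlation of per-case region mean ADC
   is significant after Bonferroni correction over the 15 pairs
   (corrected p < 0.05); node degrees summarise how far a tumour "spreads"
   its diffusion signature. One-way ANOVA compares mean ADC across regions
   and groups.
5. **Classification** — a binary genetic algorithm (tournament selection,
   single-point crossover 0.6, per-bit mutation 0.01, elitism) searches for
   an optimal feature pool, scored by stratified 5-fold CV AUC of a
   ridge-stabilised logistic model; leave-one-out cross-validation then runs
   greedy forward wrapper selection *inside every training fold* and pools
   the held-out scores into ROC/AUC (bootstrap CI), a Youden-index operating
   point, and per-feature selection frequencies.

Because no patient images ship with the package, a **synthetic cohort
generator** renders two-b-value DWI cases with the documented structure:
ascending region mean-ADC from core to distal stroma (whole-tumour mean
centred near 0.888×10⁻³ mm²/s), adjacent-only inter-region correlation in
the low-Ki-67 group vs longer-range correlation in the high group, and
positively skewed boundary ADC in high-Ki-67 cases.

## Worked example

```python
import peristroma as ps
from peristroma.pipeline import PipelineConfig, run_all

config = PipelineConfig(
    out_dir="demo_out",
    cohort=ps.CohortConfig(n_cases=80, seed=1),
    seed=1,
)
bundle = run_all(config)
print(f"high-group total degree: {bundle['graphs']['high'].total_degree}")
print(f"low-group  total degree: {bundle['graphs']['low'].total_degree}")
r = bundle["report"]
print(f"LOOCV AUC {r.auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}), "
      f"sens {r.sensitivity:.2f} spec {r.specificity:.2f}")
```

prints (seed 1):

```
high-group total degree: 26
low-group  total degree: 2
LOOCV AUC 0.997 (95% CI 0.990-1.000), sens 0.96 spec 1.00
```

That is: the high-Ki-67 group's region graph is far denser (its tumours
couple non-adjacent regions), and the classifier recovers the group label
almost perfectly from the engineered effects — on synthetic data whose
signal strength is by construction clean; real cohorts are harder.

The same run is available from the shell:

```bash
peristroma run-all --out demo_out --seed 1
```

with subcommands `simulate / adc / segment / features / graph / classify`
for the individual stages (NIfTI images, CSV tables, JSON reports).

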