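# solmark

Solanidine metabolic-ratio biomarkers of CYP2D6 activity.

The potato glycoalkaloid aglycone **solanidine** is ingested with ordinary
diet and cleared almost entirely by the polymorphic drug-metabolizing
enzyme **CYP2D6**. Fasting plasma solanidine and, even more sharply, the
ratios of its metabolite ions (*m/z* 414, 416, 444, 430, 412) to the parent
concentration therefore read out CYP2D6 activity without administering a
probe drug. `solmark` implements the full analysis pipeline needed to
characterise such a biomarker in a genotyped cohort, for pharmacogenetics
and clinical-pharmacology researchers working from Python:

* **Genotype → phenotype** — star-allele diplotype parsing (`*1x2/*41`),
  the CPIC-style activity score `AS = Σ value(allele) × copy number` with
  per-allele function values in {0, 0.25, 0.5, 1}, phenotype bins
  `AS = 0 → gPM`, `0 < AS < 1.25 → gIM`, `1.25 ≤ AS ≤ 2.25 → gNM`,
  `AS > 2.25 → gUM`, and the optional NFIB rs28379954 sensitivity
  reclassification (gNM carriers → gUM).
* **Quantification** — 1/x-weighted linear calibration over 0.01–25 ng/mL,
  curve inversion, and the censoring rules: subjects with parent solanidine
  below the LLOQ (0.01 ng/mL) are excluded; metabolite responses below
  their S/N-10 LLOQ are imputed at half the LLOQ and flagged.
* **Group contrasts** — log-scale analysis throughout: geometric means with
  t-based 95% CIs, forward-stepwise covariate selection (entry p ≤ 0.05,
  removal p ≥ 0.10), covariate-adjusted ANOVA with Fisher's-LSD contrasts
  against the gNM reference, reported as geometric-mean ratios.
* **Classifier evaluation** — AUROC (rank statistic, ties half credit),
  non-interpolated average precision with its prevalence baseline, F1max,
  class-stratified percentile bootstrap CIs (1000 resamples), paired marker
  comparisons sharing resample indices, and a correlated-ROC (DeLong)
  p-value for AUROC differences.
* **Feature screening** — robust scaling (median/IQR), then random-forest
  and gradient-boosted regression trees fitted to numeric phenotype codes
  under repeated 2-fold nested CV with randomized hyperparameter search;
  mean impurity-decrease importance > 0.01 flags a feature.
* **Association scan** — per-variant additive-dosage linear regression
  (vectorized Frisch–Waugh OLS) with covariates, genome-wide threshold
  5 × 10⁻⁸, LD as squared dosage correlation, and conditional re-scans;
  dosage tables or minimal VCF (GT) input.
* **In vitro kinetics** — first-order substrate-depletion fits
  (k = −slope of ln C vs t), CLint = k / protein, well-stirred scaling
  CLh = Q·fu·CLint,liver / (Q + fu·CLint,liver), percent inhibition, and
  the phenotype-ratio fraction-metabolized estimate fm = 1 − GM_gNM/GM_gPM.
* **Synthetic cohorts** — a seeded generator calibrated to the published
  group geometric means and CIs (sizes 9/89/196/20), with class-consistent
  diplotypes, censoring applied exactly as in the pipeline, and SNP panels
  with a causal no-function variant plus LD proxies.

## Worked example

`examples/group_contrasts.py` simulates a cohort at the default
calibration, censors it, and produces the summary-table view:

```
cohort: 314 subjects, 8 excluded below the solanidine LLOQ

     feature phenotype   n     gm  gm_ci_low  gm_ci_high  ratio_raw  ratio_adj  ratio_ci_low  ratio_ci_high  p_value
 solanidine       gPM   9 2.5127     1.2515      5.0448    25.8841    25.8841       12.3916        54.0680   0.0000
 solanidine       gIM  89 0.1683     0.1323      0.2140     1.7336     1.7336        1.3131         2.2886   0.0001
 solanidine       gNM 188 0.0971     0.0829      0.1136     1.0000     1.0000           NaN            NaN      NaN
 solanidine       gUM  20 0.0536     0.0339      0.0846     0.5518     0.5518        0.3321         0.9168   0.0219
```

Read: poor metabolizers carry ~26-fold higher fasting solanidine than
normal metabolizers (they cannot clear it), intermediate metabolizers
~1.7-fold, and ultrarapid metabolizers run ~45% lower; the p-values are
unadjusted Fisher's-LSD pairwise tests from the fitted log-scale ANOVA.
`examples/depletion_kinetics.py` shows the in vitro side:

```
depletion fit: k = 0.0463 /min, t1/2 = 15.0 min, R^2 = 0.994
CLint = 0.232 mL/min/mg protein
well-stirred hepatic CL = 82.6 L/h (92% of hepatic blood flow)
inhibition: 95% reduction of CLint
fraction of clearance mediated by CYP2D6 in gNM subjects: 94.9%
```

The other scripts in `examples/` cover genotype translation, calibration
and censoring, ROC/PR biomarker evaluation, the association scan, and
feature screening, each printing the quantities it computes.

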