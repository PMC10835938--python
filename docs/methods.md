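# Methods

This note documents the models, conventions, and numerical choices behind
`solmark`, and what the synthetic-data tests do and do not demonstrate.

## Genotype-to-phenotype translation

CYP2D6 star alleles carry per-copy function values restricted to
{0, 0.25, 0.5, 1}; a diplotype's activity score is the sum over both
haplotypes of function value × copy number, so duplications (`xN`) scale
their haplotype and the `*5` deletion (validated to value 0) contributes
nothing. Phenotype bins follow the activity-score convention with exact
boundary inclusivity: AS = 0 → gPM, 0 < AS < 1.25 → gIM,
1.25 ≤ AS ≤ 2.25 → gNM, AS > 2.25 → gUM.

The bundled default table assigns normal function to `*1, *2, *39`, no
function to `*3, *4, *5, *6, *11, *13`, 0.25 to `*10`, and 0.5 to the other
decreased-function alleles (`*9, *17, *29, *41, *59, *65, *69, *88`). The
exact decreased values for a handful of rare alleles vary between
curations, so the whole table is overridable; alleles absent from the table
raise rather than silently scoring as normal (safety over convenience).
Subjects whose diplotype is missing or unparseable are classed
`indeterminate` and carry no numeric code. The NFIB rs28379954
reclassification is a pure sensitivity switch: enabled, it moves gNM
carriers to gUM and touches nothing else.

## Quantification and censoring

Calibration is a weighted least-squares line (weights 1/concentration, the
usual LC–MS/MS variance model; unweighted fitting is available) requiring
at least three distinct positive standards; the reported `r` is the
weighted correlation of the fit and the slope must be positive for the
curve to be usable. Quantification inverts the line; non-positive results
are flagged non-quantifiable rather than clipped.

Censoring policy is asymmetric by design: a parent solanidine value below
the 0.01 ng/mL LLOQ invalidates all of that subject's ratios, so the
subject is excluded; a metabolite response below its per-ion LLOQ is
imputed at half the LLOQ and flagged (zero/negative responses count as
below-LLOQ). The operation is idempotent, and exclusion is a returned
state, never an exception. Metabolite responses stay in semi-quantitative
units (peak area / IS area); ratios divide response by parent concentration
in ng/mL and are computed only for retained subjects — passing an excluded
subject is treated as a caller error.

## Group contrasts

All biomarker endpoints are analysed as natural logs and back-transformed
for reporting. Group location is the geometric mean with a t-interval on
the log scale (`exp(mean ± t_{0.975, n−1} SE)`); pooled cohort means weight
log-means by group size. Demographic covariates (sex, log bodyweight,
study period) are chosen once per endpoint by forward-stepwise regression
(entry p ≤ 0.05 via the partial F of the added column, backward removal at
p ≥ 0.10, iterated to convergence; constant candidates are skipped with a
warning, collinear ones cannot enter) and then held fixed. Contrasts come
from an OLS fit of the log endpoint on phenotype dummies (gNM reference)
plus selected covariates; each class coefficient back-transforms to a
geometric-mean ratio with a CI at the pooled residual df. Fisher's LSD
means exactly this: unadjusted pairwise p-values from the pooled error
variance, with no multiplicity correction. The report emits both raw and
covariate-adjusted ratios because printed cohort tables do not always say
which they used; the two coincide when nothing is selected.

## Classifier evaluation

Each task scores one phenotype class against gNM. Orientation is explicit
per marker (parent concentration scores impaired classes high; metabolic
ratios score them low) and is applied by negation so an informative marker
sits above AUROC 0.5. AUROC is the midrank U statistic (ties half credit);
AUPRC is non-interpolated average precision evaluated at distinct
thresholds, the conservative standard convention (commercial packages vary
and rarely document their interpolation); its baseline is the positive
prevalence. F1max scans the same distinct thresholds. Bootstrap CIs are
percentile intervals over class-stratified resamples (default B = 1000),
which preserves prevalence and guarantees both classes in every resample;
paired marker comparisons reuse identical resample indices for both
markers so the difference distribution is honest. AUROC differences also
get the correlated-ROC (DeLong placement-value) variance and a two-sided
normal p; AUPRC differences are judged from the bootstrap CI alone. A
degenerate zero-variance difference (marker compared with itself) returns
p = 1.

## Feature screening

Features are robust-scaled per feature ((x − median)/IQR, quartiles by
linear interpolation); zero-IQR features are centred and flagged, never
divided. Two learner families — bagged (random forest) and boosted
(gradient-boosted) regression trees fitted to the numeric phenotype codes
gPM=0 … gUM=3, an ordinal-by-activity coding — run under repeated 2-fold
outer CV (default 5 repeats) with randomized hyperparameter search in
2-fold inner CV. "Gini" importance for regressors is read as its
regression analogue, mean impurity (variance) decrease; per-fit importance
vectors (each summing to 1) are averaged over all outer-fold refits, and a
mean above 0.01 flags the feature. Averaging over folds is reported rather
than a single full-data refit. Note the 0.01 threshold presumes a large
feature panel: with only a few dozen features the residual importance mass
per null feature alone can exceed it, so desk-scale simulations here use a
few hundred features. Tree ensembles come from scikit-learn; exact
importance values (not rankings) can shift marginally under feature
reordering through split-tie resolution at small nodes.

## Association scan

Per variant, the log endpoint is regressed on allele dosage (0–2) plus
covariates; the implementation residualizes the endpoint and all dosages
on the covariate design once and fits the marginal slopes vectorized
(Frisch–Waugh), which agrees with per-variant OLS to machine precision.
Wald p-values use the t distribution at n − (covariates + 2) df; p < 5e-8
is genome-wide significant. Missing dosages are mean-imputed per variant
(standard practice; the alternative, casewise deletion, changes n per
variant); monomorphic or all-missing variants are skipped with a reason.
LD is the squared Pearson correlation of dosage vectors (computed on
dosages, not phased haplotypes). The conditional scan adds the named
variant's dosage as a covariate and skips the variant itself. Coordinates
are 1-based; input is a delimited dosage table or, optionally, a GT-only
VCF via cyvcf2.

## In vitro kinetics

Depletion curves are fitted as ln C vs t by OLS (two points suffice for
the closed-form rate, though three or more are preferred); negative fitted
rates are clipped to 0 with a warning. CLint = k / protein concentration
(mL/min/mg). Whole-liver scaling multiplies by MPPGL and liver mass and
converts to L/h; hepatic clearance uses the well-stirred model, monotone
in CLint and bounded by hepatic blood flow Q. The default constants —
MPPGL 40 mg/g, liver 1800 g, Q 90 L/h, fu 1 — are ordinary textbook
values and fully configurable; published scaled-clearance figures depend
on each study's own constants, so no specific printed value is asserted.
The fraction-metabolized estimate fm = 1 − GM_gNM/GM_gPM assumes
steady-state concentrations scale inversely with clearance, i.e. that the
phenotype groups differ only in CYP2D6-mediated clearance.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: group sizes 9/89/196/20;
per-group lognormal distributions for solanidine (ng/mL) and the five
metabolite ratios with geometric means from the published group table and
log-SDs backed out of the printed 95% CIs as
σ = √n · ln(CI_hi/CI_lo) / (2z) with z = 1.96 (a normal quantile — these
are calibration heuristics, not estimates, so no t correction). Metabolite
responses are ratio × solanidine; ratios and parent are drawn independently
within group (their joint correlation is unpublished; `log_corr` provides a
hook). Per-ion response LLOQs default to the levels at which the mixture
model reproduces the published detected-subject counts (310/308/299/296/225
of 314), solved numerically at config time. Diplotypes are drawn from an
illustrative per-class table chosen to be consistent with the activity-score
bins (verified by round-tripping through the translator), bodyweight is
lognormal matching the published mean/SD (69.7 ± 12.1 kg), sex and study
period are Bernoulli(0.5), and NFIB carriage uses the published gNM carrier
fraction (17/196).

Dosage panels derive the causal variant deterministically from each
subject's no-function allele count; proxies copy the causal dosage and
re-draw a fraction ≈ 1 − √r² of entries, retrying (with a nudged fraction)
until the achieved r² is within ±0.05 of target; background variants are
independent binomial(2, maf), maf ~ U(0.05, 0.5). Depletion curves are
exponentials with mean-one multiplicative lognormal noise, which leaves the
log-slope unbiased.

Known divergences from real data, hence limits on what passing tests show:
the lognormal model yields roughly 3–5% of subjects below the parent LLOQ
(~8–15 of 314), whereas the real excess (41 of 355) largely reflects potato
non-consumption, a behavioural zero-class the distributional model does not
emulate; real LC–MS feature matrices have correlated features, batch
structure and thousands of features, where the generator plants one
informative feature among independent noise; and real genotype panels have
block-wise LD rather than star-shaped proxies around a single causal
variant. Parameter-recovery tests accordingly compare estimates against
the generator's pre-censoring truth values — post-censoring estimates are
left-truncation-biased by construction (≈ +0.1 log units for gNM), which is
a property of the exclusion rule, not an estimator defect.

## Problem sizes and tolerances

Simulation-based checks run at desk scale chosen for a laptop-class
budget: bootstrap-coverage at 500 replicates × 500 resamples (n = 200
scores), cohort recovery over 200 seeds, association scans at ~2000
variants × 314 subjects, feature screens at 300 subjects × 201 features
over six seeds, and depletion recovery over 1000 noisy curves. Exact
identities are asserted to 1e-10–1e-12 relative tolerance; published
rounded values to their printed precision (~1%); Monte-Carlo quantities to
2–4 standard errors of their simulation size. Numerical edge cases are
handled explicitly rather than by exception where the domain expects it:
degenerate zero-residual ANOVA fits return point CIs, flat depletion
curves return k = 0, and constant screening features carry exactly zero
importance.
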