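# Methods

This note documents the statistical models the package implements, the
assumptions and defaults behind them, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Transmission imputation

At a biallelic SNP with alleles labelled by population frequency
(`A` major, `a` minor), a complete family triad determines the parentally
transmitted alleles by gamete-pair enumeration: of the 27 genotype
configurations, 15 are Mendelian-consistent, and exactly one of those — the
triple heterozygote — admits two gamete assignments and is
*uninformative*. The implementation is a transcription of the standard
imputation table; the test-suite checks it against an independent
enumeration oracle on all 27 configurations.

Choices:

* **Allele labels** are assigned per SNP from founder (parental) allele
  frequencies only, to avoid transmission-induced bias in the frequency
  estimate.
* **Missing members** give `unknown` transmissions; duo-based partial
  inference is deliberately not attempted.
* **Mendelian-inconsistent triads** (genotyping error or non-paternity) are
  excluded from analysis and counted in the pipeline manifest, since the
  originating study design does not specify their handling.
* The **maternal untransmitted allele** is the complement of the maternal
  transmitted allele within the mother's genotype; for a heterozygous
  mother it is known exactly when her transmission is informative.
* **SNP QC**: founder genotypes must be consistent with Hardy–Weinberg
  equilibrium (Pearson χ², 1 df, p > 0.05) and, when duplicate genotyping
  is available, repeat discordancy must be below 1 %.

## Peak-table preprocessing

A lipid species enters analysis only if (a) strictly more than 70 % of
*study* samples (QC/QA/blanks excluded from the denominator) have intensity
above the limit of detection, and (b) its mean intensity across the pooled
QC dilution series (relative concentrations 1.0, 0.5, 0.2) correlates with
those concentrations at Pearson r > 0.9 with positive slope. "More than
70 %" is read as a strict inequality and the threshold is configurable,
because at a round cohort size the boundary case (exactly 70 %) is
ambiguous in prose descriptions of this rule. The QC r-threshold 0.9 is a
package default — the filtering convention gives no number — and is
reported per species.

Normalization is row-median scaling (each study sample divided by its
median intensity over retained species), then log₁₀, then per-species mean
centring, in that order — the default order of the metabolomics tool
family these studies use. The log base is configurable; centring makes
column means exactly zero, and median scaling makes the output invariant
to per-sample multiplicative factors (dilution, injection volume).
Below-LOD entries in retained species are imputed before the log step
(half the minimum detected value by default, LOD/√2 optionally).

## PLS-DA screening

Per (SNP, parental transmission), the centred lipid matrix X is regressed
on the centred binary transmitted-allele indicator y by NIPALS PLS1: per
component, w ∝ Xᵀy (‖w‖ = 1), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, with X and
y deflated by the component; SSYₐ = qₐ²·tₐᵀtₐ. X is centred but not
unit-variance scaled, matching the normalization above; y is dummy-coded
and centred, not scaled.

Predictive ability is Q²(A) = 1 − PRESS(A)/TSS over stratified k-fold
cross-validation (10 folds by default; stratification guarantees both
classes in every training fold; folds are reduced to the minority-class
count when needed; fully deterministic given the seed). A model is
accepted iff its best Q² over A = 1..5 components is positive, ties
resolved to the smallest A (parsimony). Whether the original executor used
10-fold or leave-one-out CV is unknowable; both are supported and 10-fold
is the default.

VIP_j = √( J Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ ) over the Q²-maximizing component
count; candidates are species with VIP > 2.0 in accepted models.
Single-component VIPs are reported alongside because screening tables in
this literature sometimes quote the component-wise value. Σⱼ VIP²ⱼ = J is
an algebraic identity of the formula and is enforced as a test invariant.
The estimator is cross-checked against scikit-learn's `PLSRegression`
(identical scores, loadings and predictions for single-y problems); that
library is never used in the computation path.

## Association battery and parent-of-origin rules

Cohort-level associations are Pearson correlations with the exact two-sided
Student-t p-value on n − 2 df. Published tables in this design print R as a
magnitude — the allele coding direction is arbitrary — so the reported R is
|r| with the sign retained internally for meta-analytic harmonization. α =
0.05 without multiple-testing correction is the design's explicit
convention; a Benjamini–Hochberg option exists but is off by default.

The classifier compares five pooled contrasts per (SNP, species):

1. both transmitted alleles significant → **fetal-biallelic** (expression
   from both parental copies);
2. one transmission significant, exceeding the maternal-genotype and
   untransmitted-allele magnitudes, with the other parent's contrast null →
   **fetal-effect-imprinted-(maternal|paternal)**;
3. a maternal-genome contrast significant and at least as strong as any
   transmitted contrast → **maternal-mediated**;
4. otherwise **indeterminate**.

The untransmitted maternal allele is the key negative control: it shares
the mother's genome but not the fetus, so a fetally mediated effect should
not appear there. Classification uses the pooled (meta) estimates and the
one-sided pooled p.

HOMA indices use the HOMA1 closed forms — insulin converted from pmol/L to
mU/L by 6.945 (WHO convention; configurable since assay factors vary),
then HOMA-IR = G·I/22.5 and HOMA-B = 20·I/(G − 3.5). The iterative HOMA2
calculator gives systematically lower IR values (≈ 0.9 where HOMA1 gives
≈ 1.25 at typical pregnancy values); the `homa_variant` distinction is
documented rather than emulated because HOMA2 is a proprietary numerical
model. The summary-statistics group test reconstructs SEs from printed 95 %
CIs (half-width / 1.96) and applies a two-sided normal z-test — exact for
the large-sample tables it is meant to reproduce.

## Meta-analysis

Per-cohort correlations are pooled on the Fisher-z scale (z = atanh r,
variance 1/(n − 3)) by DerSimonian–Laird: Q = Σwᵢ(zᵢ − z_fixed)²,
C = Σwᵢ − Σwᵢ²/Σwᵢ, τ² = max(0, (Q − (k−1))/C), random-effects weights
1/(vᵢ + τ²). CIs back-transform through tanh. The **primary p-value is the
one-sided upper-tail normal probability** of z_pooled/SE: this is the
output convention of the R correlation-meta-analysis tooling this design
used, and it is the only convention that reproduces every printed pooled
p-value; the two-sided value is always emitted alongside. Before pooling,
cohort signs are harmonized to the Discovery-cohort direction. No
small-k or Hartung–Knapp corrections are applied by default (k = 2
throughout the emulated design).

## Synthetic generator

The generator's defaults state the emulated world: 767 families split
200/567 into Discovery and Validation cohorts, 151 SNPs with MAF drawn
U(0.05, 0.5), 173 lipid species with log₁₀ baselines U(2.5, 4.0) a.u.,
residual log₁₀ SD 0.25, per-sample scale SD 0.10, a global LOD at the
pooled 5 % intensity quantile, QC dilutions at 1.0/0.5/0.2 with 4
replicates each plus 6 blanks and 6 QA samples (the per-batch design of
the emulated assay), fasting glucose centred at 4.3 mmol/L and insulin at
45 pmol/L (cohort-table marginals), GDM flagged by IADPSG-style thresholds
(fasting ≥ 5.1 or 60-min ≥ 10.0 mmol/L).

Allele effects are additive on the log scale — d × (residual log SD) per
effect-dose unit, where the dose is the transmitted-minor indicator
(maternal-only / paternal-only), the child's minor count (biallelic), or
the mother's minor count (maternal-genome). Everything is deterministic
per seed.

**What a green test does not establish.** The generator simulates
*independent* lipid species: real lipidomes are strongly co-regulated,
which concentrates class signal in a few latent dimensions and makes
PLS-DA far more sensitive than it can be here. Consequently the Q² > 0
acceptance gate, faithful to the screening rule, rarely accepts a model
whose only signal is a single species at a modest standardized effect
(measured acceptance ≈ 3 % at d = 0.3 and ≈ 20 % at d = 1.0 with 170
independent species at n ≈ 105) — the corresponding end-to-end recovery
property is therefore expected to fail at small d in this synthetic world,
and the suite reports it honestly rather than inflating the generator's
effect sizes. Likewise a maternal-only effect of d = 0.25 at ~350
informative transmissions yields ≈ 64 % univariate power at two-sided
α = 0.05 (the textbook value for a point-biserial r ≈ 0.12), not ≥ 90 %.
Batch effects, LD between SNPs and population stratification are also not
simulated.

## Numerical choices

* Correlation p at r = 0 is exactly 1 (t = 0 convention); |r| ≥ 1 gives
  p = 0.
* Monomorphic SNPs give a degenerate HWE result (χ² = 0, p = 1, flagged)
  rather than an error.
* NIPALS stops early when X deflates to numerical zero (`stopped_early_`);
  out-of-fold predictions then use the components actually extracted.
* Q² ties across component counts resolve to the smallest count after
  rounding Q² to 12 decimals.
* `meta_scan` emits unpooled single-cohort keys flagged `pooled=False`
  instead of dropping them; duplicate keys within a cohort are an error.
* Perfect separation in the logistic fit raises instead of returning a
  divergent estimate.
* Pipeline reruns with identical config and seed are byte-identical,
  and every exclusion (inconsistent triads, filtered species, dropped
  samples) is ledgered once in the JSON manifest.

## Known limitations

* HOMA2 is approximated by HOMA1 closed forms (flagged, documented above).
* The power calculation conventions of the emulated design are not
  reproduced; no power calculator is provided.
* X-chromosome transmission rules, genotype phasing from population LD and
  missing-genotype imputation are out of scope.
* The GDM odds-ratio and birth-weight regressions require raw cohort data;
  only the generic regression utilities are provided.
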