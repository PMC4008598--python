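# Methods

## The risk model

Every analysis starts from a summary-statistics panel: per risk locus, the
risk allele, its per-allele odds ratio `OR`, its frequency `p` in
controls/the general population, and the case/control sample sizes of the
source association study. Two quantities are derived per locus:

* **weight** `w = ln OR` — the per-allele contribution to the weighted
  genetic risk score (wGRS). Under the multiplicative model a profile with
  dosages `g = (g₁ … g_L)`, `gᵢ ∈ {0,1,2}`, has log risk
  `S(g) = Σᵢ gᵢ wᵢ`; risks multiply across alleles and loci.
* **Woolf standard error of ln OR.** The source study's allele-level 2×2
  table is reconstructed from its expected counts: with case allele
  frequency `p′ = OR·p / (1 − p + OR·p)`, the counts are
  `a = 2 n_cases p′`, `b = 2 n_cases (1 − p′)`, `c = 2 n_controls p`,
  `d = 2 n_controls (1 − p)`, and `SE = √(1/a + 1/b + 1/c + 1/d)`. This uses
  exactly the inputs a published panel provides (OR, frequency, sample
  size); no per-variant SEs are required in the input file.

The variance of a profile's log risk treats the dosages as fixed and the
per-locus ln OR estimates as independent across loci:
`Var S(g) = Σᵢ gᵢ² SEᵢ²`. The only uncertainty quantified is therefore the
source studies' sampling error, not genotype sampling; a profile with zero
risk alleles has zero variance and a degenerate (point) confidence interval.

## Population simulation and risk categories

A general population of `n` individuals (default 100,000, explicit seed
mandatory) is simulated one locus at a time as Binomial(2, p) dosages —
exactly the Hardy–Weinberg genotype distribution ((1−p)², 2p(1−p), p²) —
with loci independent (no linkage disequilibrium, no interaction terms).
Identical dosage vectors share a risk profile; profiles are weighted by
their population counts.

The **baseline profile** is the one whose risk is closest to the population
mean risk, with the mean taken on the risk (exponentiated) scale and ties
broken by lower risk, then lower index. All risks are rescaled by the
baseline to give relative risks (RR); each profile's 95% CI is
`exp(log RR ± 1.96·√Var S)` using its own variance. The CI multiplier is
1.96 throughout.

Categories follow CI-overlap rules, each profile receiving exactly one:

* **average** — its CI overlaps the baseline profile's CI (touching counts
  as overlap);
* **reduced** / **elevated** — its CI lies entirely below / above the
  baseline CI (strict inequality);
* **high** — among elevated profiles, the one with the lowest RR is the
  *first elevated* profile; any profile whose CI lies entirely above the
  first elevated profile's CI is promoted to high.

The reported `RiskDistribution` records the realized RR boundaries between
adjacent categories as (baseline CI low, baseline CI high, first-elevated CI
high) — the average band *is* the baseline CI. With a single-locus panel the
baseline (zero-dosage) profile has zero variance, so the first two
boundaries coincide at RR = 1; boundaries are therefore guaranteed
non-decreasing rather than strictly increasing. When no profile is elevated
the third boundary is +∞ (serialized as the string `"inf"` in JSON).

Because categorization of a genotyped cohort later uses these point
boundaries rather than recomputing per-sample CIs, a cohort member is placed
in the category whose RR interval contains its RR — matching how the
simulated population's category counts are defined. For profiles drawn from
the same panel the two views agree whenever CI width increases with RR,
which holds for panels of risk-increasing alleles.

## Cohort scoring

Samples with more than 10% missing genotypes are excluded (strictly greater;
a sample at exactly the threshold is retained). The wGRS is `Σᵢ gᵢ wᵢ` over
the panel's variants; on a fully typed sample it is numerically identical to
the population engine's log risk, by construction. Missing dosages default
to expected-dosage imputation (`2·p`, the HWE mean), which keeps scores
comparable across samples with different missingness patterns and leaves the
cohort mean unchanged in expectation under MCAR missingness; a `skip` policy
(drop the term) is available. The per-variant QC report gives the allele
frequency (mean non-missing dosage / 2; undefined, not zero, when all calls
are missing), the missing fraction, and a 1-df chi-square Hardy–Weinberg
test on control genotype counts.

## Performance evaluation

Orientation is fixed: higher wGRS = more case-like; a sample is called
positive when its score is ≥ the threshold.

* **ROC/AUC** — one operating point per distinct score plus a sentinel;
  trapezoidal AUC, which with those points equals the midrank Mann–Whitney
  probability P(case > control) + ½ P(tie).
* **DeLong variance and test** — placement values are computed via midranks;
  the AUC variance is `Var(V_case)/m + Var(V_control)/n` (sample variances,
  ddof 1), and the paired test of two models scored on the same samples uses
  the analogous placement-value covariance. The test statistic is compared
  to a standard normal, two-sided. If the variance of the AUC difference is
  zero the test degenerates: p = 1 for equal AUCs, a signed infinite
  statistic otherwise.
* **Youden threshold** — maximizes sensitivity + specificity; ties broken by
  higher specificity, then lower threshold.
* **Mann–Whitney** — exact enumeration when both groups have ≤ 20 samples
  and no ties; otherwise the normal approximation with tie and continuity
  corrections. U is counted for the cases, so `U/(m·n)` equals the AUC.
* **Predictive values** — `PPV = sens·π / (sens·π + (1−spec)(1−π))` and the
  analogous NPV at prevalence π (default 0.001, the approximate MS
  prevalence). Zero denominators yield NaN rather than an exception.
* Two-sided p-values throughout; AUCs are reported as percentages with one
  decimal.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the study's conditions: cohorts of 70 cases / 79 controls by default, panels
of ~111 independent biallelic loci with one strong HLA-like locus (OR 3.08,
risk-allele frequency 0.2013) and the rest drawn with ORs in 1.05–1.25 and
frequencies in 0.05–0.95, and MCAR missingness at a configurable rate (the
real data's per-sample missingness ran up to ~10%). Control genotypes are
HWE draws at `p`; case genotypes are HWE draws at the tilted frequency
`p′` above. That case distribution is exact only under the rare-disease
approximation and locus independence — appropriate here, since the modelled
disease has prevalence ≈ 1/1,000 and the risk model itself is
multiplicative. What the generator deliberately omits: linkage
disequilibrium, ascertainment bias, population stratification, genotyping
batch effects and environmental covariates. Tests passing on these cohorts
therefore validate the statistical machinery under the model's own
assumptions, not robustness to real-data artefacts.

`expected_auc` provides the generator's analytic AUC of the wGRS. For
panels of up to 12 loci the discrete case and control score distributions
are enumerated exactly (3^L profiles) and the AUC computed with midrank tie
handling; this matters for small panels, where the score is coarsely
discrete and a Gaussian approximation overstates the AUC (single HLA-like
locus: exact 0.681 vs normal 0.699). Beyond 12 loci the normal approximation
`Φ(Δμ / √(σ²_case + σ²_control))` on the exact per-locus moments is used;
in that many-locus regime the CLT makes it accurate to well under 0.01.

## Numerical and design notes

* Dosages are floats with NaN as the missing code; genotype TSVs use
  `NA`. The VCF reader counts risk-allele copies in GT calls and treats
  half-calls as missing.
* Population grouping uses exact row uniqueness of the integer dosage
  matrix; with many loci most profiles are unique and the grouping is a
  no-op, by design.
* The baseline tie rule, Youden tie rule and first-elevated rule are all
  deterministic, so a seed fully reproduces every output; CLI outputs embed
  a provenance block (seed, panel checksum, options).
* Problem sizes in the test suite are chosen so each statistical check has
  comfortable Monte-Carlo margin at a fixed seed: 100,000 individuals for
  population proportions (binomial SE ≤ 0.16 percentage points per
  category), 20,000 + 20,000 samples for AUC formula checks (MC error
  ≈ 0.003), 100 replicates × 6 loci for odds-ratio CI coverage, 10,000
  bootstrap replicates for the DeLong variance cross-check.

## Known limitations

* Confidence intervals reflect only summary-statistic sampling error, and
  the Woolf reconstruction is itself a modelling choice; other risk-
  stratification engines may include additional variance components, so
  interval *edges* are implementation-dependent. Category *proportions* are
  far more robust (profiles separated by an OR of 3 remain separated under
  any reasonable variance model).
* In-sample evaluation only: no cross-validation, no reclassification
  indices, matching the analysis the package reproduces.
* No liftover, strand-flipping heuristics, proxy-SNP lookup or reference-
  panel imputation; input panels and genotypes must already be harmonized
  to the same risk alleles.
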