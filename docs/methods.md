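# Methods

This note documents the statistical model behind `qtlmr`, the design choices
made where the design was genuinely open, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Two-sample cis-MR model

The exposure is a molecular trait (gene expression or protein abundance,
variance-standardized); the outcome is a binary disease analysed as a
case-control GWAS. Instruments are cis-QTLs: variants near the gene strongly
associated with its expression. Under the MR assumptions (relevance,
independence, exclusion restriction), the Wald ratio β_Y/β_X of a valid
instrument estimates the causal effect θ of one SD of the exposure on the
outcome's log-odds; multiple instruments are combined by fixed-effect IVW,
i.e. weighted regression of β_Y on β_X through the origin with weights
1/se_Y². Fixed-effect IVW (no multiplicative overdispersion scaling) is the
headline estimator; the scaling exists as an option but is off by default
since the significance criterion is defined on plain IVW.

### Instrument selection

Pipeline order per trait: cis-window restriction → study significance filter
→ greedy p-ordered LD clumping (ties broken by position then variant id) →
proxy substitution for instruments absent from the outcome → F filter →
allele harmonization. All comparators are strict as stated: F > 10,
proxy r² > 0.8, clumping retains r² ≤ 0.001. Defaults: cis-window ±1 Mb of
the TSS (per-study override supported), QTL threshold 5×10⁻⁸, clump window
10 Mb interpreted as ±5 Mb around the index variant (configurable — external
clumping tools are ambiguous on this point), proxy search confined to the
same window. F is computed from the exposure study's reported β/se, not
re-estimated. An empty instrument set is a valid outcome ("trait not
tested"), not an error.

### Harmonization

The outcome effect and EAF are flipped when its effect allele matches the
exposure's other allele, directly or on the complementary strand.
Palindromic variants (A/T, C/G) are resolved by EAF-side agreement and
dropped when either side's minor-allele frequency exceeds 0.42 (configurable)
or an EAF is missing; 0.42 is the conventional ambiguity cutoff in two-sample
MR tooling. Coordinates are 1-based; only biallelic SNVs are supported —
indels and multi-allelics are rejected at read time.

### Sensitivity suite

* **Weighted median** of per-instrument ratios with inverse-variance weights
  (delta-method ratio SEs, linear interpolation at cumulative standardized
  weight 0.5); SE by seeded parametric bootstrap, 1,000 draws by default.
* **MR-Egger**: weighted regression with intercept after orienting all β_X
  positive (β_Y flipped jointly — the orientation convention is stated
  because results are not invariant to it); multiplicative overdispersion
  with the residual scale floored at 1; t reference with J−2 df.
* **MR-PRESSO**: the global statistic is the weighted RSS of observed outcome
  effects around leave-one-out IVW predictions, with its null distribution
  from 1,000 parametric simulations under the fitted no-pleiotropy model
  (both β_X and β_Y resampled). Per-instrument outlier p-values are
  Bonferroni-thresholded at 0.05. The distortion test builds its null by
  removing random subsets of the same size as the outlier set (drawn
  uniformly over all instruments) and comparing the induced IVW shift to the
  observed raw→corrected shift, two-sided; when it fires at P < 0.05 the
  outlier-corrected estimate is carried forward, otherwise the raw one.
  Simulation count and seed are explicit arguments; runs are deterministic.
* **Steiger filtering**: per-variant, an instrument is kept iff it explains
  more variance in the exposure (2·maf·(1−maf)·β_X² on the standardized
  scale; F/(F+n−2) fallback when the EAF is missing) than in the outcome on
  the liability scale at prevalence K = 0.10 by default. The log-OR →
  liability-r² conversion composes the logistic-to-linear observed-scale step
  with the ascertained observed-to-liability transformation; the case
  fraction cancels, leaving r²_liab = β² · 2f(1−f) · (K(1−K)/φ(t))² with
  t = Φ⁻¹(1−K). This closed form is validated against a brute-force latent-
  variable simulation in the test suite. Filtering is applied per variant
  (drop discordant instruments) rather than as one global test, matching the
  per-SNP semantics of standard Steiger filtering, and is idempotent.
* **Concordance** across sensitivity estimates is defined as sign agreement
  with IVW over the *applicable* estimates — the weakest defensible reading
  of "concordant effect"; a CI-overlap variant is configurable. With a single
  instrument nothing is applicable and the flag is not-applicable.

### Colocalization and conditional analysis

Per-variant Wakefield log-ABFs use prior effect SDs 0.20 (quantitative trait)
and 0.15 (case-control, log-OR scale). Hypothesis posteriors PPH0–4 sum over
single-causal configurations, assembled in log space with the
S1+S2−S12 identity for H3; the brute-force configuration enumeration exists
independently in the tests. Priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵
(field-standard) and are recorded in output.

Conditional estimates are computed from marginal statistics plus reference
LD on the standardized-genotype scale: marginal z-scores are mapped to
standardized betas z/√(n−2+z²), the conditioning set is fitted jointly
through the LD submatrix (rejected when its condition number exceeds 10⁸),
and remaining variants are residualized. Stepwise signal selection seeds with
the min-p variant and adds conditionally significant variants (defaults:
p < 10⁻⁵ QTL side, 5×10⁻⁸ GWAS side; collinearity r² < 0.9; at most 10
signals). The pairwise-conditional scan runs only when the marginal PPH4
falls below 0.8 — a high marginal PPH4 is returned unchanged — and reports
the maximal PPH4 over all conditioned-vs-conditioned and
conditioned-vs-marginal pairs. The same ancestry's panel must serve both
traits; the panel is an explicit argument precisely because LD mismatch is a
known failure mode of cross-ancestry colocalization.

### Cascade, replication, meta-analysis

FDR correction is Benjamini–Hochberg, stratified per (cohort × tissue)
analysis. The causal call is the conjunction described in the README;
criteria that cannot be evaluated (single-instrument traits, short-circuited
layers) are recorded as not-applicable and excluded from the conjunction,
while the FDR and colocalization criteria are always required. The pipeline
computes sensitivity and colocalization lazily, only for FDR-significant
traits: a trait failing criterion 1 can never become causal, so the skipped
flags are reported not-applicable. The ambiguous wording of the
heterogeneity/pleiotropy criterion is resolved as requiring a
*non-significant* Egger intercept (p ≥ 0.05); the comparator is configurable.

Replication applies BH-FDR over exactly the discovery-causal traits testable
in the replication cohort; a trait replicates at q < 0.05 with a direction
concordant with the discovery IVW estimate. The five-criterion ladder (all
tested → nominal p → q < 5% → + sensitivity → + colocalization, the last
split by single- vs multi-instrument) recomputes the FDR within each row's
tested set and reports the proportion with replication q < 5%.

Cross-ancestry pooling uses random-effects IVW, DerSimonian–Laird by default
(closed form, exactly testable; REML iteration available), requiring ≥ 2
ancestries; Cochran's Q across ancestries is reported. A caveat worth
stating: with k = 2 equal-precision cohorts, DL gives τ² = max(0, (Q−1))·v,
so the pooled SE exceeds the inputs' SE whenever Q > 2 — an event of
probability ≈ 16% even under exact homogeneity. Pooling therefore tightens
the SE in most, not all, replicates; this is a property of truncated
random-effects estimators at k = 2, not an implementation artifact.

### Power and MDE

NCP = b_MR²/var(b_MR) with b_MR = K(OR/(1+K(OR−1)) − 1) and
var(b_MR) = (K(1−K) − b_MR²)/(N·R²); power is the upper tail of a
noncentral χ²(1, NCP) beyond the central (1−α) quantile, α = 0.05 by
default. Two transcription variants of these formulas circulate: a product
form of var(b_MR) under which the NCP is independent of OR (no MDE can then
exist), and an R² summand without the squared effect (which can go
negative). The difference form and the squared-effect R² are the defaults —
they reproduce the behaviour of the standard mRnd-style calculator and are
validated against a Monte-Carlo oracle — while the product/unsquared forms
remain available behind `form="printed"` for comparison. The MDE is found by
bisection to 10⁻⁶ in OR on the risk side (OR > 1) and symmetrically on the
protective side; when b_MR approaches its ceiling √(K(1−K)) the variance
form degenerates and power saturates at 1.

### Post-analysis

A gene counts as expressed in a tissue when median TPM is strictly above 0.1.
Enrichment uses two-sided Fisher exact tests on 2×2 tables over tested genes;
fold enrichment is the percentage of causal calls inside the set over the
percentage outside; infinite odds ratios are reported as a sentinel with the
exact p still computed. Tissue-cluster enrichment retains only (tissue,
cluster) pairs sharing at least one causal gene, BH-corrected. Locus-overlap
grouping uses a 1 Mb window centered on the gene-body midpoint, with
membership in the reference set taking precedence over proximity.

## The synthetic-data generator

The generator is individual-level so that marginal statistics, LD and
case-control ascertainment are mutually consistent:

* **Genotypes**: two haplotypes per individual from a latent Gaussian AR(1)
  chain thresholded at Φ⁻¹(EAF) (Hardy–Weinberg by construction). Because
  thresholding attenuates correlation, the latent adjacent-pair correlation
  is numerically inverted (bivariate-normal CDF, frequencies rounded to 0.01
  for caching) so the *dosage* LD matches the requested AR(1) profile.
* **Expression**: y = s·Gγ + ε with s chosen so the genetic variance equals
  the target cis-heritability and the total variance is 1; per-variant
  marginal OLS gives β/se/p/EAF.
* **Outcome**: liability ℓ = θ_liab·expr + Gδ + ε with unit total variance;
  case iff ℓ exceeds Φ⁻¹(1−K). The causal effect θ is specified on the
  marginal log-OR-per-SD scale — the scale MR estimates — and converted
  internally via θ_liab = θ·K(1−K)/φ(Φ⁻¹(1−K)); δ holds per-variant direct
  (pleiotropic) liability effects. Cases and controls are ascertained by
  chunked rejection sampling and analysed by vectorized per-variant logistic
  regression (Newton–Raphson on the two-parameter model).
* **Studies**: one panel per ancestry with block-diagonal LD (one dense block
  per gene locus; a dense genome-wide matrix would be prohibitively large);
  causal-variant positions and effects shared across ancestries while allele
  frequencies and LD are ancestry-specific; across tissues the architecture
  follows a sharing rule (shared / independent / sign-flipped) with a
  designated causal tissue driving the outcome. Outcome cohorts are drawn
  independently per gene locus: loci are unlinked, so per-locus marginal
  statistics are distributionally equivalent to one genome-wide cohort while
  memory stays bounded. An `architecture_seed` separates the causal
  architecture from cohort noise, so discovery and replication cohorts of
  the same study are generated by varying the cohort seed.
* A fast multivariate-normal z-score generator (z ~ MVN(Rλ, R)) serves
  colocalization-scale experiments where individual-level simulation adds
  nothing.

All randomness flows from explicit integer seeds through named generators;
there is no global random state.

**What it does not emulate**: realistic human LD maps (haplotype blocks,
recombination hotspots), imputation uncertainty, relatedness and admixture,
winner's-curse in QTL discovery, assay-specific measurement error, sample
overlap between exposure and outcome, and trans-QTL architecture. Passing
tests therefore demonstrate the *statistical machinery* is correct and
calibrated under the stated generative model — not that real-data analyses
are immune to violations these features can induce.

## Problem sizes

Validation and the reproduction script use desk-scale simulations chosen to
make Monte-Carlo bounds meaningful: 100 random instrument sets for the
estimator/oracle check; 50 random loci (≤ 200 variants) for the
colocalization oracle; 50 (tests) / 30 (script) multi-signal loci for the
conditional-rescue rate; a 100-gene × 2-ancestry null study (≥ 200 trait
analyses) for type-I control; 200 (tests) / 100 (script) replicates at
θ = log 1.3 with 10 instruments and 20,000 cases + 20,000 controls per
ancestry for coverage and meta-analysis behaviour; 100–200 MR-PRESSO
replicates with 20 instruments; a 30-gene (10 causal) high-power study for
the replication ladder.

## Known limitations

* The COJO-style conditional step keeps the marginal SE (standard
  approximation); it tracks a full joint regression to ~10% relative error
  at n ≥ 10,000 but degrades in extreme LD.
* The liability↔log-OR conversion is first-order; at very large per-variant
  effects the induced bias becomes visible relative to tiny SEs.
* Weighted-median SE is bootstrap-based and hence seed-dependent;
  MR-PRESSO p-values are simulation-based with resolution 1/(n_sim+1).
* Multivariable MR, SuSiE-based colocalization, mode-based estimators and
  trans instruments are out of scope.
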