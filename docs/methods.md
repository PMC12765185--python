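# Methods

## The switching phenotype

The caller operates on each person's ordered sequence of study-pair fills
(all other ATC codes are ignored; concomitant medication is out of scope).
Within a person, fills are sorted by (date, ATC code); the date tie-break
by ATC code only matters for same-day fills of both drugs on the first
date, in which case the first drug is undefined and the person is excluded
with reason `ambiguous_first` (counted and logged). Duplicate same-day
fills of one drug are retained — registry fills are events and no
deduplication rule is imposed.

Decision order for direction A→B: fewer than `min_fills` study-drug fills →
excluded (`min_fills`); first fill not drug A → excluded (`first_drug`);
ambiguous first date → excluded (`ambiguous_first`); no drug-B fill →
control; otherwise the *tail* is the fills strictly after the first drug-B
fill — an empty tail is a control (annotated `empty_tail`), and a tail with
B-fraction ≥ `tail_threshold` (default 0.5, "at least" semantics: equality
is a case) is a case.

Two readings of the eligibility and tail rules are genuinely open, and both
are exposed rather than decided silently:

- `min_fills` applies to the two drugs **combined** by default (the cohort
  is described by its total study-drug fills); `per_drug=True` applies the
  floor to either drug separately.
- The first drug-B fill is **excluded** from the tail by default (the
  literal reading of "subsequent" fills, and the stricter notion of a
  *consistent* switch); `tail_includes_first_b=True` implements the
  inclusive alternative. Under the default, `A B` patterns with nothing
  after the first B are controls — one fill of the new drug is no evidence
  of a consistent switch.

The cohort summary reports the switch percentage as cases / starters, where
starters are persons whose first fill is the origin drug and who meet the
fill floor. Ambiguous-first persons are excluded from that denominator;
their count is reported separately so the alternative denominator can be
formed.

## Association models

All genetic effects are additive in effect-allele dose. Binary outcomes use
maximum-likelihood logistic regression (statsmodels `Logit`), quantitative
traits OLS; both report Wald SEs, 95% Wald CIs and two-sided normal
p-values. The study this emulates used linear mixed models to absorb
relatedness; synthetic cohorts have none, so plain regression stands in —
a documented fidelity gap, not an approximation of the mixed model.
Default covariates are sex (in pooled fits) and year of birth when present;
the original covariate set is unpublished, so covariates are configuration,
not doctrine.

Perfect separation or non-convergence yields a *flagged* result (`p = 1`,
NaN effect, a `separation` flag) rather than an exception, so genome-scale
loops survive degenerate variants. Missing doses are dropped per variant
(complete case) and the dropped count is flagged on the result.

The sex-difference test is the standard independent-strata heterogeneity z
on the log-OR scale. Reconstructing the SEs from published sex-stratified
CIs (SE = ln(U/L)/(2·1.96)) reproduces published difference p-values to
within rounding of 2-decimal ORs, which is the test's validation anchor. A
genotype×sex interaction Wald test is provided as an alternative; the
z-test is the default because it needs only stratum-level summaries.

Rank-based inverse normalization uses Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4)),
with average ranks for ties, applied to the pooled sample (per-stratum
transforms can be done by fitting per stratum). The transform makes effects
SD-scaled and rank-invariant; the exact transform used for the original
taste ratings is unpublished, so Blom — the common GWAS choice — is used.

Conditional analysis refuses r² = 1 conditioning and rank-deficient joint
dose matrices by name. With r² = 0.93 between target and conditioner, the
conditional SE inflates by 1/√(1−r²) ≈ 3.8; at n = 40 000 and a true
per-allele OR of 1.29 that puts the expected Wald z near 3.3, i.e. ~75–80%
power at α = 0.01. The two-signal test therefore asserts a majority of
seeded runs significant and a median p < 0.01, the level the simulation
itself establishes — not near-certainty, which this design cannot deliver.

The weighted-Bonferroni scheme assigns variant class c the threshold
`α·w_c / Σ_v w_class(v)`, conserving the α budget exactly (tested to
1e-12). The default is a single class (plain Bonferroni); multi-class
weights are configuration because the published weighting is external to
this package. Significance is strict (`p < threshold`); a p-value exactly
at the threshold is not significant.

The Hardy–Weinberg check is an exact conditional test (the distribution of
the heterozygote count given the rare-allele count), reported as a mid-p —
half weight on outcomes exactly as probable as the observed one — which has
better size than the plain exact p. It requires hard calls; fractional
dosages get EAF only.

## The synthetic cohort: what it emulates, what it does not

The generator states one world and the tests measure it; its defaults are
the discovery-cohort anchors: n = 40 000 zopiclone starters, EAF 0.446,
baseline switch rate 14%, per-allele ORs 1.36 (female) / 1.19 (male), 59%
female. Per-sex intercepts are solved numerically (Brent) so that the
HWE-averaged switch probability equals the baseline rate — the published
anchors are population rates, not intercepts.

Fill counts are shifted-geometric with floor `fills_min` (default 3) and
mean `fills_mean` (default 10): right-skewed like real refill data, one
parameter, floor chosen so every simulated person passes eligibility by
construction. The default mean of 10 fills is a realistic refill count for
chronic hypnotic use over a multi-year registry window; the true
distribution is unpublished, so the parameter is exposed in `SimConfig`.
Dates advance one fill per 30 days from 2003-01-01 — dates only carry
ordering information in this design.

Sequences are constructed inside the caller's decision regions: switcher
tails carry ≥ 75% drug-B fills, non-switcher excursions ≤ 25% (or an empty
tail), both bounded away from the 50% threshold, so the caller reproduces
the latent label *exactly* and parameter-recovery tests measure the
statistics, not boundary noise. Consequences: a green round-trip test
establishes that calling inverts this generator, not that the rule is
robust to real-world boundary patterns (those are covered separately by the
exhaustive rule-oracle tests); and the generator does not emulate stockout
dynamics, censoring, co-medication, dose tapering, or calendar effects.

Linked pairs are drawn per chromosome from the four-haplotype table with
`D = +√(r²·p₁q₁p₂q₂)` (positive-sign convention); infeasible (p₁, p₂, r²)
triples fail with the violated Lewontin bound in the message. Quantitative
traits default to unit marginal variance (noise SD solved from the dose
variance), so the generative `beta_sd` is directly comparable to the
estimate after rank normalization; an explicit `trait_noise_sd` overrides
this.

Randomness: one `SeedSequence` per run, spawned deterministically into
per-component streams (genotypes, sex, latent status, fills, trait), so
identical configs give byte-identical output files.

## Numerical choices and degenerate inputs

- Allele frequencies and baseline rates must lie strictly inside (0, 1)
  (tolerance 1e-9); boundary values are rejected as degenerate.
- Intercept solving brackets β₀ in [−40, 40] (|logit| > 40 is saturated in
  double precision).
- CI half-width uses z = Φ⁻¹(0.975) throughout, matching the Wald tests.
- 2×2 tables with a zero cell get the Haldane–Anscombe 0.5 correction and
  a flag; negative cells are rejected.
- Collinearity refusal threshold: |r| > 1 − 1e-10 between target and
  conditioning dose.
- p-values are floored at the smallest positive double to keep downstream
  log-scale handling finite.

## Known limitations

- No relatedness/mixed-model correction, imputation-quality handling, or
  cross-cohort meta-analysis; replication means re-running the pipeline on
  a second cohort.
- The phenotype treats the full fill history as one episode by design;
  episode segmentation by gap length is out of scope.
- The per-seed sampling SE of the recovered OR at n = 40 000 is ≈ 0.027, so
  single-seed estimates scatter around the generative value; headline
  recoveries are reported as a median over 20 seeds (or a mean over 200
  replicates for the trait effect) for that reason.
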