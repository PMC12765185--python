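# rxswitch

Pharmacogenetic analysis of **drug switching** derived from electronic
prescription records, built around the zopiclone↔zolpidem use case
(nonbenzodiazepine "Z-drug" hypnotics, ATC codes N05CF01 and N05CF02).
Switching between two drugs of comparable efficacy is a registry-observable
proxy for intolerance — for zopiclone, chiefly its taste-distortion side
effect — so genetic variants that predict switching can inform which drug
to prescribe first.

The package is aimed at statistical geneticists and pharmacoepidemiologists
who have (a) longitudinal fill records, (b) genotypes, and (c) a sample
sheet, and who want a reproducible path from raw fills to GWAS-style
summary statistics. Because real prescription registries are
access-controlled, a synthetic-cohort generator with known effects is a
first-class component: every statistic in the package can be validated by
parameter recovery before touching real data.

## What it computes

**Phenotype.** A person is a *switcher* (case) from drug A to drug B if
their first recorded study-drug fill is drug A and, among the fills
strictly after their first drug-B fill, at least 50% are drug B; a
*control* starts on drug A but never reaches that fraction (including
never trying B). Persons with fewer than 3 study-drug fills are excluded
(a consistent switch cannot be inferred from 1–2 fills). The B→A direction
is the mirror image; a person's first drug decides which direction applies.

**Association.** With effect-allele dose g ∈ {0, 1, 2} (or a fractional
dosage), case status y, and covariates x:

- additive logistic model `logit P(y=1) = β₀ + β·g + γᵀx`, Wald tests and
  95% CIs, odds ratio `OR = e^β`;
- sex-stratified fits compared with the heterogeneity z-test
  `z = (β_F − β_M) / √(SE_F² + SE_M²)` (a genotype×sex interaction test is
  also provided);
- conditional analysis: re-testing a variant with another variant's dose
  as a covariate, to ask whether two correlated signals are distinct;
- quantitative traits (e.g. bitter-taste intensity ratings) by OLS after a
  Blom rank-based inverse-normal transform
  `Φ⁻¹((rank − 3/8)/(n + 1/4))`, so effects are in SD units;
- 2×2 contingency odds ratios with Woolf CIs, genotype-dose LD r², EAF and
  an exact Hardy–Weinberg mid-p test, and class-weighted Bonferroni
  significance thresholds (`0.05·w_c / Σ_v w_class(v)`).

**Simulation.** Genotypes under Hardy–Weinberg equilibrium; linked variant
pairs at a target genotype r² via the two-locus haplotype construction
(`D = √(r²·p₁q₁p₂q₂)`, rejected loudly when it violates the Lewontin
bound); switch status from a per-sex logistic model whose intercepts are
solved so the population switch rate matches a target baseline; fill
sequences emitted inside the caller's decision regions so the latent label
round-trips exactly; quantitative traits with per-allele effects in SD
units.

## Worked example

Simulate an Iceland-scale cohort (40 000 zopiclone starters, EAF 0.446,
baseline switch rate 14%, per-allele OR 1.36 in women / 1.19 in men — the
generator defaults), call the phenotype, and fit the association:

```python
import rxswitch as rx

cohort = rx.simulate_switch_cohort(rx.SimConfig(n_individuals=40_000, seed=11))
calls = rx.call_cohort(cohort.records, rx.DrugPair())
print(calls.summary["A->B"])
# {'n_starters': 40000, 'n_cases': 5535, 'n_controls': 34465,
#  'n_excluded_by_reason': {}, 'switch_pct': 13.8375}

ab = calls.calls.query("direction == 'A->B' and status in ('case','control')")
merged = (ab.set_index("person_id")
            .join(cohort.genotypes)
            .join(cohort.samples.set_index("person_id")))
model = rx.LogisticAssociation(
    (merged["status"] == "case").astype(float), merged["v1"],
    covariates=(merged["sex"] == "F").astype(float).to_frame("female"),
    variant_id="rs_sim",
)
print(model.fit().summary())
# Association: rs_sim  [logistic, stratum=all]
#   n = 40000  (cases 5535 / controls 34465)
#   beta = 0.2834  SE = 0.0205  95% CI [0.2431, 0.3237]  p = 2.86e-43
#   OR = 1.3276  95% CI [1.2752, 1.3822]
```

The called switch rate (13.8%) matches the generative baseline (14%), and
the pooled per-allele OR estimate 1.33 [1.28, 1.38] brackets the female/male
mixture of the generative ORs (1.36/1.19 at 59% female). Stratifying by sex
recovers OR 1.42 [1.35, 1.50] in women and 1.20 [1.13, 1.28] in men
(heterogeneity z = 4.02, p = 5.8×10⁻⁵ on this realization).

The same analyses run from the shell:

```bash
rxswitch simulate --config sim.yaml --out data/
rxswitch call --rx data/prescriptions.tsv --min-fills 3 --threshold 0.5 --out pheno.tsv
rxswitch assoc --pheno pheno.tsv --geno data/genotypes.vcf \
               --samples data/samples.tsv --stratify-sex --condition-on v2
rxswitch run --config run.yaml       # full pipeline into a run directory
```

## Acceptance script

`scripts/acceptance.py` recomputes the pipeline's headline parameter
recoveries from scratch — the per-allele switching odds ratio from an
end-to-end simulate→call→fit run (median over 20 seeds at n = 40 000), the
per-allele quantitative-trait effect in SD units under rank-inverse-normal
association (mean over 200 replicates at n = 2238), and the realized r² of
a simulated linked variant pair at n = 50 000 — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/rxswitch/phenotype.py` — fill filtering, switch-rule caller, cohort summaries
- `src/rxswitch/simulate.py` — synthetic cohorts, LD pairs, traits, writers
- `src/rxswitch/association.py` — model/results classes and the statistics above
- `src/rxswitch/pipeline.py`, `cli.py` — orchestration, reporting, CLI verbs
- `docs/methods.md` — model assumptions, parameter defaults, numerical choices
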