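"""Registry-style synthetic cohorts with known genetic effects.

The generator produces the three inputs the pipeline consumes — a
prescription fill stream, a genotype matrix, and a sample sheet — from a
declarative :class:`SimConfig`.  Genotypes are drawn under Hardy–Weinberg
equilibrium; a second variant can be generated jointly at a target genotype
r² via the standard two-locus haplotype-frequency construction; switch
status follows a per-sex logistic model in effect-allele dose; and fill
sequences are emitted so that the phenotype caller recovers the latent
switch label exactly (tail fractions are bounded away from the calling
threshold by construction).

Defaults mirror the Icelandic discovery cohort: effect-allele frequency
0.446, baseline zopiclone->zolpidem switch rate 14%, per-allele odds ratios
1.36 (female) and 1.19 (male), 59% female.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .phenotype import ZOPICLONE_ATC, ZOLPIDEM_ATC

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_linked_pair",
    "simulate_switch_cohort",
    "simulate_quantitative_trait",
    "solve_intercept",
    "write_cohort",
]

_EAF_EPS = 1e-9
_FILL_ORIGIN = pd.Timestamp("2003-01-01")
_FILL_STEP_DAYS = 30
# switcher tails carry >= 75% destination-drug fills, non-switcher
# excursions <= 25%, so calls at the 50% threshold are unambiguous
_SWITCH_TAIL_MIN = 0.75
_EXCURSION_TAIL_MAX = 0.25


@dataclass
class SimConfig:
    """Full generative parameterization of a synthetic switching cohort."""

    n_individuals: int = 40_000
    female_fraction: float = 0.59
    eaf: float = 0.446
    or_per_allele_female: float = 1.36
    or_per_allele_male: float = 1.19
    baseline_switch_rate: float = 0.14
    fills_min: int = 3
    fills_mean: float = 10.0
    seed: int = 0
    # optional second, linked variant
    eaf2: float | None = None
    target_r2: float | None = None
    # optional quantitative trait (per-allele effect in SD units)
    beta_sd: float | None = None
    trait_noise_sd: float | None = None
    # fraction of non-switchers who get a minority drug-B excursion
    excursion_fraction: float = 0.35
    drug_a_atc: str = ZOPICLONE_ATC
    drug_b_atc: str = ZOLPIDEM_ATC

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0, 1]")
        _check_eaf(self.eaf, "eaf")
        if not (_EAF_EPS < self.baseline_switch_rate < 1 - _EAF_EPS):
            raise ValueError("baseline_switch_rate must be strictly inside (0, 1)")
        if self.or_per_allele_female <= 0 or self.or_per_allele_male <= 0:
            raise ValueError("odds ratios must be positive")
        if self.fills_min < 3:
            raise ValueError("fills_min must be >= 3 (eligibility floor)")
        if self.fills_mean < self.fills_min:
            raise ValueError("fills_mean must be >= fills_min")
        if (self.eaf2 is None) != (self.target_r2 is None):
            raise ValueError("eaf2 and target_r2 must be given together")
        if self.eaf2 is not None:
            _check_eaf(self.eaf2, "eaf2")
            # fails loudly if the triple is infeasible
            haplotype_frequencies(self.eaf, self.eaf2, self.target_r2)
        if self.trait_noise_sd is not None and self.trait_noise_sd <= 0:
            raise ValueError("trait_noise_sd must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _check_eaf(eaf: float, name: str) -> None:
    if not (_EAF_EPS < eaf < 1 - _EAF_EPS):
        raise ValueError(f"{name} must be strictly inside (0, 1); got {eaf!r}")


def simulate_genotypes(n: int, eaf: float, seed: int | np.random.Generator) -> pd.DataFrame:
    """Sample effect-allele doses for one biallelic variant under HWE.

    Returns a one-column DataFrame (column ``v1``) of doses in {0, 1, 2}
    indexed by person id, with genotype frequencies (1-p)^2, 2p(1-p), p^2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_eaf(eaf, "eaf")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dose = rng.binomial(2, eaf, size=n)
    return pd.DataFrame({"v1": dose}, index=_person_index(n))


def haplotype_frequencies(p1: float, p2: float, r2: float, sign: int = 1) -> np.ndarray:
    """Two-locus haplotype frequencies [h11, h10, h01, h00] at a target r².

    D = sign * sqrt(r² p1 q1 p2 q2); the construction fails with an explicit
    message when D exceeds the Lewontin bound (a haplotype frequency would
    go negative).
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("target_r2 must be in [0, 1]")
    _check_eaf(p1, "eaf1")
    _check_eaf(p2, "eaf2")
    q1, q2 = 1 - p1, 1 - p2
    d = sign * math.sqrt(r2 * p1 * q1 * p2 * q2)
    h = np.array([p1 * p2 + d, p1 * q2 - d, q1 * p2 - d, q1 * q2 + d])
    if (h < -1e-12).any():
        dmax = min(p1 * q2, q1 * p2) if sign > 0 else min(p1 * p2, q1 * q2)
        raise ValueError(
            f"infeasible LD target: r2={r2}, eaf1={p1}, eaf2={p2} requires "
            f"|D|={abs(d):.6g} > Lewontin bound {dmax:.6g} "
            f"(a haplotype frequency would be negative)"
        )
    return np.clip(h, 0.0, None) / np.clip(h, 0.0, None).sum()


def simulate_linked_pair(
    n: int,
    eaf1: float,
    eaf2: float,
    target_r2: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Sample two linked variants at a target genotype-dose r².

    Each individual is formed from two independent chromosomes, each a
    haplotype drawn from the four-class frequency table; the realized
    squared dose correlation approximates ``target_r2``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h = haplotype_frequencies(eaf1, eaf2, target_r2)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # haplotype classes: 0 = (1,1), 1 = (1,0), 2 = (0,1), 3 = (0,0)
    hap = rng.choice(4, size=(n, 2), p=h)
    allele1 = np.isin(hap, (0, 1)).astype(np.int64)
    allele2 = np.isin(hap, (0, 2)).astype(np.int64)
    return pd.DataFrame(
        {"v1": allele1.sum(axis=1), "v2": allele2.sum(axis=1)}, index=_person_index(n)
    )


def solve_intercept(or_per_allele: float, eaf: float, target_rate: float) -> float:
    """Intercept beta0 such that E_dose[expit(beta0 + ln(OR) * dose)] = target_rate.

    The expectation is over HWE genotype frequencies at ``eaf``; this anchors
    the generator on the observed population switch rate rather than on an
    arbitrary non-carrier intercept.
    """
    log_or = math.log(or_per_allele)
    p = eaf
    w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])

    def mean_rate(b0: float) -> float:
        return float(w @ expit(b0 + log_or * np.arange(3))) - target_rate

    return brentq(mean_rate, -40.0, 40.0, xtol=1e-12)


@dataclass
class SimulatedCohort:
    """Everything one simulation run produced, including the latent truth."""

    records: pd.DataFrame  # person_id, date, atc_code
    genotypes: pd.DataFrame  # person x variant dose
    samples: pd.DataFrame  # person_id, sex, yob
    latent: pd.Series  # true switch indicator per person
    trait: pd.Series | None = None
    config: SimConfig | None = None


def simulate_switch_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate prescriptions, genotypes and a sample sheet from ``config``.

    Switch status is latent-first: each person's indicator is drawn from
    logit P(switch) = beta0(sex) + ln(OR_sex) * dose, with the per-sex
    intercepts solved so the average switch rate at the configured EAF
    equals ``baseline_switch_rate``.  Fill sequences are then constructed
    inside the caller's decision regions, so calling them reproduces the
    latent labels exactly:

    * switchers: >=1 drug-A fill, then the first drug-B fill, then a
      non-empty tail with >= 75% drug-B fills;
    * non-switchers: either all drug-A fills, or a drug-B excursion whose
      tail carries <= 25% drug-B fills (or is empty).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_sex, rng_latent, rng_fills, rng_trait = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = cfg.n_individuals

    if cfg.eaf2 is not None:
        genotypes = simulate_linked_pair(n, cfg.eaf, cfg.eaf2, cfg.target_r2, rng_geno)
    else:
        genotypes = simulate_genotypes(n, cfg.eaf, rng_geno)
    dose = genotypes["v1"].to_numpy()

    female = rng_sex.random(n) < cfg.female_fraction
    b0_f = solve_intercept(cfg.or_per_allele_female, cfg.eaf, cfg.baseline_switch_rate)
    b0_m = solve_intercept(cfg.or_per_allele_male, cfg.eaf, cfg.baseline_switch_rate)
    logit = np.where(
        female,
        b0_f + math.log(cfg.or_per_allele_female) * dose,
        b0_m + math.log(cfg.or_per_allele_male) * dose,
    )
    latent = rng_latent.random(n) < expit(logit)

    records = _emit_fill_sequences(latent, cfg, rng_fills)

    samples = pd.DataFrame(
        {
            "person_id": genotypes.index,
            "sex": np.where(female, "F", "M"),
            "yob": rng_sex.integers(1930, 1990, size=n),
        }
    )
    trait = None
    if cfg.beta_sd is not None:
        trait = simulate_quantitative_trait(
            genotypes, cfg.beta_sd, noise_sd=cfg.trait_noise_sd, seed=rng_trait
        )
    return SimulatedCohort(
        records=records,
        genotypes=genotypes,
        samples=samples,
        latent=pd.Series(latent, index=genotypes.index, name="latent_switch"),
        trait=trait,
        config=cfg,
    )


def _emit_fill_sequences(
    latent: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill sequences per person, one fill per 30-day step from a common origin."""
    n = latent.shape[0]
    # shifted geometric fill counts with floor fills_min (right-skewed)
    p_geom = 1.0 / (cfg.fills_mean - cfg.fills_min + 1.0)
    n_fills = cfg.fills_min + rng.geometric(p_geom, size=n) - 1

    # switcher anatomy: a leading drug-A run, the first drug-B fill, a tail
    # sequences are laid out in a flat boolean array (True = drug B)
    total = int(n_fills.sum())
    is_b_flat = np.zeros(total, dtype=bool)
    offsets = np.concatenate(([0], np.cumsum(n_fills)))
    excursion = (~latent) & (rng.random(n) < cfg.excursion_fraction)

    u_prefix = rng.random(n)
    u_tailb = rng.random(n)
    for i in np.flatnonzero(latent | excursion):
        m = int(n_fills[i])
        if latent[i]:
            # prefix 1..m-2 A's, then first B at index a, tail length >= 1
            a = 1 + int(u_prefix[i] * (m - 2))  # in [1, m-2]
            t = m - a - 1
            b_min = math.ceil(_SWITCH_TAIL_MIN * t)
            n_b_tail = b_min + int(u_tailb[i] * (t - b_min + 1))
        else:
            a = 1 + int(u_prefix[i] * (m - 1))  # in [1, m-1]; tail may be empty
            t = m - a - 1
            b_max = math.floor(_EXCURSION_TAIL_MAX * t)
            n_b_tail = int(u_tailb[i] * (b_max + 1))
        seg = is_b_flat[offsets[i] : offsets[i + 1]]
        seg[a] = True
        if n_b_tail > 0:
            tail_idx = a + 1 + rng.permutation(t)[:n_b_tail]
            seg[tail_idx] = True

    person_idx = np.repeat(np.arange(n), n_fills)
    step = np.arange(total) - np.repeat(offsets[:-1], n_fills)
    dates = _FILL_ORIGIN + pd.to_timedelta(step * _FILL_STEP_DAYS, unit="D")
    persons = _person_index(n)
    return pd.DataFrame(
        {
            "person_id": persons[person_idx],
            "date": dates.strftime("%Y-%m-%d"),
            "atc_code": np.where(is_b_flat, cfg.drug_b_atc, cfg.drug_a_atc),
        }
    )


def simulate_quantitative_trait(
    genotypes: pd.DataFrame | np.ndarray,
    beta_sd: float,
    noise_sd: float | None = None,
    seed: int | np.random.Generator = 0,
    variant: str | int = 0,
) -> pd.Series:
    """Quantitative trait with a per-allele effect in SD units.

    trait = beta_sd * dose + N(0, noise_sd).  When ``noise_sd`` is None it
    is set so the marginal trait variance is 1 (using the empirical dose
    variance), making ``beta_sd`` directly interpretable on the SD scale
    after rank-based standardization.
    """
    if not np.isfinite(beta_sd):
        raise ValueError("beta_sd must be finite")
    if isinstance(genotypes, pd.DataFrame):
        col = genotypes.columns[variant] if isinstance(variant, int) else variant
        dose = genotypes[col].to_numpy(dtype=float)
        index = genotypes.index
    else:
        dose = np.asarray(genotypes, dtype=float)
        index = _person_index(dose.shape[0])
    if noise_sd is None:
        resid_var = 1.0 - beta_sd**2 * float(np.var(dose))
        if resid_var <= 0:
            raise ValueError("beta_sd too large for unit marginal variance; pass noise_sd")
        noise_sd = math.sqrt(resid_var)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = beta_sd * dose + rng.normal(0.0, noise_sd, size=dose.shape[0])
    return pd.Series(y, index=index, name="trait")


def _person_index(n: int) -> pd.Index:
    width = max(6, len(str(n)))
    return pd.Index([f"P{i:0{width}d}" for i in range(n)], name="person_id")


# ---------------------------------------------------------------------------
# on-disk formats


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write prescriptions TSV, sample sheet TSV, dosage TSV and VCF 4.2."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "prescriptions": out / "prescriptions.tsv",
        "samples": out / "samples.tsv",
        "dosages": out / "dosages.tsv",
        "vcf": out / "genotypes.vcf",
        "latent": out / "latent_truth.tsv",
    }
    cohort.records.to_csv(paths["prescriptions"], sep="\t", index=False)
    samples = cohort.samples
    if cohort.trait is not None:
        samples = samples.merge(
            cohort.trait.rename("trait"), left_on="person_id", right_index=True, how="left"
        )
    samples.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")
    cohort.genotypes.T.to_csv(paths["dosages"], sep="\t", index_label="variant_id")
    write_vcf(cohort.genotypes, paths["vcf"])
    cohort.latent.astype(int).to_frame().to_csv(paths["latent"], sep="\t")
    return paths


def write_vcf(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Write hard-call doses as a minimal VCF 4.2 (GT field, placeholder contig)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    persons = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrS,length=1000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(persons) + "\n")
        for j, vid in enumerate(genotypes.columns):
            doses = genotypes[vid].to_numpy()
            calls = "\t".join(gt_map[int(round(d))] for d in doses)
            fh.write(f"chrS\t{1000 * (j + 1)}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")
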