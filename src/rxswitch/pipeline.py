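"""End-to-end orchestration: simulate or load → call phenotype → associate.

A :class:`RunConfig` names either real input files (prescriptions, genotypes,
sample sheet) or a :class:`~rxswitch.simulate.SimConfig` — never both — plus
the drug pair, the analyses to run, and the significance scheme.
:func:`run_pipeline` executes the stages, writes the phenotype table, the
GWAS-style summary-statistics TSV and a JSON report into the run directory,
and returns the report.  Identical configs (including the seed) produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    AssociationResult,
    ThresholdScheme,
    apply_threshold_scheme,
    conditional_assoc,
    eaf_and_hwe,
    linear_assoc,
    logistic_assoc,
    sex_difference_test,
)
from .io import (
    SUMSTATS_COLUMNS,
    config_hash,
    provenance_header,
    read_genotypes,
    read_prescriptions,
    read_samples,
    write_table,
)
from .phenotype import Direction, DrugPair, Status, call_cohort
from .simulate import SimConfig, simulate_switch_cohort

logger = logging.getLogger("rxswitch")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "forest_table"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible run: inputs, analyses, outputs.

    Exactly one of ``sim`` (a SimConfig) or the three real-input paths
    (``prescriptions``, ``genotypes``, ``samples``) must be given.
    """

    out_dir: str = "rxswitch_run"
    seed: int = 0
    sim: SimConfig | None = None
    prescriptions: str | None = None
    genotypes: str | None = None
    samples: str | None = None
    pair: DrugPair = field(default_factory=DrugPair)
    directions: tuple[str, ...] = (Direction.A_TO_B.value, Direction.B_TO_A.value)
    stratify_sex: bool = True
    covariates: tuple[str, ...] = ("yob",)  # sample-sheet columns; sex added when present
    condition_on: str | None = None
    trait_column: str | None = None
    trait_transform: bool = True
    scheme: ThresholdScheme = field(default_factory=ThresholdScheme.single_class)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        real = [self.prescriptions, self.genotypes, self.samples]
        has_real = any(p is not None for p in real)
        if self.sim is not None and has_real:
            raise ValueError("config must name either simulated or real inputs, not both")
        if self.sim is None and not all(p is not None for p in real):
            raise ValueError(
                "config must provide a SimConfig or all of prescriptions/genotypes/samples"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "pair" in raw and raw["pair"] is not None:
            raw["pair"] = DrugPair(**raw["pair"])
        if "scheme" in raw and raw["scheme"] is not None:
            raw["scheme"] = ThresholdScheme(**raw["scheme"])
        for key in ("directions", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load → phenotype → association; write the run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logger.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> dict:
    cfg_dict = config.to_dict()
    seed = config.seed

    # ---- stage 1: inputs --------------------------------------------------
    try:
        if config.sim is not None:
            sim = SimConfig(**{**asdict(config.sim), "seed": seed})
            cohort = simulate_switch_cohort(sim)
            records, genotypes, samples = cohort.records, cohort.genotypes, cohort.samples
            trait = cohort.trait
        else:
            records = read_prescriptions(config.prescriptions)
            genotypes = read_genotypes(config.genotypes)
            samples = read_samples(config.samples)
            trait = (
                samples.set_index("person_id")[config.trait_column]
                if config.trait_column and config.trait_column in samples.columns
                else None
            )
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc

    # ---- stage 2: phenotype ----------------------------------------------
    try:
        calls = call_cohort(records, config.pair)
    except Exception as exc:
        raise PipelineError("phenotype", str(exc)) from exc
    for direction, summ in calls.summary.items():
        if isinstance(summ, dict):
            for reason, n_excl in summ["n_excluded_by_reason"].items():
                logger.warning("%s: %d persons excluded (%s)", direction, n_excl, reason)

    pheno_tab = calls.calls.copy()
    write_table(pheno_tab, out / "phenotype.tsv", cfg_dict, seed)

    # ---- stage 3: association ---------------------------------------------
    sample_idx = samples.set_index("person_id")
    results: list[AssociationResult] = []
    sumstats_rows: list[dict] = []
    report: dict = {
        "version": __version__,
        "config_hash": config_hash(cfg_dict),
        "seed": seed,
        "cohort": calls.summary,
        "associations": {},
    }

    try:
        for direction in config.directions:
            sub = pheno_tab[
                (pheno_tab["direction"] == direction)
                & (pheno_tab["status"].isin([Status.CASE.value, Status.CONTROL.value]))
            ]
            if sub.empty:
                continue
            merged = sub.merge(
                genotypes, left_on="person_id", right_index=True, how="inner"
            ).merge(sample_idx, left_on="person_id", right_index=True, how="inner")
            merged["is_case"] = (merged["status"] == Status.CASE.value).astype(float)
            if "sex" in merged.columns:
                merged["female"] = (merged["sex"] == "F").astype(float)

            strata = [("all", merged)]
            if config.stratify_sex and "female" in merged.columns:
                strata += [
                    ("female", merged[merged["female"] == 1.0]),
                    ("male", merged[merged["female"] == 0.0]),
                ]
            dir_results: dict = {}
            for variant in genotypes.columns:
                per_variant: dict = {}
                for stratum, frame in strata:
                    res = _fit_stratum(frame, variant, stratum, direction, config)
                    if res is None:
                        continue
                    results.append(res)
                    per_variant[stratum] = res.to_dict()
                    sumstats_rows.append(_sumstats_row(res, frame, variant, direction))
                if {"female", "male"} <= set(per_variant):
                    rf = _res_from_dict(per_variant["female"])
                    rm = _res_from_dict(per_variant["male"])
                    if np.isfinite(rf.beta) and np.isfinite(rm.beta):
                        z, p = sex_difference_test(rf, rm)
                        per_variant["sex_difference"] = {"z": z, "p": p}
                if config.condition_on and config.condition_on in genotypes.columns \
                        and variant != config.condition_on:
                    per_variant["conditional"] = _conditional(
                        merged, variant, config.condition_on, config
                    )
                dir_results[variant] = per_variant
            report["associations"][direction] = dir_results
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("association", str(exc)) from exc

    # ---- stage 4: trait ----------------------------------------------------
    if trait is not None:
        try:
            report["trait"] = _trait_analyses(trait, genotypes, sample_idx, config)
        except Exception as exc:
            raise PipelineError("trait", str(exc)) from exc

    # ---- stage 5: thresholds & outputs -------------------------------------
    sumstats = pd.DataFrame(sumstats_rows, columns=SUMSTATS_COLUMNS + ["DIRECTION"])
    if len(sumstats):
        annotated = apply_threshold_scheme(
            sumstats.rename(columns={"P": "p"}), config.scheme
        ).rename(columns={"p": "P"})
        sumstats["THRESHOLD"] = annotated["threshold"]
        sumstats["SIGNIFICANT"] = annotated["significant"]
    _write_sumstats(sumstats, out / "sumstats.tsv", cfg_dict, seed, config.scheme)
    report["threshold_scheme"] = {
        "alpha": config.scheme.alpha,
        "class_weights": dict(config.scheme.class_weights),
    }
    report["forest"] = forest_table(results).to_dict(orient="records") if results else []
    with open(out / "report.json", "w") as fhj:
        json.dump(report, fhj, indent=2, sort_keys=True, default=_jsonify)
        fhj.write("\n")
    return report


def _fit_stratum(frame, variant, stratum, direction, config) -> AssociationResult | None:
    if frame.empty or frame["is_case"].nunique() < 2 or frame[variant].nunique() < 2:
        return None
    covs = [c for c in config.covariates if c in frame.columns]
    if stratum == "all" and "female" in frame.columns:
        covs = ["female"] + covs
    cov = frame[covs].astype(float) if covs else None
    return logistic_assoc(
        frame[variant].to_numpy(dtype=float),
        frame["is_case"].to_numpy(),
        covariates=cov,
        variant_id=str(variant),
        stratum=f"{stratum}",
    )


def _conditional(merged, variant, cond_variant, config) -> dict:
    covs = [c for c in config.covariates if c in merged.columns]
    if "female" in merged.columns:
        covs = ["female"] + covs
    res = conditional_assoc(
        merged[variant].to_numpy(dtype=float),
        merged[cond_variant].to_numpy(dtype=float),
        merged["is_case"].to_numpy(),
        covariates=merged[covs].astype(float) if covs else None,
        model="logistic",
        variant_id=str(variant),
        conditioned_on=str(cond_variant),
    )
    return res.to_dict()


def _trait_analyses(trait, genotypes, sample_idx, config) -> dict:
    t = pd.Series(trait).dropna()
    covariate_sheet = sample_idx.drop(columns=["trait"], errors="ignore")
    merged = genotypes.join(t.rename("trait"), how="inner").join(covariate_sheet, how="inner")
    merged = merged.dropna(subset=["trait"])
    if "sex" in merged.columns:
        merged["female"] = (merged["sex"] == "F").astype(float)
    covs = [c for c in ("female",) if c in merged.columns]
    out: dict = {}
    for variant in genotypes.columns:
        res = linear_assoc(
            merged[variant].to_numpy(dtype=float),
            merged["trait"].to_numpy(dtype=float),
            covariates=merged[covs].astype(float) if covs else None,
            transform=config.trait_transform,
            variant_id=str(variant),
        )
        out[variant] = res.to_dict()
    variants = list(genotypes.columns)
    if config.condition_on in variants:
        for variant in variants:
            if variant == config.condition_on:
                continue
            res = conditional_assoc(
                merged[variant].to_numpy(dtype=float),
                merged[config.condition_on].to_numpy(dtype=float),
                merged["trait"].to_numpy(dtype=float),
                covariates=merged[covs].astype(float) if covs else None,
                model="linear",
                transform=config.trait_transform,
                variant_id=str(variant),
                conditioned_on=str(config.condition_on),
            )
            out[f"{variant}|{config.condition_on}"] = res.to_dict()
    return out


def _sumstats_row(res: AssociationResult, frame, variant, direction) -> dict:
    dose = frame[variant].to_numpy(dtype=float)
    eaf, _ = eaf_and_hwe(dose[np.isfinite(dose)])
    or_ci = res.or_ci
    return {
        "CHR": "chrS",
        "POS": 0,
        "ID": str(variant),
        "EA": "G",
        "OA": "A",
        "EAF": eaf,
        "N": res.n,
        "BETA": res.beta,
        "SE": res.se,
        "P": res.p,
        "OR": res.odds_ratio if res.odds_ratio is not None else math.nan,
        "CI_L": or_ci[0] if or_ci else res.ci_low,
        "CI_U": or_ci[1] if or_ci else res.ci_high,
        "STRATUM": res.stratum,
        "MODEL": res.model,
        "DIRECTION": direction,
    }


def _write_sumstats(df, path, cfg_dict, seed, scheme) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(cfg_dict, seed))
        fh.write(
            f"# threshold_scheme: alpha={scheme.alpha} "
            f"weights={json.dumps(scheme.class_weights, sort_keys=True)}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _res_from_dict(d: dict) -> AssociationResult:
    return AssociationResult(
        variant_id=d["variant_id"], beta=d["beta"], se=d["se"], p=d["p"],
        model=d["model"], stratum=d["stratum"], n=d["n"],
    )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def forest_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Rows for a forest plot: stratum, direction-agnostic OR/effect and CI.

    Ordered by (variant, stratum); every row's CI brackets its estimate.
    Raises on empty input.
    """
    if not results:
        raise ValueError("no association results to tabulate")
    rows = []
    for r in results:
        est = r.odds_ratio if r.odds_ratio is not None else r.beta
        lo, hi = (r.or_ci if r.or_ci is not None else (r.ci_low, r.ci_high))
        rows.append(
            {
                "variant_id": r.variant_id,
                "stratum": r.stratum,
                "model": r.model,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "n": r.n,
                "p": r.p,
            }
        )
    return pd.DataFrame(rows).sort_values(["variant_id", "stratum"]).reset_index(drop=True)


def plot_forest(table: pd.DataFrame, path: str | Path) -> None:
    """Optional simple forest plot (matplotlib, if installed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table["estimate"], y,
        xerr=[table["estimate"] - table["ci_low"], table["ci_high"] - table["estimate"]],
        fmt="s", color="k", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(table["variant_id"] + " / " + table["stratum"])
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
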