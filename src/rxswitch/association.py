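"""Association statistics for the switching phenotype and taste traits.

The modelling surface follows the statsmodels convention: a model object is
built from data (:class:`LogisticAssociation`, :class:`LinearAssociation`),
its ``fit()`` returns an :class:`AssociationResult` carrying the per-allele
estimate, its Wald uncertainty and a ``summary()`` table.  Thin functional
wrappers (:func:`logistic_assoc`, :func:`linear_assoc`,
:func:`conditional_assoc`) cover the common one-shot uses.

All genetic effects are additive: the dose of the effect allele (0/1/2 hard
calls, or fractional dosages) enters the linear predictor directly.  Binary
outcomes are fitted by maximum-likelihood logistic regression; quantitative
traits by OLS, optionally after a rank-based inverse-normal transform so
effects are in SD units.  Sex-stratified effects are compared with the
standard two-sample heterogeneity z-test on the log odds ratios, and
conditional analysis re-tests a variant with another variant's dose as a
covariate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "AssociationResult",
    "LogisticAssociation",
    "LinearAssociation",
    "ThresholdScheme",
    "logistic_assoc",
    "linear_assoc",
    "conditional_assoc",
    "or_from_counts",
    "sex_difference_test",
    "sex_interaction_test",
    "rank_inverse_normal",
    "ld_r2",
    "eaf_and_hwe",
    "apply_threshold_scheme",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    """Per-variant effect estimate with Wald uncertainty.

    ``beta`` is the log odds ratio for logistic models and the effect in
    trait units (SD units when rank-normalized) for linear models.
    """

    variant_id: str
    beta: float
    se: float
    p: float
    model: str  # "logistic" | "linear" | "logistic-conditional" | ...
    stratum: str = "all"
    n: int = 0
    n_cases: int | None = None
    n_controls: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def ci_low(self) -> float:
        return self.beta - _Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + _Z95 * self.se

    @property
    def odds_ratio(self) -> float | None:
        return math.exp(self.beta) if self.model.startswith("logistic") else None

    @property
    def or_ci(self) -> tuple[float, float] | None:
        if not self.model.startswith("logistic"):
            return None
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def summary(self) -> str:
        lines = [
            f"Association: {self.variant_id}  [{self.model}, stratum={self.stratum}]",
            f"  n = {self.n}"
            + (
                f"  (cases {self.n_cases} / controls {self.n_controls})"
                if self.n_cases is not None
                else ""
            ),
            f"  beta = {self.beta:.4f}  SE = {self.se:.4f}  "
            f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}]  p = {self.p:.3g}",
        ]
        if self.odds_ratio is not None:
            lo, hi = self.or_ci
            lines.append(f"  OR = {self.odds_ratio:.4f}  95% CI [{lo:.4f}, {hi:.4f}]")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "variant_id": self.variant_id,
            "stratum": self.stratum,
            "model": self.model,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
        }
        if self.odds_ratio is not None:
            d["odds_ratio"] = self.odds_ratio
            d["or_ci_low"], d["or_ci_high"] = self.or_ci
        if self.n_cases is not None:
            d["n_cases"], d["n_controls"] = self.n_cases, self.n_controls
        if self.flags:
            d["flags"] = ";".join(self.flags)
        return d


def _design(dose: np.ndarray, covariates: pd.DataFrame | np.ndarray | None) -> pd.DataFrame:
    X = pd.DataFrame({"dose": dose})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov.columns = [str(c) for c in cov.columns]
        X = pd.concat([X, cov], axis=1)
    return sm.add_constant(X, has_constant="add")


class LogisticAssociation:
    """Additive-model logistic regression of a binary outcome on allele dose.

    Parameters
    ----------
    status : array-like of bool/int
        1 = case, 0 = control.
    dose : array-like
        Effect-allele dose in [0, 2] per person.
    covariates : DataFrame, optional
        Additional numeric covariates (e.g. sex indicator, year of birth).
    variant_id, stratum : str
        Labels carried through to the result.
    """

    def __init__(self, status, dose, covariates=None, variant_id="v", stratum="all"):
        status = np.asarray(status, dtype=float)
        dose = np.asarray(dose, dtype=float)
        if status.shape[0] != dose.shape[0]:
            raise ValueError("status and dose lengths differ")
        keep = np.isfinite(status) & np.isfinite(dose)
        if covariates is not None:
            cov = pd.DataFrame(covariates).reset_index(drop=True)
            keep &= np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
            covariates = cov.loc[keep].reset_index(drop=True)
        self.status = status[keep]
        self.dose = dose[keep]
        self.covariates = covariates
        self.variant_id = variant_id
        self.stratum = stratum
        self._n_dropped = int((~keep).sum())
        if self.status.min() == self.status.max():
            raise ValueError("need at least one case and one control")
        if np.ptp(self.dose) == 0:
            raise ValueError("dose has zero variance")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, status="status", dose="dose",
                       covariates=(), **kw) -> "LogisticAssociation":
        cov = df[list(covariates)] if covariates else None
        return cls(df[status], df[dose], covariates=cov, **kw)

    def fit(self) -> AssociationResult:
        X = _design(self.dose, self.covariates)
        flags = [] if self._n_dropped == 0 else [f"dropped_missing={self._n_dropped}"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.status, X).fit(disp=0, maxiter=200)
                beta = float(res.params["dose"])
                se = float(res.bse["dose"])
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception as exc:  # perfect separation raises in statsmodels
                return self._flagged_result(flags + [f"separation:{type(exc).__name__}"])
        if not converged or not np.isfinite(se) or se > 100:
            return self._flagged_result(flags + ["separation_or_nonconvergence"])
        p = 2 * stats.norm.sf(abs(beta / se))
        return AssociationResult(
            variant_id=self.variant_id,
            beta=beta,
            se=se,
            p=float(max(p, np.nextafter(0, 1))),
            model="logistic",
            stratum=self.stratum,
            n=self.status.shape[0],
            n_cases=int(self.status.sum()),
            n_controls=int((1 - self.status).sum()),
            flags=flags,
        )

    def _flagged_result(self, flags: list[str]) -> AssociationResult:
        return AssociationResult(
            variant_id=self.variant_id,
            beta=float("nan"),
            se=float("nan"),
            p=1.0,
            model="logistic",
            stratum=self.stratum,
            n=self.status.shape[0],
            n_cases=int(self.status.sum()),
            n_controls=int((1 - self.status).sum()),
            flags=flags,
        )


class LinearAssociation:
    """OLS of a quantitative trait on allele dose, optionally rank-normalized.

    With ``transform=True`` (default) the trait is replaced by Blom rank
    scores before fitting, so the dose effect is in SD units.
    """

    def __init__(self, trait, dose, covariates=None, transform=True,
                 variant_id="v", stratum="all"):
        trait = np.asarray(trait, dtype=float)
        dose = np.asarray(dose, dtype=float)
        if trait.shape[0] != dose.shape[0]:
            raise ValueError("trait and dose lengths differ")
        keep = np.isfinite(trait) & np.isfinite(dose)
        if covariates is not None:
            cov = pd.DataFrame(covariates).reset_index(drop=True)
            keep &= np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
            covariates = cov.loc[keep].reset_index(drop=True)
        self.trait = trait[keep]
        self.dose = dose[keep]
        self.covariates = covariates
        self.transform = transform
        self.variant_id = variant_id
        self.stratum = stratum
        k = 0 if covariates is None else covariates.shape[1]
        if self.trait.shape[0] <= k + 2:
            raise ValueError("n must exceed number of covariates + 2")
        if np.ptp(self.dose) == 0:
            raise ValueError("dose has zero variance")

    def fit(self) -> AssociationResult:
        y = rank_inverse_normal(self.trait) if self.transform else self.trait
        X = _design(self.dose, self.covariates)
        res = sm.OLS(y, X).fit()
        beta = float(res.params["dose"])
        se = float(res.bse["dose"])
        p = 2 * stats.norm.sf(abs(beta / se))
        return AssociationResult(
            variant_id=self.variant_id,
            beta=beta,
            se=se,
            p=float(max(p, np.nextafter(0, 1))),
            model="linear",
            stratum=self.stratum,
            n=self.trait.shape[0],
        )


def logistic_assoc(dose, status, covariates=None, *, variant_id="v", stratum="all") -> AssociationResult:
    """Additive-model logistic association (one-shot wrapper)."""
    return LogisticAssociation(
        status, dose, covariates=covariates, variant_id=variant_id, stratum=stratum
    ).fit()


def linear_assoc(dose, trait, covariates=None, *, transform=True,
                 variant_id="v", stratum="all") -> AssociationResult:
    """Quantitative-trait association, rank-normalized by default."""
    return LinearAssociation(
        trait, dose, covariates=covariates, transform=transform,
        variant_id=variant_id, stratum=stratum,
    ).fit()


def conditional_assoc(
    target_dose,
    conditioning_dose,
    outcome,
    covariates=None,
    *,
    model: str = "logistic",
    transform: bool = True,
    variant_id: str = "v",
    conditioned_on: str = "cond",
    stratum: str = "all",
) -> AssociationResult:
    """Re-test a variant with one or more other variants' doses as covariates.

    Refuses collinear conditioning (r² = 1 between target and any
    conditioning dose, or a rank-deficient joint dose matrix) with an error
    naming the culprit — two perfectly correlated variants carry no
    information to separate their signals.
    """
    target = np.asarray(target_dose, dtype=float)
    cond = np.atleast_2d(np.asarray(conditioning_dose, dtype=float))
    if cond.shape[0] == target.shape[0] and cond.shape[1] != target.shape[0]:
        cond = cond.T
    names = (
        [conditioned_on]
        if cond.shape[0] == 1
        else [f"{conditioned_on}{k}" for k in range(cond.shape[0])]
    )
    for name, c in zip(names, cond):
        if np.ptp(c) == 0:
            raise ValueError(f"conditioning dose {name} is constant")
        if abs(np.corrcoef(target, c)[0, 1]) > 1 - 1e-10:
            raise ValueError(
                f"collinearity: target {variant_id} and conditioning variant {name} "
                f"have r^2 = 1; their signals cannot be separated"
            )
    joint = np.column_stack([target, *cond])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(target)), joint])) < joint.shape[1] + 1:
        raise ValueError("collinearity: joint dose matrix is rank deficient")
    cov = pd.DataFrame(cond.T, columns=names)
    if covariates is not None:
        extra = pd.DataFrame(covariates).reset_index(drop=True)
        cov = pd.concat([cov, extra], axis=1)
    if model == "logistic":
        res = logistic_assoc(target, outcome, covariates=cov, variant_id=variant_id, stratum=stratum)
    elif model == "linear":
        res = linear_assoc(
            target, outcome, covariates=cov, transform=transform,
            variant_id=variant_id, stratum=stratum,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    res.model += "-conditional"
    res.flags.append(f"conditioned_on={','.join(names)}")
    return res


def or_from_counts(a: float, b: float, c: float, d: float, *, variant_id="2x2") -> AssociationResult:
    """Odds ratio from a 2x2 table with Woolf (log-scale) confidence interval.

    Layout::

        exposed cases      a   |  b   unexposed cases
        exposed controls   c   |  d   unexposed controls

    OR = ad/bc, SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d).  Zero cells get
    the Haldane–Anscombe 0.5 continuity correction (flagged).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("2x2 counts must be non-negative")
    flags = []
    if any(x == 0 for x in cells):
        cells = [x + 0.5 for x in cells]
        flags.append("haldane_anscombe_0.5")
    a, b, c, d = cells
    beta = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(abs(beta / se))
    return AssociationResult(
        variant_id=variant_id,
        beta=beta,
        se=se,
        p=float(p),
        model="logistic-2x2",
        stratum="all",
        n=int(round(a + b + c + d)),
        n_cases=int(round(a + b)),
        n_controls=int(round(c + d)),
        flags=flags,
    )


def sex_difference_test(
    result_female: AssociationResult, result_male: AssociationResult
) -> tuple[float, float]:
    """Heterogeneity z-test comparing two independent-stratum effects.

    z = (beta_f - beta_m) / sqrt(se_f^2 + se_m^2); two-sided normal p.
    The strata must be disjoint samples (the test assumes independence).
    """
    if result_female.stratum == result_male.stratum:
        raise ValueError(
            "strata are not disjoint: both results are labelled "
            f"{result_female.stratum!r}; the z-test requires independent strata"
        )
    z = (result_female.beta - result_male.beta) / math.hypot(result_female.se, result_male.se)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def sex_interaction_test(dose, status, female, covariates=None) -> tuple[float, float]:
    """Genotype-by-sex interaction Wald test (alternative to the stratified z)."""
    dose = np.asarray(dose, dtype=float)
    female = np.asarray(female, dtype=float)
    inter = pd.DataFrame({"female": female, "dose_x_female": dose * female})
    if covariates is not None:
        inter = pd.concat([inter, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    X = _design(dose, inter)
    res = sm.Logit(np.asarray(status, dtype=float), X).fit(disp=0, maxiter=200)
    z = float(res.params["dose_x_female"] / res.bse["dose_x_female"])
    return z, float(2 * stats.norm.sf(abs(z)))


def rank_inverse_normal(values, offset: float = 0.375) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    Maps value with (average, for ties) rank r among n to
    Phi^-1((r - offset) / (n - 2*offset + 1)); the default offset 0.375
    gives the Blom scores Phi^-1((r - 3/8)/(n + 1/4)).  The output is
    invariant to strictly monotone transforms of the input and has mean
    ~0, SD ~1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d array")
    if np.unique(x).size < 2:
        raise ValueError("rank_inverse_normal needs >= 2 distinct values")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.shape[0] - 2 * offset + 1))


def ld_r2(dose1, dose2) -> float:
    """Composite LD: squared Pearson correlation of genotype doses."""
    d1 = np.asarray(dose1, dtype=float)
    d2 = np.asarray(dose2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dose vectors must cover the same persons")
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        raise ValueError("LD undefined for a constant dose vector")
    return float(np.corrcoef(d1, d2)[0, 1] ** 2)


def eaf_and_hwe(dose) -> tuple[float, float | None]:
    """Effect-allele frequency and Hardy–Weinberg exact mid-p.

    EAF = mean(dose)/2 for hard calls or dosages.  The HWE exact test
    (conditional distribution of the heterozygote count given the allele
    count) requires hard calls; for fractional dosages only the EAF is
    returned (HWE p is None).
    """
    d = np.asarray(dose, dtype=float)
    if d.size == 0:
        raise ValueError("empty dose vector")
    if np.isnan(d).any():
        raise ValueError("missing doses; drop them before QC")
    eaf = float(d.mean() / 2.0)
    hard = np.allclose(d, np.round(d))
    if not hard:
        return eaf, None
    g = np.round(d).astype(int)
    n_het = int((g == 1).sum())
    n_hom_alt = int((g == 2).sum())
    n = g.shape[0]
    return eaf, hwe_exact_midp(n_het, n_hom_alt, n - n_het - n_hom_alt)


def hwe_exact_midp(n_het: int, n_hom_alt: int, n_hom_ref: int) -> float:
    """Exact HWE test mid-p via the conditional heterozygote distribution.

    Enumerates P(het = h | n, rare-allele count) over all feasible h and
    sums the probabilities of outcomes as or less probable than the
    observed one, counting the observed outcome at half weight (mid-p).
    """
    n = n_het + n_hom_alt + n_hom_ref
    if n == 0:
        raise ValueError("no genotypes")
    rare = min(2 * n_hom_alt + n_het, 2 * n_hom_ref + n_het)
    h_values = np.arange(rare % 2, rare + 1, 2)
    # log P(h) up to a constant: conditional distribution of het count
    logp = (
        h_values * math.log(2)
        - gammaln((rare - h_values) / 2 + 1)
        - gammaln(h_values + 1)
        - gammaln(n - (rare + h_values) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[h_values == n_het][0]
    less = probs[probs < p_obs - 1e-12].sum()
    equal = probs[np.abs(probs - p_obs) <= 1e-12].sum()
    return float(min(1.0, less + 0.5 * equal))


@dataclass
class ThresholdScheme:
    """Class-weighted Bonferroni significance thresholds.

    Each variant belongs to an annotation class with prior weight w_c; the
    per-class threshold is 0.05 * w_c / sum_v w_class(v), so the total alpha
    budget sum_v threshold(v) equals ``alpha`` exactly.
    """

    class_weights: dict[str, float]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.class_weights:
            raise ValueError("at least one class required")
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")

    @classmethod
    def single_class(cls, alpha: float = 0.05) -> "ThresholdScheme":
        """Plain Bonferroni: one class, weight 1 (threshold alpha/M)."""
        return cls({"all": 1.0}, alpha=alpha)

    def thresholds(self, variant_classes: pd.Series | dict) -> pd.Series:
        """Per-variant thresholds given each variant's class label."""
        classes = pd.Series(variant_classes)
        unknown = set(classes) - set(self.class_weights)
        if unknown:
            raise ValueError(f"variants with unweighted classes: {sorted(unknown)}")
        weights = classes.map(self.class_weights)
        return self.alpha * weights / weights.sum()


def apply_threshold_scheme(
    results: pd.DataFrame,
    scheme: ThresholdScheme,
    class_column: str = "variant_class",
) -> pd.DataFrame:
    """Annotate a results table with per-variant thresholds and significance.

    A variant is significant iff its p-value is strictly below its class
    threshold.  The input needs columns ``p`` and (unless every variant is
    in one implicit class) ``variant_class``.
    """
    out = results.copy()
    if class_column not in out.columns:
        if set(scheme.class_weights) != {"all"}:
            raise ValueError(f"results lack a {class_column!r} column")
        out[class_column] = "all"
    out["threshold"] = scheme.thresholds(out[class_column]).to_numpy()
    out["significant"] = out["p"].to_numpy() < out["threshold"].to_numpy()
    out.attrs["threshold_scheme"] = {
        "alpha": scheme.alpha,
        "class_weights": dict(scheme.class_weights),
    }
    return out
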