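"""Drug-switching phenotype derivation from longitudinal prescription records.

A person is a *switcher* from drug A to drug B when their first recorded
study-drug fill is drug A and, counting the fills strictly after their first
drug-B fill, at least ``tail_threshold`` (default 50%) of those fills are for
drug B.  Controls started on drug A but either never filled drug B or filled
it for less than the threshold fraction of the post-first-B fills.  Persons
with fewer than ``min_fills`` study-drug fills in total, persons whose first
fill is not drug A, and persons whose earliest fill date carries both drugs
(first drug undefined) are excluded from that direction.

The definition is symmetric: the B->A direction is obtained by swapping the
drug roles, and a person's first drug decides which direction applies to them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ZOPICLONE_ATC = "N05CF01"
ZOLPIDEM_ATC = "N05CF02"

__all__ = [
    "ZOPICLONE_ATC",
    "ZOLPIDEM_ATC",
    "DrugPair",
    "Direction",
    "Status",
    "PhenotypeCall",
    "filter_to_pair",
    "call_switch",
    "call_cohort",
    "CohortCalls",
]


class Direction(str, enum.Enum):
    """Switch direction: origin drug -> destination drug."""

    A_TO_B = "A->B"
    B_TO_A = "B->A"


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class DrugPair:
    """The two study drugs and the eligibility/calling thresholds.

    Parameters
    ----------
    drug_a_atc, drug_b_atc
        ATC codes of the two drugs (defaults: zopiclone N05CF01 and
        zolpidem N05CF02).
    min_fills
        Minimum number of study-drug fills (both drugs combined) for a
        person to enter the analysis.  With ``per_drug=True`` the floor
        applies to either drug separately instead.
    tail_threshold
        Minimum fraction of drug-B fills among the fills after the first
        drug-B fill for a case call.  "At least" semantics: a fraction
        exactly equal to the threshold is a case.
    tail_includes_first_b
        When True the first drug-B fill itself is counted in both the
        numerator and denominator of the tail fraction (alternative
        reading of "subsequent prescriptions").
    """

    drug_a_atc: str = ZOPICLONE_ATC
    drug_b_atc: str = ZOLPIDEM_ATC
    min_fills: int = 3
    tail_threshold: float = 0.5
    per_drug: bool = False
    tail_includes_first_b: bool = False

    def __post_init__(self) -> None:
        if self.drug_a_atc == self.drug_b_atc:
            raise ValueError("drug_a_atc and drug_b_atc must differ")
        if not (0.0 < self.tail_threshold <= 1.0):
            raise ValueError("tail_threshold must be in (0, 1]")
        if self.min_fills < 1:
            raise ValueError("min_fills must be >= 1")

    def swapped(self) -> "DrugPair":
        """The same pair with the drug roles exchanged (for B->A calling)."""
        return replace(self, drug_a_atc=self.drug_b_atc, drug_b_atc=self.drug_a_atc)


@dataclass
class PhenotypeCall:
    """One person's call for one switch direction, with audit fields."""

    person_id: str
    direction: Direction
    status: Status
    first_drug: str | None
    n_fills_total: int
    n_fills_tail: int
    frac_b_tail: float | None
    exclusion_reason: str = ""


class BadRecordError(ValueError):
    """A prescription record that cannot be interpreted (with its position)."""


def _validate_records(records: pd.DataFrame, skip_bad_records: bool) -> pd.DataFrame:
    req = {"person_id", "date", "atc_code"}
    missing = req - set(records.columns)
    if missing:
        raise BadRecordError(f"prescription table lacks columns: {sorted(missing)}")
    df = records.copy()
    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    pid = df["person_id"].astype(str)
    bad = dates.isna() | (pid.str.len() == 0) | df["person_id"].isna()
    if bad.any():
        first = int(np.flatnonzero(bad.to_numpy())[0])
        if not skip_bad_records:
            raise BadRecordError(
                f"unparseable date or empty person_id at input row {first} "
                f"(0-based, after header); rerun with skip_bad_records=True to drop"
            )
        df = df.loc[~bad]
        dates = dates.loc[~bad]
    df = df.assign(date=dates, person_id=df["person_id"].astype(str))
    return df


def filter_to_pair(
    records: pd.DataFrame,
    pair: DrugPair,
    *,
    skip_bad_records: bool = False,
) -> pd.DataFrame:
    """Restrict records to the study pair and order fills within person.

    Returns a frame with columns ``person_id``, ``date``, ``atc_code``,
    ``is_b`` (fill is the destination drug) sorted by
    (person_id, date, atc_code), plus a boolean ``ambiguous_first`` column
    (constant per person) flagging persons whose earliest fill date carries
    both drugs, so their first drug is undefined.
    """
    df = _validate_records(records, skip_bad_records)
    df = df[df["atc_code"].isin([pair.drug_a_atc, pair.drug_b_atc])]
    df = df.sort_values(["person_id", "date", "atc_code"], kind="stable").reset_index(drop=True)
    if df.empty:
        return df.assign(is_b=pd.Series(dtype=bool), ambiguous_first=pd.Series(dtype=bool))
    df["is_b"] = df["atc_code"] == pair.drug_b_atc
    grp = df.groupby("person_id", sort=False)
    first_date = grp["date"].transform("min")
    on_first = df["date"] == first_date
    drugs_on_first = (
        df[on_first].groupby("person_id", sort=False)["atc_code"].nunique().rename("n_first_drugs")
    )
    df = df.merge(drugs_on_first, on="person_id", how="left")
    df["ambiguous_first"] = df["n_first_drugs"] > 1
    return df.drop(columns="n_first_drugs")


def call_switch(
    sequence,
    pair: DrugPair,
    direction: Direction = Direction.A_TO_B,
    *,
    person_id: str = "",
    ambiguous_first: bool = False,
) -> PhenotypeCall:
    """Call one person's switch status from their ordered fill sequence.

    ``sequence`` is an ordered iterable over the study-pair fills, each
    element an ATC code (or the letters "A"/"B" mapped onto the pair's
    drugs).  For direction B->A the drug roles are swapped internally.
    """
    if direction == Direction.B_TO_A:
        pair_eff = pair.swapped()
    else:
        pair_eff = pair
    # the letters A/B always denote the pair's original drugs
    seq = [_as_code(x, pair) for x in sequence]
    is_b = [s == pair_eff.drug_b_atc for s in seq]
    n_total = len(seq)
    n_a = n_total - sum(is_b)
    n_b = sum(is_b)

    def excl(reason: str) -> PhenotypeCall:
        return PhenotypeCall(
            person_id=person_id,
            direction=direction,
            status=Status.EXCLUDED,
            first_drug=seq[0] if seq else None,
            n_fills_total=n_total,
            n_fills_tail=0,
            frac_b_tail=None,
            exclusion_reason=reason,
        )

    eligible = (
        max(n_a, n_b) >= pair_eff.min_fills if pair_eff.per_drug else n_total >= pair_eff.min_fills
    )
    if not eligible:
        return excl("min_fills")
    if seq[0] != pair_eff.drug_a_atc:
        return excl("first_drug")
    if ambiguous_first:
        return excl("ambiguous_first")

    if True not in is_b:  # never tried the destination drug
        return PhenotypeCall(
            person_id, direction, Status.CONTROL, seq[0], n_total, 0, None, ""
        )
    first_b = is_b.index(True)
    if pair_eff.tail_includes_first_b:
        tail = is_b[first_b:]
    else:
        tail = is_b[first_b + 1 :]
    if not tail:
        return PhenotypeCall(
            person_id, direction, Status.CONTROL, seq[0], n_total, 0, None, "empty_tail"
        )
    frac = sum(tail) / len(tail)
    status = Status.CASE if frac >= pair_eff.tail_threshold else Status.CONTROL
    return PhenotypeCall(person_id, direction, status, seq[0], n_total, len(tail), frac, "")


def _as_code(x, pair: DrugPair) -> str:
    if x == "A":
        return pair.drug_a_atc
    if x == "B":
        return pair.drug_b_atc
    return x


@dataclass
class CohortCalls:
    """Phenotype calls for a cohort plus the audit summary."""

    calls: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.calls


def call_cohort(records: pd.DataFrame, pair: DrugPair, *, skip_bad_records: bool = False) -> CohortCalls:
    """Call the switch phenotype for every person, both directions.

    Each person contributes at most one case/control row — the direction
    whose origin drug matches their first fill; the opposite direction
    records them as excluded with reason ``first_drug``.  The summary
    reports, per direction, starters (persons whose first fill is the
    origin drug and who meet the fill floor), cases, controls, exclusion
    counts by reason, and the switch percentage ``cases / starters``.  A
    second denominator that additionally drops ambiguous-first persons is
    reported alongside because registries differ on that point.
    """
    fills = filter_to_pair(records, pair, skip_bad_records=skip_bad_records)
    frames = []
    for direction in (Direction.A_TO_B, Direction.B_TO_A):
        frames.append(_call_direction_vectorized(fills, pair, direction))
    calls = pd.concat(frames, ignore_index=True)

    summary: dict = {"n_persons": int(fills["person_id"].nunique()) if len(fills) else 0}
    for direction in (Direction.A_TO_B, Direction.B_TO_A):
        sub = calls[calls["direction"] == direction.value]
        n_cases = int((sub["status"] == Status.CASE.value).sum())
        n_controls = int((sub["status"] == Status.CONTROL.value).sum())
        reasons = (
            sub.loc[sub["status"] == Status.EXCLUDED.value, "exclusion_reason"]
            .value_counts()
            .to_dict()
        )
        n_starters = n_cases + n_controls
        summary[direction.value] = {
            "n_starters": n_starters,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "n_excluded_by_reason": {str(k): int(v) for k, v in reasons.items()},
            "switch_pct": (100.0 * n_cases / n_starters) if n_starters else float("nan"),
        }
    return CohortCalls(calls=calls, summary=summary)


def _call_direction_vectorized(
    fills: pd.DataFrame, pair: DrugPair, direction: Direction
) -> pd.DataFrame:
    """Vectorized per-direction calling; agrees with :func:`call_switch`."""
    pair_eff = pair.swapped() if direction == Direction.B_TO_A else pair
    if fills.empty:
        return pd.DataFrame(
            columns=[
                "person_id",
                "direction",
                "status",
                "first_drug",
                "n_fills_total",
                "n_fills_tail",
                "frac_b_tail",
                "exclusion_reason",
            ]
        )
    work = fills.assign(_is_b=(fills["atc_code"] == pair_eff.drug_b_atc))
    pos = work.groupby("person_id", sort=True).cumcount().to_numpy()
    work["_first_b_pos"] = np.where(work["_is_b"].to_numpy(), pos, np.iinfo(np.int64).max)
    grp = work.groupby("person_id", sort=True)

    agg = grp.agg(
        n_total=("atc_code", "size"),
        n_b=("_is_b", "sum"),
        first_drug=("atc_code", "first"),
        ambiguous=("ambiguous_first", "first"),
        first_b_pos=("_first_b_pos", "min"),
    )

    n_total = agg["n_total"].to_numpy()
    n_b = agg["n_b"].to_numpy()
    n_a = n_total - n_b
    has_b = agg["first_b_pos"].to_numpy() < np.iinfo(np.int64).max
    first_b_pos = np.where(has_b, agg["first_b_pos"].to_numpy(), 0)

    if pair_eff.tail_includes_first_b:
        tail_len = n_total - first_b_pos
        tail_b = n_b
    else:
        tail_len = n_total - first_b_pos - 1
        tail_b = n_b - 1
    tail_len = np.where(has_b, tail_len, 0)
    tail_b = np.where(has_b, tail_b, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(tail_len > 0, tail_b / np.maximum(tail_len, 1), np.nan)

    eligible = (
        np.maximum(n_a, n_b) >= pair_eff.min_fills
        if pair_eff.per_drug
        else n_total >= pair_eff.min_fills
    )
    first_is_a = agg["first_drug"].to_numpy() == pair_eff.drug_a_atc
    ambiguous = agg["ambiguous"].to_numpy().astype(bool)

    status = np.full(len(agg), Status.CONTROL.value, dtype=object)
    reason = np.full(len(agg), "", dtype=object)
    is_case = has_b & (tail_len > 0) & (frac >= pair_eff.tail_threshold)
    status[is_case] = Status.CASE.value
    reason[has_b & (tail_len == 0)] = "empty_tail"
    # exclusion checks in precedence order: min_fills, first_drug, ambiguous
    excl_amb = ambiguous & eligible & first_is_a
    excl_first = (~first_is_a) & eligible
    excl_min = ~eligible
    for mask, why in ((excl_amb, "ambiguous_first"), (excl_first, "first_drug"), (excl_min, "min_fills")):
        status[mask] = Status.EXCLUDED.value
        reason[mask] = why
    excluded = status == Status.EXCLUDED.value
    frac_out = np.where(~excluded & has_b & (tail_len > 0), frac, np.nan)
    tail_out = np.where(~excluded, tail_len, 0)

    return pd.DataFrame(
        {
            "person_id": agg.index.astype(str),
            "direction": direction.value,
            "status": status,
            "first_drug": agg["first_drug"].to_numpy(),
            "n_fills_total": n_total,
            "n_fills_tail": tail_out.astype(int),
            "frac_b_tail": frac_out,
            "exclusion_reason": reason,
        }
    )
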