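"""Shared fixtures and the independent brute-force switch-rule oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rxswitch as rx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def brute_force_call(seq, min_fills=3, threshold=0.5):
    """Literal transcription of the switch rule, independent of the package.

    ``seq`` is a string over {"A", "B"} in fill order.  Returns
    (status, reason):  a person is a case if their first fill is A and,
    among the fills strictly after their first B fill, at least
    ``threshold`` are B; a control if they start on A and never reach that
    fraction (including never trying B); excluded otherwise.
    """
    if len(seq) < min_fills:
        return ("excluded", "min_fills")
    if seq[0] != "A":
        return ("excluded", "first_drug")
    if "B" not in seq:
        return ("control", "")
    tail = seq[seq.index("B") + 1 :]
    if not tail:
        return ("control", "empty_tail")
    frac = tail.count("B") / len(tail)
    return ("case" if frac >= threshold else "control", "")


def all_sequences(max_len):
    """Every fill sequence over {A,B} of length 1..max_len."""
    for length in range(1, max_len + 1):
        for combo in itertools.product("AB", repeat=length):
            yield "".join(combo)


@pytest.fixture(scope="session")
def pair():
    return rx.DrugPair()


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-person simulated cohort shared by read-only tests."""
    cfg = rx.SimConfig(n_individuals=3000, seed=42, eaf2=0.446, target_r2=0.93, beta_sd=-0.25)
    return rx.simulate_switch_cohort(cfg)


def records_from_sequences(seqs, pair, start="2010-01-01"):
    """Build a prescriptions frame from {person_id: 'ABBA...'} strings."""
    rows = []
    origin = pd.Timestamp(start)
    for pid, seq in seqs.items():
        for i, ch in enumerate(seq):
            atc = pair.drug_a_atc if ch == "A" else pair.drug_b_atc
            rows.append((pid, (origin + pd.Timedelta(days=30 * i)).strftime("%Y-%m-%d"), atc))
    return pd.DataFrame(rows, columns=["person_id", "date", "atc_code"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
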