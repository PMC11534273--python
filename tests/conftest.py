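import numpy as np
import pandas as pd
import pytest

from ctfmeta import (
    Item,
    ItemBank,
    SimulationConfig,
    build_paired_cohort,
    select_first_posttest,
    simulate_cohort,
)
from ctfmeta.studydata import load_study_bank


@pytest.fixture(scope="session")
def study_bank() -> ItemBank:
    return load_study_bank()


@pytest.fixture(scope="session")
def tiny_bank() -> ItemBank:
    """Four items, two keyed each way, one concept group."""
    return ItemBank(
        items=(
            Item("a1", "statement one", False, "grp"),
            Item("a2", "statement two", True),
            Item("a3", "statement three", False, "grp"),
            Item("a4", "statement four", True),
        )
    )


def make_records(rows) -> pd.DataFrame:
    """Build a response table from (pid, phase, time, item, choice) tuples."""
    return pd.DataFrame(
        rows, columns=["participant_id", "phase", "attempt_time", "item_id", "choice"]
    )


def full_phase(pid, phase, time, bank, choice_fn) -> list[tuple]:
    """One complete phase for one participant; choice_fn(item) -> choice."""
    return [(pid, phase, time, it.item_id, choice_fn(it)) for it in bank]


def correct_choice(item, confident=True):
    if item.answer_key:
        return "sure_true" if confident else "unsure_true"
    return "sure_false" if confident else "unsure_false"


def incorrect_choice(item, confident=True):
    if item.answer_key:
        return "sure_false" if confident else "unsure_false"
    return "sure_true" if confident else "unsure_true"


@pytest.fixture(scope="session")
def improvement_sim():
    """Simulated cohort with a real knowledge and confidence gain (defaults)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def improvement_cohort(improvement_sim):
    cohort = build_paired_cohort(
        select_first_posttest(improvement_sim.responses), improvement_sim.bank
    )
    return improvement_sim.bank, cohort
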