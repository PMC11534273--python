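"""Published reference inputs from the naloxone-coprescription CTF study.

The study's participant-level responses were never deposited, but its
report prints everything needed to exercise the desk-scale computations:
the 20-item bank with answer keys, the per-item CTF category percentages
at both phases (N=307 completers), the per-item McNemar statistics, and
the cohort-level Wilcoxon z statistics for each of the seven summary
measures.  Those printed values are transcribed as plain-text package
data and exposed here as inputs — the package recomputes everything
derivable from them (effect sizes, change columns, p-values) rather than
carrying the derived numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_cohort import ItemBank, load_item_bank
from .item_analysis import confident_incorrect_category, confident_incorrect_change

#: Completers analyzed in the published cohort.
STUDY_N = 307

#: Published Wilcoxon z per summary measure (negative = posttest higher).
STUDY_Z = {
    "ctf_sum": -9.41,
    "binary_pct": -9.41,
    "ac": -9.42,
    "bs": -13.08,
    "ccp": -13.59,
    "cip": -12.82,
    "dis": 2.85,
}

#: Concept group tag for the overdose-risk-index items (q7, q12, q15).
RIOSORD_GROUP = "riosord"


def _data(name: str):
    return resources.files("ctfmeta.data").joinpath(name)


def load_study_bank() -> ItemBank:
    """The 20-statement naloxone-coprescription item bank (13 keyed False)."""
    with resources.as_file(_data("naloxone_bank.json")) as path:
        return load_item_bank(path)


def load_item_frequencies() -> pd.DataFrame:
    """Published per-item CTF category percentages, long by (item, phase)."""
    with resources.as_file(_data("item_frequencies.csv")) as path:
        df = pd.read_csv(path)
    return df.set_index(["item_id", "phase"])


def load_item_tests() -> pd.DataFrame:
    """Published per-item McNemar statistics, p strings, and change column."""
    with resources.as_file(_data("item_tests.csv")) as path:
        df = pd.read_csv(path, dtype={"mcnemar_p": str})
    return df.set_index("item_id")


def table_confident_incorrect_changes(
    frequencies: pd.DataFrame | None = None, bank: ItemBank | None = None
) -> pd.Series:
    """Confident-incorrect percent change per item, recomputed from the
    published category percentages (NaN where the pretest cell is zero)."""
    freq = load_item_frequencies() if frequencies is None else frequencies
    bank = load_study_bank() if bank is None else bank
    out = {}
    for item in bank:
        cat = confident_incorrect_category(item.answer_key)
        pre = float(freq.loc[(item.item_id, "pre"), cat])
        post = float(freq.loc[(item.item_id, "post"), cat])
        out[item.item_id] = confident_incorrect_change(pre, post)
    return pd.Series(out, name="conf_incorrect_change")
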