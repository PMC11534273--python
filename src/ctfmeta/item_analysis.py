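"""Item-level CTF distributions, binary aggregation, and change metrics.

For each item the four CTF categories are tabulated as percentages of the
paired cohort (same denominator at both phases), listed worst-to-best
relative to the answer key: a false-keyed item runs sure_true,
unsure_true, unsure_false, sure_false; a true-keyed item the reverse.
Binary True/False percentages are the confidence-collapsed margins
(True = sure_true + unsure_true).

The confident-incorrect change metric tracks the category most indicative
of miscalibration — the "I am confident" choice in the wrong direction —
as the relative percent change from pre to post:
100·(post − pre)/pre, undefined when the pretest percentage is zero.
It is scale-invariant: proportions and percentages give the same value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import McNemarResult, mcnemar
from .io_cohort import CHOICES, PHASES, ItemBank, PairedCohort
from .scoring import matrix_flags

#: Category order from confident-incorrect to confident-correct, per key.
ORDER_FALSE_KEYED = ("sure_true", "unsure_true", "unsure_false", "sure_false")
ORDER_TRUE_KEYED = ("sure_false", "unsure_false", "unsure_true", "sure_true")


def category_order(answer_key: bool) -> tuple[str, ...]:
    return ORDER_TRUE_KEYED if answer_key else ORDER_FALSE_KEYED


def confident_incorrect_category(answer_key: bool) -> str:
    """The 'Sure' choice in the wrong direction for this key."""
    return "sure_false" if answer_key else "sure_true"


@dataclass(frozen=True)
class ItemDistribution:
    """Percent of the paired cohort in each CTF category for one item-phase."""

    item_id: str
    phase: str
    pct: dict[str, float]  # category -> percent, full precision
    ordering: tuple[str, ...]  # worst-to-best given the answer key

    @property
    def true_pct(self) -> float:
        return self.pct["sure_true"] + self.pct["unsure_true"]

    @property
    def false_pct(self) -> float:
        return self.pct["sure_false"] + self.pct["unsure_false"]


@dataclass(frozen=True)
class ItemChangeReport:
    """Everything reported per item: both distributions, binary margins,
    the McNemar test on binary correctness, and the confident-incorrect
    change (NaN when undefined)."""

    item_id: str
    concept_group: str | None
    pre: ItemDistribution
    post: ItemDistribution
    mcnemar: McNemarResult
    confident_incorrect_change: float


def ctf_distribution(
    cohort: PairedCohort, bank: ItemBank, item_id: str, phase: str
) -> ItemDistribution:
    """CTF category percentages for one item at one phase."""
    keys = bank.answer_keys
    if item_id not in keys:
        raise KeyError(f"unknown item {item_id!r}")
    col = cohort.phase_matrix(phase)[item_id]
    counts = col.value_counts().reindex(list(CHOICES), fill_value=0)
    pct = (100.0 * counts / cohort.n).to_dict()
    return ItemDistribution(
        item_id=item_id, phase=phase, pct=pct, ordering=category_order(keys[item_id])
    )


def confident_incorrect_change(pre_pct: float, post_pct: float) -> float:
    """Relative percent change of the confident-incorrect category.

    Returns NaN when ``pre_pct`` is zero (relative change undefined).
    """
    if pre_pct < 0 or post_pct < 0:
        raise ValueError("percentages must be non-negative")
    if pre_pct == 0:
        return math.nan
    return 100.0 * (post_pct - pre_pct) / pre_pct


def item_report(cohort: PairedCohort, bank: ItemBank) -> list[ItemChangeReport]:
    """One :class:`ItemChangeReport` per bank item, in bank order."""
    correct = {
        phase: matrix_flags(cohort.phase_matrix(phase), bank)[1] for phase in PHASES
    }
    reports = []
    for j, item in enumerate(bank):
        pre = ctf_distribution(cohort, bank, item.item_id, "pre")
        post = ctf_distribution(cohort, bank, item.item_id, "post")
        ci_cat = confident_incorrect_category(item.answer_key)
        reports.append(
            ItemChangeReport(
                item_id=item.item_id,
                concept_group=item.concept_group,
                pre=pre,
                post=post,
                mcnemar=mcnemar(correct["pre"][:, j], correct["post"][:, j]),
                confident_incorrect_change=confident_incorrect_change(
                    pre.pct[ci_cat], post.pct[ci_cat]
                ),
            )
        )
    return reports


def concept_group_change(
    reports: list[ItemChangeReport], group: str
) -> dict[str, float]:
    """Min and max defined confident-incorrect changes within a concept group."""
    members = [r for r in reports if r.concept_group == group]
    if not members:
        raise ValueError(f"no items in concept group {group!r}")
    changes = [
        r.confident_incorrect_change
        for r in members
        if not math.isnan(r.confident_incorrect_change)
    ]
    if not changes:
        raise ValueError(f"concept group {group!r} has no defined changes")
    return {"min_change": min(changes), "max_change": max(changes)}


def items_frame(reports: list[ItemChangeReport], round_output: bool = True) -> pd.DataFrame:
    """Flatten reports to the items table: one row per item-phase.

    With ``round_output`` the category and binary percentages are rounded
    to integers and the change column to the nearest integer; the McNemar
    statistic keeps 2 decimals and p 3.
    """
    rows = []
    for r in reports:
        for dist in (r.pre, r.post):
            row = {"item_id": r.item_id, "phase": dist.phase}
            row.update({c: dist.pct[c] for c in CHOICES})
            row["true_pct"] = dist.true_pct
            row["false_pct"] = dist.false_pct
            row["mcnemar_stat"] = r.mcnemar.statistic
            row["mcnemar_p"] = r.mcnemar.p
            row["conf_incorrect_change"] = r.confident_incorrect_change
            rows.append(row)
    df = pd.DataFrame(rows)
    if round_output:
        for c in (*CHOICES, "true_pct", "false_pct"):
            df[c] = df[c].round(0).astype(int)
        df["conf_incorrect_change"] = df["conf_incorrect_change"].round(0)
        df["mcnemar_stat"] = df["mcnemar_stat"].round(2)
        df["mcnemar_p"] = df["mcnemar_p"].round(3)
    return df
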