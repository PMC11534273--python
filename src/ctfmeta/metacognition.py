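"""Metacognitive calibration indices from (confident, correct) classifications.

Each response is reduced to two bits — was the participant confident, and
was the answer correct — giving four counts per participant-phase:

* ``cc`` confident-correct, ``uc`` unconfident-correct,
* ``ci`` confident-incorrect, ``ui`` unconfident-incorrect.

From those counts, five indices:

* AC  (absolute accuracy) = (cc + ui) / n — how often confidence matched
  the outcome (confident when right, unsure when wrong).
* BS  (bias) = confidence rate − accuracy rate = (ci − uc) / n.
  Positive means overconfident, negative underconfident, 0 calibrated.
* CCP = cc / (cc + uc) — probability of being confident given a correct
  answer; undefined when the participant got nothing right.
* CIP = ci / (ci + ui) — probability of being confident given an
  incorrect answer; undefined when the participant got nothing wrong.
* DIS = CCP − CIP — how reliably confidence discriminates correct from
  incorrect answers; undefined when either ratio is.

Undefined components are carried as NaN and excluded pairwise downstream;
they are never imputed, since imputing 0 or 1 would manufacture bias in
exactly the quantities under study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_cohort import CONFIDENT_CHOICES, PHASES, ItemBank, PairedCohort
from .scoring import binary_correct, matrix_flags

PROFILE_COLUMNS = ("ac", "bs", "ccp", "cip", "dis", "cc", "ci", "uc", "ui")


@dataclass(frozen=True)
class ClassifiedResponse:
    confident: bool
    correct: bool


def classify(choice: str, answer_key: bool) -> ClassifiedResponse:
    """Reduce one CTF response to its (confident, correct) bits."""
    return ClassifiedResponse(
        confident=choice in CONFIDENT_CHOICES,
        correct=binary_correct(choice, answer_key),
    )


@dataclass(frozen=True)
class MetacogProfile:
    """Calibration counts and the five indices for one participant-phase.

    ``ccp``, ``cip`` and ``dis`` are NaN when their denominators are zero.
    """

    cc: int
    ci: int
    uc: int
    ui: int

    @property
    def n_items(self) -> int:
        return self.cc + self.ci + self.uc + self.ui

    @property
    def ac(self) -> float:
        return (self.cc + self.ui) / self.n_items

    @property
    def bs(self) -> float:
        return (self.ci - self.uc) / self.n_items

    @property
    def ccp(self) -> float:
        denom = self.cc + self.uc
        return self.cc / denom if denom else math.nan

    @property
    def cip(self) -> float:
        denom = self.ci + self.ui
        return self.ci / denom if denom else math.nan

    @property
    def dis(self) -> float:
        return self.ccp - self.cip  # NaN propagates when either is undefined


def metacog_profile(classified: Iterable[ClassifiedResponse]) -> MetacogProfile:
    """Aggregate classified responses into a :class:`MetacogProfile`."""
    cc = ci = uc = ui = 0
    for r in classified:
        if r.confident:
            if r.correct:
                cc += 1
            else:
                ci += 1
        else:
            if r.correct:
                uc += 1
            else:
                ui += 1
    if cc + ci + uc + ui == 0:
        raise ValueError("cannot profile an empty response list")
    return MetacogProfile(cc=cc, ci=ci, uc=uc, ui=ui)


def profile_participant(
    responses: Sequence[tuple[str, bool]] | dict[str, str],
    bank: ItemBank | None = None,
) -> MetacogProfile:
    """Profile one participant-phase from raw (choice, key) pairs or an
    item_id -> choice mapping resolved against *bank*."""
    if isinstance(responses, dict):
        if bank is None:
            raise ValueError("bank required when responses are keyed by item_id")
        keys = bank.answer_keys
        pairs = [(choice, keys[item]) for item, choice in responses.items()]
    else:
        pairs = list(responses)
    return metacog_profile(classify(c, k) for c, k in pairs)


def profile_cohort(cohort: PairedCohort, bank: ItemBank) -> pd.DataFrame:
    """Compute all five indices for every participant at both phases.

    Returns a DataFrame indexed by (participant_id, phase) with columns
    ``ac, bs, ccp, cip, dis, cc, ci, uc, ui``; undefined index values are
    NaN so they propagate as missing into downstream inference.
    """
    frames = []
    for phase in PHASES:
        m = cohort.phase_matrix(phase)
        confident, correct = matrix_flags(m, bank)
        cc = (confident & correct).sum(axis=1)
        ci = (confident & ~correct).sum(axis=1)
        uc = (~confident & correct).sum(axis=1)
        ui = (~confident & ~correct).sum(axis=1)
        n = cc + ci + uc + ui
        with np.errstate(divide="ignore", invalid="ignore"):
            ccp = np.where(cc + uc > 0, cc / np.maximum(cc + uc, 1), np.nan)
            cip = np.where(ci + ui > 0, ci / np.maximum(ci + ui, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "phase": phase,
                    "ac": (cc + ui) / n,
                    "bs": (ci - uc) / n,
                    "ccp": ccp,
                    "cip": cip,
                    "dis": ccp - cip,
                    "cc": cc,
                    "ci": ci,
                    "uc": uc,
                    "ui": ui,
                },
                index=m.index,
            )
        )
    out = pd.concat(frames).set_index("phase", append=True)
    return out.sort_index(level="participant_id", sort_remaining=False)
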