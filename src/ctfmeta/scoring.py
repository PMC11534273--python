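"""Content-knowledge scoring of CTF responses.

Three scores are computed per participant per phase:

* ``ctf_sum`` — the summed confidence-weighted score.  Each item earns
  points from a 4-vector over (confident-correct, unsure-correct,
  unsure-incorrect, confident-incorrect); the default mapping is
  (4, 3, 1, 0), so a 20-item test spans 0-80.
* ``ctf_pct`` — ``ctf_sum`` as a percent of the maximum attainable.
* ``binary_pct`` — percent of items whose true/false direction matches
  the key, regardless of confidence.

The point 4-vector is configurable so alternative published mappings can
be swapped in; only the endpoints (confident-correct highest,
confident-incorrect lowest) are fixed by the scoring construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_cohort import (
    CHOICES,
    CONFIDENT_CHOICES,
    PHASES,
    TRUE_DIRECTION,
    ItemBank,
    PairedCohort,
)

#: Points for (confident-correct, unsure-correct, unsure-incorrect, confident-incorrect).
DEFAULT_POINTS = (4, 3, 1, 0)


def _check_points(points) -> tuple[float, float, float, float]:
    pts = tuple(points)
    if len(pts) != 4:
        raise ValueError("points must be a 4-vector")
    if not (pts[0] > pts[1] >= pts[2] > pts[3]):
        raise ValueError("points must decrease from confident-correct to confident-incorrect")
    return pts


def binary_correct(choice: str, answer_key: bool) -> bool:
    """True iff the true/false direction of *choice* matches *answer_key*."""
    if choice not in CHOICES:
        raise ValueError(f"unknown choice {choice!r}")
    return (choice in TRUE_DIRECTION) == answer_key


def ctf_points(choice: str, answer_key: bool, points=DEFAULT_POINTS) -> int:
    """Confidence-weighted points for one response."""
    pts = _check_points(points)
    correct = binary_correct(choice, answer_key)
    confident = choice in CONFIDENT_CHOICES
    if correct:
        return pts[0] if confident else pts[1]
    return pts[3] if confident else pts[2]


@dataclass(frozen=True)
class ScoreVector:
    """The three content-knowledge scores for one participant-phase."""

    ctf_sum: float
    ctf_pct: float
    binary_pct: float
    n_items: int


def score_participant(
    responses: Mapping[str, str] | pd.Series,
    bank: ItemBank,
    points=DEFAULT_POINTS,
) -> ScoreVector:
    """Score one participant's single-phase responses against the bank.

    *responses* maps item_id -> choice and must cover the bank exactly
    (no missing or extra items).
    """
    pts = _check_points(points)
    resp = dict(responses.items())
    bank_ids = set(bank.item_ids)
    extra = set(resp) - bank_ids
    missing = bank_ids - set(resp)
    if extra or missing:
        raise ValueError(
            f"responses do not match bank: {len(missing)} missing, {len(extra)} extra items"
        )
    keys = bank.answer_keys
    total = 0.0
    n_correct = 0
    for item_id, choice in resp.items():
        total += ctf_points(choice, keys[item_id], pts)
        n_correct += binary_correct(choice, keys[item_id])
    n = len(bank)
    return ScoreVector(
        ctf_sum=total,
        ctf_pct=100.0 * total / (max(pts) * n),
        binary_pct=100.0 * n_correct / n,
        n_items=n,
    )


def matrix_flags(matrix: pd.DataFrame, bank: ItemBank) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (confident, correct) boolean arrays for a choice matrix.

    *matrix* is participant x item_id with CTF choice labels; columns must
    be bank item ids.  Shared by the scoring and metacognition cohort paths.
    """
    arr = matrix.to_numpy(dtype=object)
    confident = np.isin(arr, list(CONFIDENT_CHOICES))
    direction_true = np.isin(arr, list(TRUE_DIRECTION))
    keys = np.array([bank.answer_keys[c] for c in matrix.columns], dtype=bool)
    correct = direction_true == keys[None, :]
    return confident, correct


def score_cohort(
    cohort: PairedCohort, bank: ItemBank, points=DEFAULT_POINTS
) -> pd.DataFrame:
    """Score every participant at both phases.

    Returns a DataFrame indexed by (participant_id, phase) with columns
    ``ctf_sum, ctf_pct, binary_pct, n_items``.
    """
    pts = _check_points(points)
    frames = []
    n = len(bank)
    for phase in PHASES:
        m = cohort.phase_matrix(phase)
        confident, correct = matrix_flags(m, bank)
        pt = np.where(
            correct,
            np.where(confident, pts[0], pts[1]),
            np.where(confident, pts[3], pts[2]),
        ).astype(float)
        ctf_sum = pt.sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "phase": phase,
                    "ctf_sum": ctf_sum,
                    "ctf_pct": 100.0 * ctf_sum / (max(pts) * n),
                    "binary_pct": 100.0 * correct.mean(axis=1),
                    "n_items": n,
                },
                index=m.index,
            )
        )
    out = pd.concat(frames).set_index("phase", append=True)
    return out.sort_index(level="participant_id", sort_remaining=False)
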