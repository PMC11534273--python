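"""Synthetic paired pre-post CTF cohorts with known latent structure.

No participant-level data from confidence-weighted assessments of this
kind are typically public, so the pipeline is exercised on simulated
cohorts whose generating parameters are known exactly.

The generative model:

* Each participant i draws a latent pretest correctness probability
  p_i ~ Beta(a, b); their ability on the log-odds scale is
  theta_i = logit(p_i).
* Each item j carries a difficulty offset d_j ~ Normal(0, sd).
* Correctness of participant i on item j is Bernoulli with probability
  expit(theta_i - d_j) at pretest and expit(theta_i + effect - d_j) at
  posttest, where ``knowledge_effect`` is the intervention's additive
  log-odds shift.
* The answer's true/false direction follows correctness against the key;
  confidence is then Bernoulli with probability gamma_cc (if correct) or
  gamma_ci (if incorrect), each with its own pre and post value.  This
  conditional-independence structure (confidence depends on correctness
  and phase, not item identity) is the simplest model that can move every
  index the pipeline computes.
* A participant skips the posttest with probability ``dropout_post``;
  otherwise they may log up to ``extra_attempts_max`` additional posttest
  attempts at strictly later times, each with an ``attempt_gain``
  log-odds correctness bonus — so scoring anything but the first attempt
  measurably inflates scores, making the first-attempt rule testable.

Defaults mirror the shape of a 307-learner, 20-item (13 false-keyed)
continuing-education cohort with a real knowledge and confidence gain.
A fixed seed makes the output bit-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_cohort import CHOICES, Item, ItemBank, save_item_bank, save_responses

_PROB_FIELDS = (
    "frac_false_keyed",
    "conf_given_correct_pre",
    "conf_given_correct_post",
    "conf_given_incorrect_pre",
    "conf_given_incorrect_post",
    "dropout_post",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator (see module docstring)."""

    n_participants: int = 307
    n_items: int = 20
    frac_false_keyed: float = 13 / 20
    knowledge_pre: tuple[float, float] = (6.0, 4.0)  # Beta(a, b) on p_correct
    knowledge_effect: float = 0.5  # additive log-odds shift at posttest
    conf_given_correct_pre: float = 0.40
    conf_given_correct_post: float = 0.85
    conf_given_incorrect_pre: float = 0.20
    conf_given_incorrect_post: float = 0.75
    item_difficulty_sd: float = 0.5
    dropout_post: float = 0.0
    extra_attempts_max: int = 0
    attempt_gain: float = 0.5  # log-odds bonus per later attempt
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability in [0, 1]")
        a, b = self.knowledge_pre
        if a <= 0 or b <= 0:
            raise ValueError("knowledge_pre Beta parameters must be positive")
        if self.item_difficulty_sd < 0:
            raise ValueError("item_difficulty_sd must be non-negative")
        if self.extra_attempts_max < 0:
            raise ValueError("extra_attempts_max must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["knowledge_pre"] = list(self.knowledge_pre)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "knowledge_pre" in d:
            d["knowledge_pre"] = tuple(d["knowledge_pre"])
        return cls(**d)


@dataclass(frozen=True)
class SimulatedTruth:
    """Latent quantities behind a simulated cohort."""

    ability_logit: np.ndarray  # (n_participants,)
    p_correct_pre: np.ndarray  # (n_participants,) marginal over items
    p_correct_post: np.ndarray
    item_difficulty: np.ndarray  # (n_items,)
    config: SimulationConfig

    def to_dict(self) -> dict:
        return {
            "ability_logit": self.ability_logit.tolist(),
            "p_correct_pre": self.p_correct_pre.tolist(),
            "p_correct_post": self.p_correct_post.tolist(),
            "item_difficulty": self.item_difficulty.tolist(),
            "config": self.config.to_dict(),
        }


@dataclass(frozen=True)
class SimulatedCohort:
    bank: ItemBank
    responses: pd.DataFrame  # long-format ResponseRecord table
    truth: SimulatedTruth


def _synthetic_bank(config: SimulationConfig) -> ItemBank:
    n_false = round(config.frac_false_keyed * config.n_items)
    items = []
    for j in range(config.n_items):
        key = j >= n_false  # first n_false items keyed False
        items.append(
            Item(
                item_id=f"q{j + 1}",
                statement=f"Synthetic statement {j + 1} (keyed {'True' if key else 'False'}).",
                answer_key=key,
            )
        )
    return ItemBank(items=tuple(items))


def _choices(correct: np.ndarray, confident: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Map (correct, confident) draws to CTF choice labels given item keys."""
    direction_true = correct == keys[None, :]
    out = np.where(
        direction_true,
        np.where(confident, "sure_true", "unsure_true"),
        np.where(confident, "sure_false", "unsure_false"),
    )
    return out.astype(object)


def _phase_frame(
    choices: np.ndarray,
    pids: np.ndarray,
    item_ids: list[str],
    phase: str,
    attempt_time: int,
    keep: np.ndarray | None = None,
) -> pd.DataFrame:
    n, m = choices.shape
    if keep is None:
        keep = np.ones(n, dtype=bool)
    idx = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(pids[idx], m),
            "phase": phase,
            "attempt_time": attempt_time,
            "item_id": np.tile(np.array(item_ids, dtype=object), idx.size),
            "choice": choices[idx].ravel(),
        }
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort (bank, long response table, truth).

    Output is deterministic given ``config.seed``; rows are sorted by
    participant, phase (pre first), attempt time, then item order.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_participants, config.n_items
    bank = _synthetic_bank(config)
    keys = np.array([it.answer_key for it in bank], dtype=bool)
    item_ids = list(bank.item_ids)
    width = len(str(n))
    pids = np.array([f"p{i + 1:0{width}d}" for i in range(n)], dtype=object)

    a, b = config.knowledge_pre
    theta = logit(rng.beta(a, b, size=n))
    diff = rng.normal(0.0, config.item_difficulty_sd, size=m)

    frames = []

    # Pretest
    p_pre = expit(theta[:, None] - diff[None, :])
    correct = rng.random((n, m)) < p_pre
    p_conf = np.where(correct, config.conf_given_correct_pre, config.conf_given_incorrect_pre)
    confident = rng.random((n, m)) < p_conf
    frames.append(_phase_frame(_choices(correct, confident, keys), pids, item_ids, "pre", 0))

    # Posttest: dropout, then first attempt plus optional later retakes.
    took_post = rng.random(n) >= config.dropout_post
    logit_post = theta[:, None] + config.knowledge_effect - diff[None, :]
    n_extra = (
        rng.integers(0, config.extra_attempts_max + 1, size=n)
        if config.extra_attempts_max > 0
        else np.zeros(n, dtype=int)
    )
    max_attempts = int(n_extra.max()) + 1
    for attempt in range(max_attempts):
        keep = took_post & (n_extra >= attempt)
        p_att = expit(logit_post + config.attempt_gain * attempt)
        correct = rng.random((n, m)) < p_att
        p_conf = np.where(
            correct, config.conf_given_correct_post, config.conf_given_incorrect_post
        )
        confident = rng.random((n, m)) < p_conf
        frames.append(
            _phase_frame(
                _choices(correct, confident, keys),
                pids,
                item_ids,
                "post",
                attempt + 1,
                keep=keep,
            )
        )

    responses = pd.concat(frames, ignore_index=True)
    phase_order = responses["phase"].map({"pre": 0, "post": 1})
    item_order = responses["item_id"].map({iid: j for j, iid in enumerate(item_ids)})
    responses = (
        responses.assign(_p=phase_order, _i=item_order)
        .sort_values(["participant_id", "_p", "attempt_time", "_i"], kind="mergesort")
        .drop(columns=["_p", "_i"])
        .reset_index(drop=True)
    )
    responses["attempt_time"] = responses["attempt_time"].astype("int64")

    truth = SimulatedTruth(
        ability_logit=theta,
        p_correct_pre=expit(theta[:, None] - diff[None, :]).mean(axis=1),
        p_correct_post=expit(logit_post).mean(axis=1),
        item_difficulty=diff,
        config=config,
    )
    return SimulatedCohort(bank=bank, responses=responses, truth=truth)


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict[str, Path]:
    """Write bank.json, responses.csv and truth.json; returns the paths.

    Byte-identical across runs with the same config (fixed column order,
    sorted rows, plain-text formats).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bank": out / "bank.json",
        "responses": out / "responses.csv",
        "truth": out / "truth.json",
    }
    save_item_bank(cohort.bank, paths["bank"])
    save_responses(cohort.responses, paths["responses"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(cohort.truth.to_dict(), fh, indent=1)
        fh.write("\n")
    return paths


def recover_parameters(cohort: SimulatedCohort) -> pd.DataFrame:
    """Estimate the confidence parameters back from a simulated cohort.

    The cohort-mean CCP at each phase estimates gamma_cc (confidence given
    correct) and the cohort-mean CIP estimates gamma_ci; the mean binary
    proportion correct estimates the marginal of the logistic ability
    model.  Returns one row per quantity with estimate, truth, bias, and
    the across-participant RMSE about the true value.
    """
    from .io_cohort import build_paired_cohort, select_first_posttest
    from .metacognition import profile_cohort

    cfg = cohort.truth.config
    paired = build_paired_cohort(select_first_posttest(cohort.responses), cohort.bank)
    profiles = profile_cohort(paired, cohort.bank)

    truths = {
        ("ccp", "pre"): cfg.conf_given_correct_pre,
        ("ccp", "post"): cfg.conf_given_correct_post,
        ("cip", "pre"): cfg.conf_given_incorrect_pre,
        ("cip", "post"): cfg.conf_given_incorrect_post,
        ("binary", "pre"): float(cohort.truth.p_correct_pre.mean()),
        ("binary", "post"): float(cohort.truth.p_correct_post.mean()),
    }
    rows = []
    counts = profiles[["cc", "ci", "uc", "ui"]]
    for (quantity, phase), truth_val in truths.items():
        if quantity == "binary":
            ph = counts.xs(phase, level="phase")
            vals = (ph["cc"] + ph["uc"]) / ph.sum(axis=1)
        else:
            vals = profiles[quantity].xs(phase, level="phase").dropna()
        est = float(vals.mean())
        rows.append(
            {
                "quantity": quantity,
                "phase": phase,
                "estimate": est,
                "truth": truth_val,
                "bias": est - truth_val,
                "rmse": float(np.sqrt(np.mean((vals - truth_val) ** 2))),
                "n_used": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index(["quantity", "phase"])
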