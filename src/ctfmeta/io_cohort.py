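"""Item banks, CTF response tables, and paired-cohort assembly.

The raw input for a confidence-weighted true-false (CTF) assessment is a
long-format table with one row per participant x phase x attempt x item,
where each answer is one of four levels (confident/unsure crossed with
true/false).  This module validates those inputs, applies the
first-posttest rule (when a participant retook the posttest, only the
chronologically first attempt counts), and pivots the records into the
wide complete-case matrix that the scoring and metacognition modules
consume.  Participants missing either phase, or with incomplete item
coverage within a phase, are excluded with a logged reason — the analysis
is defined on completers only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: The four CTF answer categories, in canonical order.
CHOICES = ("sure_true", "unsure_true", "unsure_false", "sure_false")

#: Choices expressing confidence ("I am confident this is ...").
CONFIDENT_CHOICES = frozenset({"sure_true", "sure_false"})

#: Choices whose true/false direction is "true".
TRUE_DIRECTION = frozenset({"sure_true", "unsure_true"})

PHASES = ("pre", "post")

_PHASE_ALIASES = {"pre": "pre", "pretest": "pre", "post": "post", "posttest": "post"}

RESPONSE_COLUMNS = ("participant_id", "phase", "attempt_time", "item_id", "choice")


class ValidationError(ValueError):
    """Raised when an item bank or response table violates its contract."""


@dataclass(frozen=True)
class Item:
    """A single true/false statement with its answer key.

    ``answer_key`` is True when the statement is true.  ``concept_group``
    optionally tags the item as part of a conceptual cluster (e.g. the
    three items about the RIOSORD overdose-risk index).
    """

    item_id: str
    statement: str
    answer_key: bool
    concept_group: str | None = None


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of CTF items with unique ids."""

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError("item bank is empty")
        seen: set[str] = set()
        for it in self.items:
            if not it.item_id:
                raise ValidationError("item with empty id")
            if it.item_id in seen:
                raise ValidationError(f"duplicate item_id {it.item_id!r}")
            seen.add(it.item_id)
            if not isinstance(it.answer_key, bool):
                raise ValidationError(f"item {it.item_id!r}: answer_key must be boolean")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def answer_keys(self) -> dict[str, bool]:
        return {it.item_id: it.answer_key for it in self.items}

    @property
    def n_false_keyed(self) -> int:
        return sum(not it.answer_key for it in self.items)

    def group(self, name: str) -> tuple[str, ...]:
        """Item ids belonging to the named concept group, in bank order."""
        return tuple(it.item_id for it in self.items if it.concept_group == name)

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "id": it.item_id,
                    "statement": it.statement,
                    "answer": "T" if it.answer_key else "F",
                    **({"group": it.concept_group} if it.concept_group else {}),
                }
                for it in self.items
            ]
        }


def load_item_bank(path) -> ItemBank:
    """Read an item bank from JSON.

    Expected layout::

        {"items": [{"id": "q1", "statement": "...", "answer": "F",
                    "group": "riosord"}, ...]}

    ``answer`` is ``"T"`` or ``"F"``.  Item order in the file is preserved.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict) or "items" not in raw:
        raise ValidationError(f"{path}: expected a JSON object with an 'items' list")
    items = []
    for i, entry in enumerate(raw["items"]):
        missing = {"id", "statement", "answer"} - set(entry)
        if missing:
            raise ValidationError(f"{path}: item #{i} missing fields {sorted(missing)}")
        ans = str(entry["answer"]).strip().upper()
        if ans not in {"T", "F"}:
            raise ValidationError(
                f"{path}: item {entry['id']!r} has answer {entry['answer']!r}; expected 'T' or 'F'"
            )
        items.append(
            Item(
                item_id=str(entry["id"]),
                statement=str(entry["statement"]),
                answer_key=ans == "T",
                concept_group=entry.get("group"),
            )
        )
    return ItemBank(items=tuple(items))


def save_item_bank(bank: ItemBank, path) -> None:
    """Write an item bank to JSON (inverse of :func:`load_item_bank`)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bank.to_dict(), fh, indent=1)
        fh.write("\n")


def _parse_attempt_time(col: pd.Series, path) -> pd.Series:
    """Parse attempt times as integers or ISO-8601 timestamps (never lexically)."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.astype("int64")
    parsed = pd.to_datetime(col, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = col[parsed.isna()].index[0]
        raise ValidationError(
            f"{path}: row {bad}: attempt_time {col[bad]!r} is neither an integer "
            "nor an ISO-8601 timestamp"
        )
    return parsed


def load_responses(path, bank: ItemBank) -> pd.DataFrame:
    """Read a long-format CTF response table from CSV.

    Required header: ``participant_id,phase,attempt_time,item_id,choice``.
    Phase labels are normalized case-insensitively from pre/pretest and
    post/posttest; choices must be one of the four CTF levels; item ids
    must resolve against *bank*.  Returns a DataFrame with one validated
    record per row.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df = df.loc[:, list(RESPONSE_COLUMNS)].copy()
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0])
        raise ValidationError(f"{path}: row {row}: empty field")

    phase = df["phase"].str.strip().str.lower().map(_PHASE_ALIASES)
    if phase.isna().any():
        row = int(phase[phase.isna()].index[0])
        raise ValidationError(
            f"{path}: row {row}: unknown phase {df['phase'][row]!r} "
            "(expected pre/pretest or post/posttest)"
        )
    df["phase"] = phase

    bad_choice = ~df["choice"].isin(CHOICES)
    if bad_choice.any():
        row = int(df[bad_choice].index[0])
        raise ValidationError(
            f"{path}: row {row}: unparseable choice {df['choice'][row]!r}; "
            f"expected one of {CHOICES}"
        )

    known = set(bank.item_ids)
    bad_item = ~df["item_id"].isin(known)
    if bad_item.any():
        row = int(df[bad_item].index[0])
        raise ValidationError(f"{path}: row {row}: unknown item_id {df['item_id'][row]!r}")

    df["attempt_time"] = _parse_attempt_time(df["attempt_time"], path)

    dup = df.duplicated(subset=list(RESPONSE_COLUMNS[:4]), keep=False)
    if dup.any():
        row = int(df[dup].index[0])
        raise ValidationError(
            f"{path}: row {row}: duplicate (participant_id, phase, attempt_time, item_id)"
        )
    return df


def save_responses(records: pd.DataFrame, path) -> None:
    """Write a response table to CSV (inverse of :func:`load_responses`).

    Integer attempt times are written as integers, timestamps in ISO-8601.
    """
    out = records.loc[:, list(RESPONSE_COLUMNS)].copy()
    if pd.api.types.is_datetime64_any_dtype(out["attempt_time"]):
        out["attempt_time"] = out["attempt_time"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False, lineterminator="\n")


def select_first_posttest(records: pd.DataFrame) -> pd.DataFrame:
    """Keep, per participant, only the chronologically first posttest attempt.

    Pretest records pass through unchanged.  Two posttest attempts sharing
    an attempt_time cannot be ordered chronologically and raise a
    :class:`ValidationError` rather than being silently tie-broken.
    Idempotent: applying it twice equals applying it once.
    """
    is_post = records["phase"] == "post"
    post = records[is_post]
    if post.empty:
        return records.copy()

    same_time_dup = post.duplicated(
        subset=["participant_id", "attempt_time", "item_id"], keep=False
    )
    if same_time_dup.any():
        pid = post[same_time_dup]["participant_id"].iloc[0]
        raise ValidationError(
            f"participant {pid!r}: two posttest attempts share the same attempt_time; "
            "the chronological first-attempt rule cannot break this tie"
        )

    first = post.groupby("participant_id")["attempt_time"].transform("min")
    keep_post = post[post["attempt_time"] == first]
    n_dropped = len(post) - len(keep_post)
    if n_dropped:
        logger.info("first-posttest rule dropped %d later-attempt records", n_dropped)
    out = pd.concat([records[~is_post], keep_post]).sort_index()
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class PairedCohort:
    """Complete-case pre/post response matrix.

    ``wide`` is indexed by participant_id with a (phase, item_id)
    MultiIndex on the columns, holding CTF choice labels.  Only
    participants with exactly one response per item per phase are present.
    """

    wide: pd.DataFrame
    exclusions: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def participants(self) -> list[str]:
        return list(self.wide.index)

    @property
    def n(self) -> int:
        return len(self.wide)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.wide["pre"].columns)

    def phase_matrix(self, phase: str) -> pd.DataFrame:
        """Participant x item matrix of choices for one phase (bank order)."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return self.wide[phase]

    def choice(self, participant_id: str, phase: str, item_id: str) -> str:
        return self.wide.at[participant_id, (phase, item_id)]

    def responses(self, participant_id: str, phase: str) -> pd.Series:
        """One participant's choices for one phase, as an item_id -> choice Series."""
        return self.wide.loc[participant_id, phase]


def build_paired_cohort(records: pd.DataFrame, bank: ItemBank) -> PairedCohort:
    """Assemble the paired complete-case cohort from deduplicated records.

    A participant enters the cohort only with both phases present and full,
    single-response item coverage in each; everyone else is excluded and
    logged with a reason.  Raises :class:`ValidationError` if no participant
    qualifies.  Output is invariant to input row order.
    """
    bank_ids = list(bank.item_ids)
    item_set = set(bank_ids)
    rows: dict[str, dict] = {}
    exclusions: list[tuple[str, str]] = []

    for pid, grp in records.groupby("participant_id", sort=True):
        reason = None
        row: dict = {}
        for phase in PHASES:
            sub = grp[grp["phase"] == phase]
            if sub.empty:
                reason = f"missing {phase}test"
                break
            if sub["item_id"].duplicated().any():
                reason = f"multiple responses per item at {phase}test"
                break
            covered = set(sub["item_id"])
            if covered != item_set:
                n_missing = len(item_set - covered)
                reason = f"incomplete {phase}test item coverage ({n_missing} items missing)"
                break
            for item, choice in zip(sub["item_id"], sub["choice"]):
                row[(phase, item)] = choice
        if reason is None:
            rows[str(pid)] = row
        else:
            exclusions.append((str(pid), reason))
            logger.info("excluding participant %s: %s", pid, reason)

    if not rows:
        raise ValidationError("no participant has complete pre and post responses")

    columns = pd.MultiIndex.from_product([PHASES, bank_ids], names=["phase", "item_id"])
    wide = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    wide.index.name = "participant_id"
    logger.info("paired cohort: n=%d (%d excluded)", len(wide), len(exclusions))
    return PairedCohort(wide=wide, exclusions=tuple(exclusions))
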