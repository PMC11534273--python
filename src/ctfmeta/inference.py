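"""Paired pre-post inference: Wilcoxon signed-rank, effect sizes, McNemar.

Score distributions on a 20-item test live on coarse grids, so ties and
zero differences are the rule, not the exception.  The signed-rank test
here uses midranks with the tie-corrected variance

    var(W+) = n(n+1)(2n+1)/24 − Σ(t³ − t)/48

and the normal approximation without continuity correction.  Zero
differences are discarded by default (classic Wilcoxon); the Pratt
variant, which ranks zeros before dropping them, is available via
``zero_method="pratt"``.

Sign convention: z is negative when posttest values systematically exceed
pretest values, so an improvement after an intervention prints a negative
z.  Effect sizes are Rosenthal correlations r = z/sqrt(N) over the pairs
actually analyzed.  McNemar's test on paired binary correctness uses the
plain chi-square form (b − c)²/(b + c) on the discordant counts, 1 df,
no continuity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: |r| thresholds separating weak / moderate / strong effect labels.
EFFECT_THRESHOLDS = (0.30, 0.60)

#: Summary rows, in report order: (column, table from, display label).
SUMMARY_MEASURES = (
    ("ctf_sum", "scores", "CTF overall score"),
    ("binary_pct", "scores", "Binary true/false score"),
    ("ac", "profiles", "Absolute accuracy of confidence judgments"),
    ("bs", "profiles", "Bias of the confidence judgments"),
    ("ccp", "profiles", "Confident correct probability"),
    ("cip", "profiles", "Confident incorrect probability"),
    ("dis", "profiles", "Discrimination between correct and incorrect decisions"),
)


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    n_effective: int  # pairs with nonzero difference
    n_pairs: int  # pairs entering the test


@dataclass(frozen=True)
class EffectSize:
    r: float
    label: str


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p: float
    b: int  # pre-correct -> post-incorrect
    c: int  # pre-incorrect -> post-correct


def _tie_term(ranks_of: np.ndarray) -> float:
    _, counts = np.unique(ranks_of, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def wilcoxon_signed_rank(pre, post, zero_method: str = "discard") -> WilcoxonResult:
    """Tie-corrected Wilcoxon signed-rank test on paired values.

    Pairs where either member is missing are dropped (and logged).
    Raises ``ValueError`` with fewer than 5 nonzero differences — at that
    size the normal approximation is meaningless and an exact test should
    be used instead.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired, equal-length vectors")
    mask = ~(np.isnan(pre) | np.isnan(post))
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("wilcoxon: dropped %d incomplete pairs", n_dropped)
    d = post[mask] - pre[mask]
    n_pairs = int(d.size)

    nonzero = d != 0
    n_eff = int(nonzero.sum())
    if n_eff < 5:
        raise ValueError(
            f"only {n_eff} nonzero differences; normal approximation invalid "
            "(use an exact/permutation test)"
        )

    if zero_method == "discard":
        dz = d[nonzero]
        n = dz.size
        ranks = stats.rankdata(np.abs(dz))
        w_plus = float(ranks[dz > 0].sum())
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(np.abs(dz)) / 48.0
    elif zero_method == "pratt":
        n = d.size
        n0 = n - n_eff
        ranks = stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        mu = (n * (n + 1) - n0 * (n0 + 1)) / 4.0
        var = (
            n * (n + 1) * (2 * n + 1) / 24.0
            - n0 * (n0 + 1) * (2 * n0 + 1) / 24.0
            - _tie_term(np.abs(d[nonzero])) / 48.0
        )
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    if var <= 0:
        raise ValueError("degenerate signed-rank variance (all differences tied at zero?)")
    # Negative z for systematic post > pre improvement.
    z = (mu - w_plus) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return WilcoxonResult(z=z, p=float(min(p, 1.0)), n_effective=n_eff, n_pairs=n_pairs)


def effect_label(r: float) -> str:
    a = abs(r)
    if a < EFFECT_THRESHOLDS[0]:
        return "weak"
    if a < EFFECT_THRESHOLDS[1]:
        return "moderate"
    return "strong"


def rosenthal_r(z: float, n_pairs: int) -> EffectSize:
    """Rosenthal effect-size correlation r = z / sqrt(N) with qualitative label."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    r = z / math.sqrt(n_pairs)
    return EffectSize(r=r, label=effect_label(r))


def mcnemar(pre_correct, post_correct) -> McNemarResult:
    """McNemar chi-square test (no continuity correction) on paired booleans."""
    pre = np.asarray(pre_correct, dtype=bool)
    post = np.asarray(post_correct, dtype=bool)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired, equal-length vectors")
    b = int((pre & ~post).sum())
    c = int((~pre & post).sum())
    if b + c == 0:
        return McNemarResult(statistic=0.0, p=1.0, b=b, c=c)
    statistic = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic=statistic, p=p, b=b, c=c)


def format_p(p: float, decimals: int = 3, floor: float = 0.001) -> str:
    """Render a p-value with the conventional '<.001' floor."""
    if np.isnan(p):
        return ""
    if p < floor:
        return f"<{floor:.3f}".replace("0.", ".")
    return f"{p:.{decimals}f}".replace("0.", ".", 1) if p < 1 else f"{p:.{decimals}f}"


def prepost_summary(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    zero_method: str = "discard",
) -> pd.DataFrame:
    """Score-by-score pre/post summary with paired tests and effect sizes.

    One row per measure (CTF sum, binary percent, AC, BS, CCP, CIP, DIS):
    median/IQR/range at each phase, tie-corrected Wilcoxon z and p,
    Rosenthal r with label, and the pairwise-complete N for that row.
    Participants with an undefined index value are excluded pairwise for
    that row only (``n_excluded``).  Rows whose differences are all zero
    (or nearly all) are flagged in ``note`` instead of erroring.
    """
    tables = {"scores": scores, "profiles": profiles}
    rows = []
    for col, source, label in SUMMARY_MEASURES:
        series = tables[source][col]
        pre = series.xs("pre", level="phase")
        post = series.xs("post", level="phase")
        pre, post = pre.align(post, join="inner")
        mask = pre.notna() & post.notna()
        n_pairs = int(mask.sum())
        n_excluded = int(len(pre) - n_pairs)
        if n_excluded:
            logger.info("%s: excluded %d participants with undefined values", col, n_excluded)
        p_pre = pre[mask]
        p_post = post[mask]
        row = {
            "measure": col,
            "label": label,
            "pre_median": p_pre.median(),
            "pre_q1": p_pre.quantile(0.25),
            "pre_q3": p_pre.quantile(0.75),
            "pre_min": p_pre.min(),
            "pre_max": p_pre.max(),
            "post_median": p_post.median(),
            "post_q1": p_post.quantile(0.25),
            "post_q3": p_post.quantile(0.75),
            "post_min": p_post.min(),
            "post_max": p_post.max(),
            "n_pairs": n_pairs,
            "n_excluded": n_excluded,
        }
        try:
            res = wilcoxon_signed_rank(p_pre, p_post, zero_method=zero_method)
            eff = rosenthal_r(res.z, res.n_pairs)
            row.update(
                z=res.z,
                p=res.p,
                n_effective=res.n_effective,
                r=eff.r,
                effect=eff.label,
                note="",
            )
        except ValueError as err:
            row.update(
                z=np.nan, p=np.nan, n_effective=0, r=np.nan, effect="", note=str(err)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")
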