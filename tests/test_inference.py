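"""Signed-rank test, Rosenthal effect sizes, McNemar, and the summary table."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctfmeta import (
    mcnemar,
    prepost_summary,
    rosenthal_r,
    wilcoxon_signed_rank,
)
from ctfmeta.inference import format_p
from ctfmeta.studydata import STUDY_N, STUDY_Z


def exact_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided p from the full 2^n sign-assignment distribution of W+."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    mu = n * (n + 1) / 4
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [(ranks * np.array(signs)).sum() for signs in itertools.product([0, 1], repeat=n)]
    )
    return float(np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-9))


class TestWilcoxon:
    def test_no_nonzero_differences_error(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="nonzero"):
            wilcoxon_signed_rank(x, x)

    def test_sign_convention_improvement_negative(self):
        pre = [1, 2, 3, 4, 5, 6]
        post = [2, 3, 4, 5, 6, 7]
        res = wilcoxon_signed_rank(pre, post)
        assert res.z < 0
        assert res.n_effective == res.n_pairs == 6

    def test_antisymmetric_in_phase_swap(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=30)
        post = pre + rng.normal(0.3, 1, size=30)
        fwd = wilcoxon_signed_rank(pre, post)
        rev = wilcoxon_signed_rank(post, pre)
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p == pytest.approx(rev.p)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_permutation_small_n(self, seed):
        """Normal-approximation p vs the exhaustive 2^n distribution at
        n=8..10 with all-distinct differences."""
        rng = np.random.default_rng(seed)
        n = 8 + seed % 3
        d = rng.normal(0.5, 1.0, size=n)
        assert len(np.unique(np.abs(d))) == n  # distinct ranks: classic regime
        if (d > 0).all() or (d < 0).all():
            d[0] = -d[0]
        res = wilcoxon_signed_rank(np.zeros(n), d)
        assert abs(res.p - exact_signed_rank_p(d)) <= 0.12

    @pytest.mark.parametrize("zero_method", ["discard", "pratt"])
    def test_cross_check_against_scipy(self, zero_method):
        """Independent oracle: scipy's approx-mode signed-rank with the same
        zero rule gives the same |z| and p (opposite sign convention)."""
        rng = np.random.default_rng(8)
        pre = rng.integers(0, 6, size=40).astype(float)
        post = pre + rng.integers(-2, 4, size=40)
        res = wilcoxon_signed_rank(pre, post, zero_method=zero_method)
        sp = stats.wilcoxon(
            post - pre,
            zero_method="wilcox" if zero_method == "discard" else "pratt",
            correction=False,
            method="approx",
        )
        # scipy's two-sided zstatistic sign tracks min(W+, W-), not a
        # pre/post convention; magnitude and p are the comparable parts
        assert abs(res.z) == pytest.approx(abs(sp.zstatistic))
        assert res.p == pytest.approx(sp.pvalue)

    def test_distinct_differences_match_textbook_closed_form(self):
        rng = np.random.default_rng(15)
        d = rng.normal(0.8, 1.0, size=25)  # continuous: no ties, tie term = 0
        res = wilcoxon_signed_rank(np.zeros(25), d)
        n = 25
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        z_closed = (n * (n + 1) / 4 - w_plus) / math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        assert res.z == pytest.approx(z_closed)

    def test_missing_pairs_dropped(self):
        pre = np.array([1, 2, 3, 4, 5, 6, np.nan, 8.0])
        post = pre + 1
        res = wilcoxon_signed_rank(pre, post)
        assert res.n_pairs == 7


class TestRosenthal:
    @pytest.mark.parametrize(
        "z,expected_r,expected_label",
        [
            (-9.41, -0.54, "moderate"),  # overall CTF score row
            (-13.59, -0.78, "strong"),  # confident-correct probability row
            (0.0, 0.0, "weak"),
        ],
    )
    def test_examples(self, z, expected_r, expected_label):
        eff = rosenthal_r(z, 307)
        assert round(eff.r, 2) == expected_r
        assert eff.label == expected_label

    def test_reproduces_all_published_effect_sizes(self):
        published = {
            "ctf_sum": (-0.54, "moderate"),
            "binary_pct": (-0.54, "moderate"),
            "ac": (-0.54, "moderate"),
            "bs": (-0.75, "strong"),
            "ccp": (-0.78, "strong"),
            "cip": (-0.73, "strong"),
            "dis": (0.16, "weak"),
        }
        for measure, z in STUDY_Z.items():
            eff = rosenthal_r(z, STUDY_N)
            r_expected, label_expected = published[measure]
            assert round(eff.r, 2) == r_expected, measure
            assert eff.label == label_expected, measure


class TestMcNemar:
    def test_symmetric_discordance_null(self):
        pre = [True] * 5 + [False] * 5 + [True] * 3
        post = [False] * 5 + [True] * 5 + [True] * 3
        res = mcnemar(pre, post)
        assert res.statistic == 0.0 and res.p == 1.0
        assert (res.b, res.c) == (5, 5)

    def test_hand_arithmetic(self):
        pre = [True] * 10 + [False] * 2 + [True] * 4
        post = [False] * 10 + [True] * 2 + [True] * 4
        res = mcnemar(pre, post)
        assert res.statistic == pytest.approx(64 / 12)

    def test_no_discordance(self):
        res = mcnemar([True, False], [True, False])
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(3)
        pre = rng.random(200) < 0.5
        post = rng.random(200) < 0.65
        res = mcnemar(pre, post)
        table = [
            [(pre & post).sum(), (pre & ~post).sum()],
            [(~pre & post).sum(), (~pre & ~post).sum()],
        ]
        sm = sm_mcnemar(table, exact=False, correction=False)
        assert res.statistic == pytest.approx(sm.statistic)
        assert res.p == pytest.approx(sm.pvalue)

    @pytest.mark.parametrize(
        "statistic,printed_p",
        [(1.25, 0.26), (0.91, 0.34), (8.56, 0.003), (4.41, 0.04), (6.86, 0.009)],
    )
    def test_chi2_p_reproduces_published_pairs(self, statistic, printed_p):
        p = stats.chi2.sf(statistic, df=1)
        decimals = len(str(printed_p).split(".")[1])
        assert round(p, decimals) == printed_p


class TestPrepostSummary:
    def _tables(self, bank, cohort):
        from ctfmeta import profile_cohort, score_cohort

        return score_cohort(cohort, bank), profile_cohort(cohort, bank)

    def test_null_cohort_flagged_not_crashed(self, tiny_bank):
        from conftest import correct_choice, full_phase, make_records
        from ctfmeta import build_paired_cohort

        rows = []
        for i in range(6):
            pid = f"p{i}"
            rows += full_phase(pid, "pre", 0, tiny_bank, correct_choice)
            rows += full_phase(pid, "post", 1, tiny_bank, correct_choice)
        cohort = build_paired_cohort(make_records(rows), tiny_bank)
        summary = prepost_summary(*self._tables(tiny_bank, cohort))
        assert len(summary) == 7
        assert (summary["note"] != "").all()  # every row flagged: no change
        assert summary["z"].isna().all()

    def test_improvement_cohort_directions(self, improvement_cohort):
        bank, cohort = improvement_cohort
        summary = prepost_summary(*self._tables(bank, cohort))
        for m in ("ctf_sum", "binary_pct", "ac", "ccp", "cip"):
            assert summary.loc[m, "z"] < 0, m
            assert summary.loc[m, "post_median"] > summary.loc[m, "pre_median"], m

    def test_quantiles_match_sort_oracle(self, improvement_cohort):
        bank, cohort = improvement_cohort
        scores, profiles = self._tables(bank, cohort)
        summary = prepost_summary(scores, profiles)
        pre = np.sort(scores["ctf_sum"].xs("pre", level="phase").to_numpy())
        row = summary.loc["ctf_sum"]
        assert row["pre_min"] == pre[0] and row["pre_max"] == pre[-1]
        assert row["pre_median"] == np.median(pre)
        assert row["pre_q1"] == np.percentile(pre, 25)
        assert row["pre_q3"] == np.percentile(pre, 75)

    def test_pairwise_exclusion_counts(self, improvement_cohort):
        bank, cohort = improvement_cohort
        scores, profiles = self._tables(bank, cohort)
        summary = prepost_summary(scores, profiles)
        pre = profiles["dis"].xs("pre", level="phase")
        post = profiles["dis"].xs("post", level="phase")
        n_complete = int((pre.notna() & post.notna()).sum())
        assert summary.loc["dis", "n_pairs"] == n_complete
        assert summary.loc["dis", "n_excluded"] == cohort.n - n_complete


def test_format_p_floor():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.0421) == ".042"
    assert format_p(float("nan")) == ""
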