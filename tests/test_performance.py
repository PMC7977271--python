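"""Diagnostic metrics, c-statistic, and paired comparisons of two flags."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from riskstrat import (
    ConfusionTable,
    c_statistic,
    compare_ppv_paired,
    compare_sensitivity_paired,
    confusion,
    mean_delta_difference,
    metrics,
    stratified_summary,
    summarize_across_strata,
)


def vectors_for(t: ConfusionTable):
    flag = np.r_[np.ones(t.tp), np.ones(t.fp), np.zeros(t.fn), np.zeros(t.tn)].astype(bool)
    out = np.r_[np.ones(t.tp), np.zeros(t.fp), np.ones(t.fn), np.zeros(t.tn)].astype(bool)
    return flag, out


class TestConfusionAndMetrics:
    def test_exact_counts(self):
        target = ConfusionTable(tp=30, fp=90, fn=70, tn=810)
        flag, out = vectors_for(target)
        assert confusion(flag, out) == target

    def test_perfect_and_inverted(self):
        o = np.array([True, False, True])
        t = confusion(o, o)
        assert t.fp == t.fn == 0
        t = confusion(~o, o)
        assert t.tp == t.tn == 0

    def test_hand_ratios(self):
        m = metrics(ConfusionTable(tp=30, fp=90, fn=70, tn=810))
        assert m.sensitivity == pytest.approx(0.30)
        assert m.ppv == pytest.approx(0.25)
        assert m.accuracy == pytest.approx(0.84)
        assert m.specificity == pytest.approx(810 / 900)
        assert m.npv == pytest.approx(810 / 880)

    def test_all_correct(self):
        m = metrics(ConfusionTable(10, 0, 0, 40))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_zero_denominators_are_nan_not_zero(self):
        m = metrics(ConfusionTable(tp=0, fp=0, fn=5, tn=95))
        assert math.isnan(m.ppv)
        assert m.specificity == 1.0 and m.npv == pytest.approx(0.95)

    def test_closed_form_oracle_on_random_tables(self, rng):
        """500 random tables against direct brute-force ratios."""
        checked = 0
        while checked < 500:
            tp, fp, fn, tn = map(int, rng.integers(0, 40, size=4))
            if tp + fp + fn + tn == 0:
                continue
            m = metrics(ConfusionTable(tp, fp, fn, tn))
            for got, num, den in [
                (m.sensitivity, tp, tp + fn), (m.specificity, tn, tn + fp),
                (m.ppv, tp, tp + fp), (m.npv, tn, tn + fn),
                (m.accuracy, tp + tn, tp + fp + fn + tn),
            ]:
                if den == 0:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(num / den)
            checked += 1


class TestCStatistic:
    def test_known_values(self):
        assert c_statistic([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert c_statistic([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
        assert c_statistic([1, 1, 2, 2], [0, 1, 0, 1]) == 0.5

    def test_single_class_undefined(self):
        assert math.isnan(c_statistic([1, 2, 3], [1, 1, 1]))

    def test_monotone_transform_invariance(self, rng):
        s = rng.normal(size=300)
        o = rng.random(300) < 0.3
        base = c_statistic(s, o)
        assert c_statistic(np.exp(s), o) == pytest.approx(base)
        assert c_statistic(3 * s - 7, o) == pytest.approx(base)

    def test_matches_sklearn(self, rng):
        for _ in range(20):
            s = rng.normal(size=200).round(1)  # rounding forces ties
            o = rng.random(200) < 0.4
            if o.all() or (~o).all():
                continue
            assert c_statistic(s, o) == pytest.approx(roc_auc_score(o, s))


class TestPairedSensitivity:
    def test_identical_flags(self):
        o = np.array([True] * 10 + [False] * 10)
        f = np.array([True] * 5 + [False] * 15)
        c = compare_sensitivity_paired(f, f, o)
        assert c.delta == 0.0 and c.p_value == 1.0

    def test_worked_discordant_example(self):
        """100 positives, a flags 40 / b flags 30 with 25 in common:
        discordant 15 vs 5 -> delta 0.10, exact p = 2 P(X>=15 | 20, 1/2)."""
        o = np.ones(100, dtype=bool)
        a = np.zeros(100, dtype=bool)
        b = np.zeros(100, dtype=bool)
        a[:40] = True
        b[:25] = True
        b[40:45] = True
        c = compare_sensitivity_paired(a, b, o)
        assert c.delta == pytest.approx(0.10)
        expected = 2 * sum(
            math.comb(20, k) for k in range(15, 21)
        ) / 2**20
        assert c.p_value == pytest.approx(expected, rel=1e-6)
        assert c.p_value == pytest.approx(0.0414, abs=5e-4)

    @pytest.mark.parametrize("n_a_only,n_b_only", [(0, 1), (3, 2), (10, 10),
                                                   (12, 8), (20, 0), (0, 0)])
    def test_reduces_to_exact_mcnemar(self, n_a_only, n_b_only):
        """For discordant totals <= 20 the p-value equals the exact binomial
        McNemar computation on the positive subset."""
        m = n_a_only + n_b_only
        n_pos = m + 30
        o = np.ones(n_pos, dtype=bool)
        a = np.r_[np.ones(n_a_only), np.zeros(n_b_only), np.ones(15), np.zeros(15)] > 0
        b = np.r_[np.zeros(n_a_only), np.ones(n_b_only), np.ones(15), np.zeros(15)] > 0
        c = compare_sensitivity_paired(a, b, o)
        if m == 0:
            assert c.p_value == 1.0
        else:
            assert c.p_value == pytest.approx(
                stats.binomtest(n_a_only, m, 0.5).pvalue
            )

    def test_asymptotic_branch_for_large_discordant_totals(self):
        o = np.ones(200, dtype=bool)
        a = np.r_[np.ones(40), np.zeros(20), np.zeros(140)] > 0
        b = np.r_[np.zeros(40), np.ones(20), np.zeros(140)] > 0
        c = compare_sensitivity_paired(a, b, o)
        z = (40 - 20) / math.sqrt(60)
        assert c.statistic == pytest.approx(z)
        assert c.p_value == pytest.approx(2 * stats.norm.sf(z))

    def test_no_positives_undefined(self):
        c = compare_sensitivity_paired([True], [False], [False])
        assert math.isnan(c.p_value)


def _ppv_scenario(scale: int = 1):
    """a flags 50*scale with PPV .40; b flags 40*scale with PPV .25,
    overlapping flagged sets; cohort n = 600*scale."""
    n = 600 * scale
    a = np.zeros(n, dtype=bool)
    b = np.zeros(n, dtype=bool)
    o = np.zeros(n, dtype=bool)
    a[: 50 * scale] = True                  # first 20*scale shared with b
    b[: 20 * scale] = True
    b[50 * scale: 70 * scale] = True        # b-only
    o[: 8 * scale] = True                   # true among shared
    o[20 * scale: 32 * scale] = True        # true among a-only -> PPV_a = .40
    o[50 * scale: 52 * scale] = True        # true among b-only -> PPV_b = .25
    o[100 * scale: 160 * scale] = True      # background cases
    return a, b, o


def _bootstrap_p(a, b, o, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = a.size
    log_r = np.log((a & o).sum() / a.sum()) - np.log((b & o).sum() / b.sum())
    draws = []
    for idx in rng.integers(0, n, size=(n_boot, n)):
        ai, bi, oi = a[idx], b[idx], o[idx]
        na, nb = ai.sum(), bi.sum()
        ta, tb = (ai & oi).sum(), (bi & oi).sum()
        if min(na, nb, ta, tb) == 0:
            continue
        draws.append(math.log(ta / na) - math.log(tb / nb))
    se = np.std(draws, ddof=1)
    return 2 * stats.norm.sf(abs(log_r) / se)


class TestPairedPpv:
    def test_identical_flags(self):
        o = np.array([True] * 5 + [False] * 15)
        f = np.array([True] * 8 + [False] * 12)
        c = compare_ppv_paired(f, f, o)
        assert c.delta == 0.0 and c.p_value == 1.0

    def test_relative_ppv_estimate(self):
        a, b, o = _ppv_scenario()
        c = compare_ppv_paired(a, b, o)
        assert c.estimate_a == pytest.approx(0.40)
        assert c.estimate_b == pytest.approx(0.25)
        assert c.estimate_a / c.estimate_b == pytest.approx(1.6)

    def test_delta_method_agrees_with_bootstrap(self):
        # scale 2 keeps the same PPVs/ratio while the flagged counts are
        # large enough for the log-ratio to be near-normal
        a, b, o = _ppv_scenario(scale=2)
        c = compare_ppv_paired(a, b, o)
        p_boot = _bootstrap_p(a, b, o, n_boot=10_000, seed=99)
        assert abs(c.p_value - p_boot) <= 0.02

    def test_delta_method_agrees_with_bootstrap_random_cohorts(self, rng):
        for _ in range(3):
            n = 800
            z = rng.normal(size=n)
            a = rng.random(n) < 1 / (1 + np.exp(-(z - 1.2)))
            b = rng.random(n) < 1 / (1 + np.exp(-(0.8 * z - 1.4)))
            o = rng.random(n) < 1 / (1 + np.exp(-(z - 1.5)))
            if min((a & o).sum(), (b & o).sum()) < 3:
                continue
            c = compare_ppv_paired(a, b, o)
            p_boot = _bootstrap_p(a, b, o, n_boot=4_000, seed=int(rng.integers(2**31)))
            assert abs(c.p_value - p_boot) <= 0.02

    def test_empty_flag_undefined(self):
        o = np.array([True, False])
        c = compare_ppv_paired([False, False], [True, False], o)
        assert math.isnan(c.p_value)


class TestStratifiedSummary:
    def test_identical_flags_give_zero_deltas(self, rng):
        n = 200
        f = rng.random(n) < 0.2
        outcomes = pd.DataFrame({
            "ed": rng.random(n) < 0.3, "hosp": rng.random(n) < 0.15,
            "expend": rng.random(n) < 0.1,
        })
        s = stratified_summary(f, f, outcomes, np.repeat("all", n))
        assert (s["delta"].abs() < 1e-12).all()
        assert (s["p_value"].dropna() == 1.0).all()

    def test_row_count_is_strata_by_outcomes_by_metrics(self, rng):
        n = 300
        labels = np.where(np.arange(n) < 150, "adjudication", "intuition")
        f1 = rng.random(n) < 0.2
        f2 = rng.random(n) < 0.2
        outcomes = pd.DataFrame({"ed": rng.random(n) < 0.3,
                                 "hosp": rng.random(n) < 0.2,
                                 "expend": rng.random(n) < 0.1})
        s = stratified_summary(f1, f2, outcomes, labels)
        assert len(s) == 2 * 3 * 5
        across = summarize_across_strata(s)
        assert len(across) == 3 * 5
        assert (across["practice_min"] <= across["practice_mean"]).all()


class TestMeanDeltaDifference:
    @staticmethod
    def summary_from_deltas(deltas: dict[str, list[float]]) -> pd.DataFrame:
        rows = []
        for stratum, ds in deltas.items():
            for outcome, d in zip(("ed", "hosp", "expend"), ds):
                rows.append(dict(stratum=stratum, outcome=outcome,
                                 metric="sensitivity", delta=d))
        return pd.DataFrame(rows)

    def test_published_style_delta_cells(self):
        s = self.summary_from_deltas({
            "adjudication": [0.03, -0.09, -0.09],
            "intuition": [-0.18, -0.17, -0.27],
        })
        got = mean_delta_difference(s, "sensitivity", "adjudication", "intuition")
        assert round(got, 3) == 0.157

    def test_identical_strata_and_antisymmetry(self):
        s = self.summary_from_deltas({"x": [0.1, 0.0, -0.1], "y": [0.2, -0.2, 0.05]})
        assert mean_delta_difference(s, "sensitivity", "x", "x") == 0.0
        assert mean_delta_difference(s, "sensitivity", "x", "y") == pytest.approx(
            -mean_delta_difference(s, "sensitivity", "y", "x")
        )
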