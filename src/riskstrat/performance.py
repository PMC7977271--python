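"""Diagnostic performance of high-risk flags, with paired comparisons.

A high-risk flag is treated as a screening test for a dichotomized
utilization outcome; the usual confusion-matrix metrics (sensitivity,
specificity, PPV, NPV, accuracy) and a rank-based c-statistic are computed.
Because the two flags under comparison (practice vs. algorithmic score) are
evaluated on the *same* patients, differences are tested with paired-design
statistics:

* paired sensitivities — a discordant-pair test restricted to
  outcome-positive subjects (exact binomial for small discordant totals,
  asymptotic otherwise); this is exactly McNemar's test on the positives.
* paired PPVs — a test on the log relative predictive value
  log(PPV_a / PPV_b) with an influence-function (delta-method) variance that
  accounts for the overlap of the two flagged sets.

Undefined quantities (zero denominators) propagate as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "PairedComparison",
    "confusion",
    "metrics",
    "c_statistic",
    "compare_sensitivity_paired",
    "compare_ppv_paired",
    "stratified_summary",
    "summarize_across_strata",
    "mean_delta_difference",
    "significance_stars",
]

#: Switch from the exact binomial to the asymptotic discordant-pair test.
EXACT_DISCORDANT_LIMIT = 25


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary test flag against a binary outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The five standard screening metrics; NaN marks an undefined ratio."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


@dataclass(frozen=True)
class PairedComparison:
    """Paired-design comparison of one metric for two flags on the same subjects."""

    metric: str
    estimate_a: float
    estimate_b: float
    delta: float
    statistic: float
    p_value: float
    method: str


def _as_bool(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=bool)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-d")
    return a


def confusion(flag, outcome) -> ConfusionTable:
    """Cross-tabulate test flag vs. condition; flag is the test."""
    f = _as_bool(flag, "flag")
    o = _as_bool(outcome, "outcome")
    if f.shape != o.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {o.shape}")
    return ConfusionTable(
        tp=int((f & o).sum()),
        fp=int((f & ~o).sum()),
        fn=int((~f & o).sum()),
        tn=int((~f & ~o).sum()),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(t: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
    NPV TN/(TN+FN), accuracy (TP+TN)/all."""
    if t.n == 0:
        raise ValueError("empty confusion table")
    return DiagnosticMetrics(
        sensitivity=_ratio(t.tp, t.tp + t.fn),
        specificity=_ratio(t.tn, t.tn + t.fp),
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
        accuracy=_ratio(t.tp + t.tn, t.n),
    )


def c_statistic(score, outcome) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties 1/2.

    NaN when only one outcome class is present.  Invariant under strictly
    monotone transforms of the score.
    """
    s = np.asarray(score, dtype=float)
    o = _as_bool(outcome, "outcome")
    if s.shape != o.shape:
        raise ValueError("score and outcome must be equal length")
    n_pos = int(o.sum())
    n_neg = o.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = stats.rankdata(s)
    return (ranks[o].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def compare_sensitivity_paired(flag_a, flag_b, outcome) -> PairedComparison:
    """Discordant-pair comparison of two sensitivities (paired design).

    Restricted to outcome-positive subjects; under H0 (equal true-positive
    fractions) the subjects flagged by exactly one test split Binomial(m, 1/2)
    between the two.  Exact binomial two-sided p when the discordant total m
    is below 25, else the asymptotic z-test (b - c)/sqrt(b + c).
    """
    a = _as_bool(flag_a, "flag_a")
    b = _as_bool(flag_b, "flag_b")
    o = _as_bool(outcome, "outcome")
    if not (a.shape == b.shape == o.shape):
        raise ValueError("inputs must have equal length")
    pos = o
    n_pos = int(pos.sum())
    if n_pos == 0:
        return PairedComparison(
            "sensitivity", math.nan, math.nan, math.nan, math.nan, math.nan,
            "discordant-pairs (no positives)",
        )
    sens_a = a[pos].mean()
    sens_b = b[pos].mean()
    n_a_only = int((a & ~b & pos).sum())
    n_b_only = int((~a & b & pos).sum())
    m = n_a_only + n_b_only
    if m == 0:
        return PairedComparison(
            "sensitivity", float(sens_a), float(sens_b), float(sens_a - sens_b),
            0.0, 1.0, "discordant-pairs exact",
        )
    if m < EXACT_DISCORDANT_LIMIT:
        p = stats.binomtest(n_a_only, m, 0.5).pvalue
        stat = float(n_a_only)
        method = "discordant-pairs exact"
    else:
        stat = (n_a_only - n_b_only) / math.sqrt(m)
        p = 2 * stats.norm.sf(abs(stat))
        method = "discordant-pairs asymptotic"
    return PairedComparison(
        "sensitivity", float(sens_a), float(sens_b), float(sens_a - sens_b),
        float(stat), float(min(p, 1.0)), method,
    )


def compare_ppv_paired(flag_a, flag_b, outcome) -> PairedComparison:
    """Paired comparison of two PPVs via the log relative predictive value.

    The estimate is rPPV = PPV_a / PPV_b.  The variance of log rPPV is
    obtained from the empirical influence function of
    log(mean(A*D)/mean(A)) - log(mean(B*D)/mean(B)), which automatically
    carries the covariance induced by evaluating both flags on the same
    subjects (overlapping flagged sets).  Two-sided normal p-value.
    """
    a = _as_bool(flag_a, "flag_a")
    b = _as_bool(flag_b, "flag_b")
    o = _as_bool(outcome, "outcome")
    if not (a.shape == b.shape == o.shape):
        raise ValueError("inputs must have equal length")
    n = a.size
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return PairedComparison(
            "ppv", math.nan, math.nan, math.nan, math.nan, math.nan,
            "log-rPPV delta-method (empty flag)",
        )
    ppv_a = (a & o).sum() / na
    ppv_b = (b & o).sum() / nb
    if np.array_equal(a, b):
        return PairedComparison(
            "ppv", float(ppv_a), float(ppv_b), float(ppv_a - ppv_b),
            0.0, 1.0, "log-rPPV delta-method",
        )
    if ppv_a == 0 or ppv_b == 0:
        return PairedComparison(
            "ppv", float(ppv_a), float(ppv_b), float(ppv_a - ppv_b),
            math.nan, math.nan, "log-rPPV delta-method (zero PPV)",
        )
    ua, ub = (a & o).mean(), (b & o).mean()
    ma, mb = a.mean(), b.mean()
    # influence of log(ua/ma) - log(ub/mb) w.r.t. the four sample means
    psi = (
        ((a & o) - ua) / ua
        - (a - ma) / ma
        - ((b & o) - ub) / ub
        + (b - mb) / mb
    )
    var = float((psi**2).mean()) / n
    log_r = math.log(ppv_a / ppv_b)
    if var <= 0:
        stat, p = math.inf if log_r != 0 else 0.0, 0.0 if log_r != 0 else 1.0
    else:
        stat = log_r / math.sqrt(var)
        p = 2 * stats.norm.sf(abs(stat))
    return PairedComparison(
        "ppv", float(ppv_a), float(ppv_b), float(ppv_a - ppv_b),
        float(stat), float(min(p, 1.0)), "log-rPPV delta-method",
    )


def significance_stars(p: float) -> str:
    """Table-legend stars: * p<.05, ** p<.01, *** p<.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


_PAIRED_TESTS = {
    "sensitivity": compare_sensitivity_paired,
    "ppv": compare_ppv_paired,
}


def stratified_summary(
    flags_practice,
    flags_hcc,
    outcomes: pd.DataFrame,
    stratum_labels,
    metrics_list=("sensitivity", "specificity", "ppv", "npv", "accuracy"),
) -> pd.DataFrame:
    """Per-stratum, per-outcome metric table with paired deltas and p-values.

    Returns a tidy DataFrame with one row per (stratum, outcome, metric):
    practice value, algorithmic-score value, delta (practice - hcc), paired
    p-value where a paired test exists (sensitivity, ppv), and stars.
    Strata with no patients are emitted as flagged empty rows, not dropped.
    """
    fp = _as_bool(flags_practice, "flags_practice")
    fh = _as_bool(flags_hcc, "flags_hcc")
    labels = np.asarray(stratum_labels)
    if not (fp.shape == fh.shape == labels.shape == (len(outcomes),)):
        raise ValueError("flags, labels and outcomes must align")
    rows = []
    for stratum in pd.unique(labels):
        mask = labels == stratum
        for outcome_name in outcomes.columns:
            out = outcomes[outcome_name].to_numpy(dtype=bool)[mask]
            if mask.sum() == 0:
                for metric_name in metrics_list:
                    rows.append(
                        dict(stratum=stratum, outcome=outcome_name,
                             metric=metric_name, practice=math.nan, hcc=math.nan,
                             delta=math.nan, p_value=math.nan, stars="",
                             n=0, empty=True)
                    )
                continue
            mp = metrics(confusion(fp[mask], out)).as_dict()
            mh = metrics(confusion(fh[mask], out)).as_dict()
            for metric_name in metrics_list:
                p = math.nan
                if metric_name in _PAIRED_TESTS:
                    p = _PAIRED_TESTS[metric_name](fp[mask], fh[mask], out).p_value
                rows.append(
                    dict(
                        stratum=stratum,
                        outcome=outcome_name,
                        metric=metric_name,
                        practice=mp[metric_name],
                        hcc=mh[metric_name],
                        delta=mp[metric_name] - mh[metric_name],
                        p_value=p,
                        stars=significance_stars(p),
                        n=int(mask.sum()),
                        empty=False,
                    )
                )
    return pd.DataFrame(rows)


def summarize_across_strata(summary: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean and (min, max) range of each metric across strata.

    Mirrors an "average (range)" presentation where each practice/stratum
    counts equally; pass ``weights='n'`` semantics by pre-aggregating instead
    if patient-weighted averages are wanted.
    """
    g = summary[~summary["empty"]].groupby(["outcome", "metric"])
    out = g.agg(
        practice_mean=("practice", "mean"),
        practice_min=("practice", "min"),
        practice_max=("practice", "max"),
        hcc_mean=("hcc", "mean"),
        hcc_min=("hcc", "min"),
        hcc_max=("hcc", "max"),
        delta_mean=("delta", "mean"),
    )
    return out.reset_index()


def mean_delta_difference(
    summary: pd.DataFrame, metric: str, stratum_x: str, stratum_y: str
) -> float:
    """mean over outcomes of delta(stratum_x) minus mean of delta(stratum_y)."""
    sub = summary[summary["metric"] == metric]
    dx = sub.loc[sub["stratum"] == stratum_x, "delta"]
    dy = sub.loc[sub["stratum"] == stratum_y, "delta"]
    if dx.empty or dy.empty or dx.isna().any() or dy.isna().any():
        raise ValueError("both strata must have defined deltas for every outcome")
    return float(dx.mean() - dy.mean())
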