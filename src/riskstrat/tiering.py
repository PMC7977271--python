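"""Score tiers and outcome dichotomization.

Continuous risk scores are converted into four ordered, size-matched tiers
(low / moderate / high / very_high) by empirical-quantile cut-points, mirroring
how a practice with a four-level rubric would be compared against an
algorithmic score.  Outcomes (ED visits, hospitalizations, expenditures) are
dichotomized at fixed cut-points; the expenditure cut-point can alternatively
be chosen so the flagged patients carry a target share of total spend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TIER_LEVELS",
    "TierCutpoints",
    "OutcomeThresholds",
    "fit_cutpoints",
    "assign_tiers",
    "high_risk_flag",
    "select_expenditure_cutpoint",
    "dichotomize",
]

#: Canonical ordered tier labels ("medium" in some rubrics == "moderate" here).
TIER_LEVELS = ("low", "moderate", "high", "very_high")


class DegenerateScoresError(ValueError):
    """Raised when scores cannot support four distinct tiers."""


@dataclass(frozen=True)
class TierCutpoints:
    """Three strictly increasing thresholds defining four ordered tiers.

    The tier rule is: score < c1 -> low; [c1, c2) -> moderate;
    [c2, c3) -> high; >= c3 -> very_high.  ``achieved_proportions`` are the
    tier shares realised on the scores the cut-points were fitted to (ties are
    never split, so these can deviate from the targets).
    """

    c1: float
    c2: float
    c3: float
    achieved_proportions: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.c1 < self.c2 < self.c3):
            raise ValueError(
                f"thresholds must be strictly increasing, got "
                f"({self.c1}, {self.c2}, {self.c3})"
            )


@dataclass(frozen=True)
class OutcomeThresholds:
    """Dichotomization cut-points: spend in USD, ED visit and admission counts."""

    expenditure_cut: float = 30_000.0
    ed_cut: int = 2
    hosp_cut: int = 1

    def __post_init__(self) -> None:
        if self.expenditure_cut <= 0 or self.ed_cut <= 0 or self.hosp_cut <= 0:
            raise ValueError("outcome thresholds must be positive")


def _validate_targets(target_proportions) -> np.ndarray:
    t = np.asarray(target_proportions, dtype=float)
    if t.shape != (4,):
        raise ValueError("exactly four tier proportions are required")
    if (t < 0).any() or (t > 1).any():
        raise ValueError("tier proportions must lie in [0, 1]")
    if abs(t.sum() - 1.0) > 1e-9:
        raise ValueError(f"tier proportions must sum to 1, got {t.sum()!r}")
    return t


def fit_cutpoints(scores, target_proportions=(0.25, 0.25, 0.25, 0.25)) -> TierCutpoints:
    """Choose score thresholds so tier sizes match the target proportions.

    Thresholds are empirical quantiles at the cumulative targets.  Tied scores
    always land in the same tier; when a tie block swallows a quantile, the
    affected threshold is advanced to the next distinct score value so the
    thresholds stay strictly increasing (achieved proportions then deviate
    from the targets, deterministically).
    """
    t = _validate_targets(target_proportions)
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1 or s.size < 4:
        raise DegenerateScoresError("need a 1-d vector of at least 4 scores")
    distinct = np.unique(s)
    if distinct.size < 4:
        raise DegenerateScoresError(
            f"need at least 4 distinct score values, got {distinct.size}"
        )
    cuts = list(np.quantile(s, np.cumsum(t)[:3]))
    # enforce strict increase by promoting collided thresholds upward
    for i in (1, 2):
        if cuts[i] <= cuts[i - 1]:
            above = distinct[distinct > cuts[i - 1]]
            if above.size == 0:
                raise DegenerateScoresError("ties leave no room for four tiers")
            cuts[i] = float(above[0])
    tiers = assign_tiers(s, TierCutpoints(*cuts))
    achieved = tuple(
        float((tiers == lev).sum()) / s.size for lev in TIER_LEVELS
    )
    return TierCutpoints(cuts[0], cuts[1], cuts[2], achieved)


def assign_tiers(scores, cutpoints: TierCutpoints) -> pd.Categorical:
    """Apply the tier rule; order and length of the input are preserved."""
    s = np.asarray(scores, dtype=float)
    idx = (
        (s >= cutpoints.c1).astype(int)
        + (s >= cutpoints.c2)
        + (s >= cutpoints.c3)
    )
    return pd.Categorical.from_codes(idx, categories=list(TIER_LEVELS), ordered=True)


def high_risk_flag(tiers, rule: str = "very_high") -> np.ndarray:
    """Boolean flag for the top tier (or, optionally, the top two tiers).

    ``rule='very_high'`` flags only the single highest tier — the default
    reading of a practice's "highest tier".  ``rule='high_or_very_high'``
    flags the union of the top two.
    """
    t = np.asarray(tiers)
    if rule == "very_high":
        return t == "very_high"
    if rule == "high_or_very_high":
        return (t == "very_high") | (t == "high")
    raise ValueError(f"unknown high-risk rule {rule!r}")


def select_expenditure_cutpoint(expenditures, target_share: float) -> float:
    """Largest threshold t such that patients with spend >= t carry the share.

    Equivalently: sort descending and take the smallest prefix whose summed
    expenditure reaches ``target_share`` of the total; the threshold is the
    last expenditure in that prefix.
    """
    if not 0 < target_share < 1:
        raise ValueError("target_share must lie strictly between 0 and 1")
    x = np.sort(np.asarray(expenditures, dtype=float))[::-1]
    total = x.sum()
    if total <= 0:
        raise ValueError("total expenditure must be positive")
    k = int(np.searchsorted(np.cumsum(x), target_share * total)) + 1
    k = min(k, x.size)
    return float(x[k - 1])


def dichotomize(
    patients: pd.DataFrame,
    thresholds: OutcomeThresholds = OutcomeThresholds(),
    window: str = "follow",
) -> pd.DataFrame:
    """Binary high-utilization outcomes for one observation window.

    Returns a DataFrame with boolean columns ``expend``, ``ed``, ``hosp``:
    spend >= expenditure_cut, ED count >= ed_cut, admissions >= hosp_cut
    (all cuts inclusive).
    """
    if window not in {"prior", "follow"}:
        raise ValueError(f"window must be 'prior' or 'follow', got {window!r}")
    cols = {k: f"{window}_{k}" for k in ("expend", "ed", "hosp")}
    missing = [c for c in cols.values() if c not in patients.columns]
    if missing:
        raise KeyError(f"missing outcome column(s): {missing}")
    return pd.DataFrame(
        {
            "expend": patients[cols["expend"]] >= thresholds.expenditure_cut,
            "ed": patients[cols["ed"]] >= thresholds.ed_cut,
            "hosp": patients[cols["hosp"]] >= thresholds.hosp_cut,
        },
        index=patients.index,
    )
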