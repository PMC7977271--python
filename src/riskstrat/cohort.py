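"""Analytic cohort construction.

Patients enter the agreement analysis if they were seen before risk
stratification, carry a valid practice tier, and neither died nor left the
practice during the two-year observation window.  The outcome analysis is
further restricted to payers with reliable utilization feeds (Medicare and
dual-eligible patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tiering import TIER_LEVELS

__all__ = ["CohortFilterReport", "apply_cohort_filters"]

RELIABLE_PAYERS = frozenset({"medicare", "dual"})

REQUIRED_COLUMNS = ("seen_prior", "practice_tier", "deceased_or_left")


@dataclass(frozen=True)
class CohortFilterReport:
    """Counts after each retention filter, in application order."""

    n_input: int
    n_after_seen_prior: int
    n_after_valid_score: int
    n_after_not_deceased_or_left: int
    n_with_outcomes: int | None = None
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = [self.n_input, self.n_after_seen_prior, self.n_after_valid_score,
               self.n_after_not_deceased_or_left]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError("filter counts must be nonincreasing")
        final = (self.n_with_outcomes if self.n_with_outcomes is not None
                 else self.n_after_not_deceased_or_left)
        if sum(self.exclusions.values()) != self.n_input - final:
            raise ValueError("exclusions must sum to n_input - final n")

    def as_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_after_seen_prior": self.n_after_seen_prior,
            "n_after_valid_score": self.n_after_valid_score,
            "n_after_not_deceased_or_left": self.n_after_not_deceased_or_left,
            "exclusions": dict(self.exclusions),
        }
        if self.n_with_outcomes is not None:
            d["n_with_outcomes"] = self.n_with_outcomes
        return d


def apply_cohort_filters(
    patients: pd.DataFrame, outcome_subset: bool = False
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Apply the retention filters in their stated order.

    With ``outcome_subset=True`` the cohort is additionally restricted to
    Medicare / dual-eligible patients (the payers with reliable outcome
    feeds) and the report carries ``n_with_outcomes``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in patients.columns]
    if outcome_subset and "payer_class" not in patients.columns:
        missing.append("payer_class")
    if missing:
        raise KeyError(f"missing required column(s): {missing}")

    n0 = len(patients)
    step1 = patients[patients["seen_prior"].astype(bool)]
    valid_tier = step1["practice_tier"].isin(TIER_LEVELS) & step1["practice_tier"].notna()
    step2 = step1[valid_tier]
    step3 = step2[~step2["deceased_or_left"].astype(bool)]
    exclusions = {
        "not_seen_prior": n0 - len(step1),
        "invalid_practice_tier": len(step1) - len(step2),
        "deceased_or_left": len(step2) - len(step3),
    }
    n_with_outcomes = None
    final = step3
    if outcome_subset:
        final = step3[step3["payer_class"].isin(RELIABLE_PAYERS)]
        exclusions["unreliable_outcomes_payer"] = len(step3) - len(final)
        n_with_outcomes = len(final)
    report = CohortFilterReport(
        n_input=n0,
        n_after_seen_prior=len(step1),
        n_after_valid_score=len(step2),
        n_after_not_deceased_or_left=len(step3),
        n_with_outcomes=n_with_outcomes,
        exclusions=exclusions,
    )
    return final.copy(), report
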