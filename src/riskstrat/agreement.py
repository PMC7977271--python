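"""Concordance between two classifications of the same patients.

Two high-risk flags (e.g. a practice's top tier vs. the top tier of an
algorithmic score) are compared by cross-tabulation, overall percent
agreement, Cohen's kappa, and the Landis-Koch qualitative band.  A 4x4 tier
cross-tabulation is also provided so full tier tables can be inspected, but
kappa is computed on the binary high/not-high collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceTable",
    "AgreementResult",
    "concordance",
    "percent_agreement",
    "both_over_either",
    "cohens_kappa",
    "kappa_band",
    "tier_crosstab",
    "agreement_result",
]


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 counts of two binary flags on the same subjects."""

    n_both_high: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    def __post_init__(self) -> None:
        if min(self.n_both_high, self.n_a_only, self.n_b_only, self.n_neither) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_both_high + self.n_a_only + self.n_b_only + self.n_neither

    @property
    def n_either(self) -> int:
        return self.n_both_high + self.n_a_only + self.n_b_only


@dataclass(frozen=True)
class AgreementResult:
    """Summary of one binary agreement comparison."""

    table: ConcordanceTable
    percent_agreement: float
    kappa: float
    band: str
    either_high: int
    both_over_either: float


def concordance(flag_a, flag_b) -> ConcordanceTable:
    """Cross-tabulate two equal-length boolean vectors."""
    a = np.asarray(flag_a, dtype=bool)
    b = np.asarray(flag_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"flag vectors must be equal-length 1-d, got {a.shape} vs {b.shape}")
    return ConcordanceTable(
        n_both_high=int((a & b).sum()),
        n_a_only=int((a & ~b).sum()),
        n_b_only=int((~a & b).sum()),
        n_neither=int((~a & ~b).sum()),
    )


def percent_agreement(t: ConcordanceTable) -> float:
    """(both-high + neither) / total."""
    if t.n_total == 0:
        raise ValueError("empty concordance table")
    return (t.n_both_high + t.n_neither) / t.n_total


def both_over_either(t: ConcordanceTable) -> float:
    """Share of patients flagged by either classifier that both flagged.

    Returns NaN when nobody is flagged by either (undefined).
    """
    if t.n_either == 0:
        return math.nan
    return t.n_both_high / t.n_either


def cohens_kappa(t: ConcordanceTable) -> float:
    """Chance-corrected agreement from the 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e) with p_e the product-of-marginals
    expectation.  When both marginals are degenerate (p_e = 1): 1.0 if
    observed agreement is also perfect, else NaN (undefined).
    """
    n = t.n_total
    if n == 0:
        raise ValueError("empty concordance table")
    p_o = percent_agreement(t)
    pa1 = (t.n_both_high + t.n_a_only) / n
    pb1 = (t.n_both_high + t.n_b_only) / n
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else math.nan
    return (p_o - p_e) / (1 - p_e)


def kappa_band(kappa: float) -> str:
    """Landis-Koch qualitative band for a kappa value (right-closed bins)."""
    if math.isnan(kappa):
        return "undefined"
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "poor"
    if kappa <= 0.2:
        return "slight"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "substantial"
    return "almost perfect"


def tier_crosstab(tiers_a, tiers_b) -> pd.DataFrame:
    """Full 4x4 cross-tabulation of two tier assignments."""
    a = pd.Series(pd.Categorical(tiers_a), name="a")
    b = pd.Series(pd.Categorical(tiers_b), name="b")
    return pd.crosstab(a, b, dropna=False)


def agreement_result(flag_a, flag_b) -> AgreementResult:
    """One-call binary agreement summary (table, agreement, kappa, band)."""
    t = concordance(flag_a, flag_b)
    k = cohens_kappa(t)
    return AgreementResult(
        table=t,
        percent_agreement=percent_agreement(t),
        kappa=k,
        band=kappa_band(k),
        either_high=t.n_either,
        both_over_either=both_over_either(t),
    )
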