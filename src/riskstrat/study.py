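"""The study object: end-to-end evaluation of a risk-stratified panel.

:class:`RiskStratificationStudy` is the model-like entry point: construct it
from patient / diagnosis tables (or a generator config), call :meth:`fit`,
and receive a :class:`StudyResults` carrying cohort accounting, tier
cut-points, agreement between the practice's tiers and the algorithmic
score's tiers, diagnostic performance of both high-risk flags against the
dichotomized utilization outcomes, paired comparisons, and optional
stratified summaries.  ``StudyResults.summary()`` renders the familiar
tables; ``StudyResults.save()`` writes them as CSV/JSON with a manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementResult, agreement_result, tier_crosstab
from .cohort import CohortFilterReport, apply_cohort_filters
from .hcc import HccModel, score_population, toy_model
from .performance import (
    PairedComparison,
    c_statistic,
    compare_ppv_paired,
    compare_sensitivity_paired,
    confusion,
    metrics,
    significance_stars,
    stratified_summary,
)
from .synthetic import GeneratorConfig, generate_population
from .tiering import (
    TIER_LEVELS,
    OutcomeThresholds,
    TierCutpoints,
    assign_tiers,
    dichotomize,
    fit_cutpoints,
    high_risk_flag,
)

__all__ = ["RiskStratificationStudy", "StudyResults"]

OUTCOME_LABELS = {"ed": "ED visits >= cut", "hosp": "Hospitalization >= cut",
                  "expend": "Expenditures >= cut"}


@dataclass
class StudyResults:
    """Everything :meth:`RiskStratificationStudy.fit` computes."""

    cohort_report: CohortFilterReport
    outcome_cohort_report: CohortFilterReport
    cutpoints: TierCutpoints
    agreement_full: AgreementResult
    agreement_outcome: AgreementResult
    tier_table_full: pd.DataFrame
    performance_table: pd.DataFrame
    paired_comparisons: list[PairedComparison]
    c_statistics: dict[str, dict[str, float]]
    stratified: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        a, ao = self.agreement_full, self.agreement_outcome
        lines = [
            "Risk stratification study",
            "=" * 60,
            f"Cohort: {self.cohort_report.n_input} scored, "
            f"{self.cohort_report.n_after_not_deceased_or_left} retained, "
            f"{self.outcome_cohort_report.n_with_outcomes} with reliable outcomes",
            "",
            "High-risk agreement (practice vs algorithmic score)",
            f"  full cohort (n={a.table.n_total}): both high {a.table.n_both_high}, "
            f"either {a.either_high}, both/either "
            f"{100 * a.both_over_either:.1f}%, agreement "
            f"{100 * a.percent_agreement:.0f}%, kappa {a.kappa:.2f} ({a.band})",
            f"  outcome cohort (n={ao.table.n_total}): both high {ao.table.n_both_high}, "
            f"agreement {100 * ao.percent_agreement:.0f}%, "
            f"kappa {ao.kappa:.2f} ({ao.band})",
            "",
            "Diagnostic performance of the high-risk flags "
            "(outcome cohort, follow year)",
        ]
        tbl = self.performance_table.pivot_table(
            index="outcome", columns="metric", values=["practice", "hcc"]
        )
        lines.append(tbl.round(2).to_string())
        lines.append("")
        lines.append("Paired comparisons (practice - algorithmic score)")
        for c in self.paired_comparisons:
            lines.append(
                f"  {c.metric:>20}: delta {c.delta:+.3f}, p = {c.p_value:.3f} "
                f"{significance_stars(c.p_value)}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.performance_table.to_csv(out / "performance.csv", index=False)
        self.tier_table_full.to_csv(out / "tier_crosstab.csv")
        if self.stratified is not None:
            self.stratified.to_csv(out / "stratified.csv", index=False)
        rows = []
        for label, res in [("full_cohort", self.agreement_full),
                           ("outcome_cohort", self.agreement_outcome)]:
            t = res.table
            rows.append(dict(comparison=label, n=t.n_total, both_high=t.n_both_high,
                             a_only=t.n_a_only, b_only=t.n_b_only, neither=t.n_neither,
                             pct_agreement=res.percent_agreement, kappa=res.kappa,
                             band=res.band))
        pd.DataFrame(rows).to_csv(out / "agreement.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


class RiskStratificationStudy:
    """Compare practice-assigned risk tiers with an HCC-style score.

    Parameters
    ----------
    patients
        Wide patient table (one row per patient) with demographics, practice
        tier, retention flags, payer class and prior/follow-year utilization.
    diagnoses
        Long table (patient_id, code).
    hcc_model
        Scoring model; defaults to the shipped toy model.
    tier_proportions
        Targets for the algorithmic tier sizes. ``None`` (default) matches
        the practice's achieved tier proportions, which is how size-matched
        cut-points are constructed when comparing against an existing rubric.
    outcome_thresholds
        Dichotomization cut-points (default $30,000 / 2 ED visits / 1
        hospitalization).
    select_expenditure_share
        If set (e.g. ``2/3``), the expenditure cut-point is instead chosen on
        the prior-year spend of the outcome cohort so the flagged patients
        carry that share of total spend.
    high_risk_rule
        ``'very_high'`` (default) or ``'high_or_very_high'``.
    outcome_window
        ``'follow'`` (default; prediction of future utilization) or
        ``'prior'``.
    strata
        Optional column name in ``patients`` (or array-like) partitioning the
        outcome cohort for stratified summaries.
    """

    def __init__(
        self,
        patients: pd.DataFrame,
        diagnoses: pd.DataFrame,
        hcc_model: HccModel | None = None,
        *,
        tier_proportions=None,
        outcome_thresholds: OutcomeThresholds = OutcomeThresholds(),
        select_expenditure_share: float | None = None,
        high_risk_rule: str = "very_high",
        outcome_window: str = "follow",
        strata=None,
        seed: int = 0,
    ) -> None:
        self.patients = patients
        self.diagnoses = diagnoses
        self.hcc_model = hcc_model if hcc_model is not None else toy_model()
        self.tier_proportions = tier_proportions
        self.outcome_thresholds = outcome_thresholds
        self.select_expenditure_share = select_expenditure_share
        self.high_risk_rule = high_risk_rule
        self.outcome_window = outcome_window
        self.strata = strata
        self.seed = seed

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_synthetic(cls, config: GeneratorConfig, **kwargs) -> "RiskStratificationStudy":
        pop = generate_population(config)
        kwargs.setdefault("seed", config.seed)
        return cls(pop.patients, pop.diagnoses, **kwargs)

    @classmethod
    def from_csv(
        cls, patients_csv, diagnoses_csv, model_dir=None, **kwargs
    ) -> "RiskStratificationStudy":
        from .hcc import load_model

        patients = pd.read_csv(patients_csv)
        diagnoses = pd.read_csv(diagnoses_csv, dtype=str)
        model = None
        if model_dir is not None:
            d = Path(model_dir)
            model = load_model(d / "map.csv", d / "hierarchy.csv", d / "coef.csv")
        return cls(patients, diagnoses, hcc_model=model, **kwargs)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> StudyResults:
        cohort, report_full = apply_cohort_filters(self.patients)
        outcome_cohort, report_outcome = apply_cohort_filters(
            self.patients, outcome_subset=True
        )

        scores = score_population(cohort, self.diagnoses, self.hcc_model)
        targets = self.tier_proportions
        if targets is None:
            counts = cohort["practice_tier"].value_counts()
            targets = tuple(counts.get(lev, 0) / len(cohort) for lev in TIER_LEVELS)
        cutpoints = fit_cutpoints(scores.to_numpy(), targets)
        hcc_tiers = assign_tiers(scores.to_numpy(), cutpoints)

        flag_practice = high_risk_flag(cohort["practice_tier"], self.high_risk_rule)
        flag_hcc = high_risk_flag(hcc_tiers, self.high_risk_rule)
        agr_full = agreement_result(flag_practice, flag_hcc)
        tier_table = tier_crosstab(cohort["practice_tier"], hcc_tiers)

        oc = outcome_cohort
        oc_scores = score_population(oc, self.diagnoses, self.hcc_model)
        oc_hcc_tiers = assign_tiers(oc_scores.to_numpy(), cutpoints)
        oc_flag_practice = high_risk_flag(oc["practice_tier"], self.high_risk_rule)
        oc_flag_hcc = high_risk_flag(oc_hcc_tiers, self.high_risk_rule)
        agr_outcome = agreement_result(oc_flag_practice, oc_flag_hcc)

        thresholds = self.outcome_thresholds
        if self.select_expenditure_share is not None:
            from .tiering import select_expenditure_cutpoint

            cut = select_expenditure_cutpoint(
                oc["prior_expend"], self.select_expenditure_share
            )
            thresholds = OutcomeThresholds(
                expenditure_cut=cut,
                ed_cut=thresholds.ed_cut,
                hosp_cut=thresholds.hosp_cut,
            )
        outcomes = dichotomize(oc, thresholds, self.outcome_window)

        perf_rows = []
        paired: list[PairedComparison] = []
        c_stats: dict[str, dict[str, float]] = {}
        practice_ordinal = pd.Categorical(
            oc["practice_tier"], categories=list(TIER_LEVELS), ordered=True
        ).codes.astype(float)
        for outcome_name in outcomes.columns:
            out_vec = outcomes[outcome_name].to_numpy(dtype=bool)
            mp = metrics(confusion(oc_flag_practice, out_vec))
            mh = metrics(confusion(oc_flag_hcc, out_vec))
            for metric_name, vp, vh in zip(
                mp.as_dict(), mp.as_dict().values(), mh.as_dict().values()
            ):
                perf_rows.append(
                    dict(outcome=outcome_name, metric=metric_name,
                         practice=vp, hcc=vh, delta=vp - vh)
                )
            for cmp_fn in (compare_sensitivity_paired, compare_ppv_paired):
                c = cmp_fn(oc_flag_practice, oc_flag_hcc, out_vec)
                paired.append(
                    PairedComparison(
                        metric=f"{outcome_name}:{c.metric}",
                        estimate_a=c.estimate_a, estimate_b=c.estimate_b,
                        delta=c.delta, statistic=c.statistic,
                        p_value=c.p_value, method=c.method,
                    )
                )
            c_stats[outcome_name] = {
                "practice": c_statistic(practice_ordinal, out_vec),
                "hcc": c_statistic(oc_scores.to_numpy(), out_vec),
            }

        stratified = None
        if self.strata is not None:
            labels = (
                oc[self.strata].to_numpy()
                if isinstance(self.strata, str)
                else np.asarray(self.strata)
            )
            stratified = stratified_summary(
                oc_flag_practice, oc_flag_hcc, outcomes, labels
            )

        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "seed": self.seed,
            "tier_targets": list(targets),
            "tier_cutpoints": [cutpoints.c1, cutpoints.c2, cutpoints.c3],
            "achieved_tier_proportions": list(cutpoints.achieved_proportions),
            "outcome_thresholds": {
                "expenditure_cut": thresholds.expenditure_cut,
                "ed_cut": thresholds.ed_cut,
                "hosp_cut": thresholds.hosp_cut,
            },
            "high_risk_rule": self.high_risk_rule,
            "outcome_window": self.outcome_window,
            "cohort": report_full.as_dict(),
            "outcome_cohort": report_outcome.as_dict(),
        }

        return StudyResults(
            cohort_report=report_full,
            outcome_cohort_report=report_outcome,
            cutpoints=cutpoints,
            agreement_full=agr_full,
            agreement_outcome=agr_outcome,
            tier_table_full=tier_table,
            performance_table=pd.DataFrame(perf_rows),
            paired_comparisons=paired,
            c_statistics=c_stats,
            stratified=stratified,
            manifest=manifest,
        )
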