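"""Synthetic primary-care panels for exercising the evaluation pipeline.

Real risk-stratified panels with linked utilization outcomes are protected
data, so this module generates populations with the structure the analysis
assumes: a positive latent severity ``lambda`` (log-normal) drives chronic
condition presence (logistic in ``log lambda``), overdispersed ED and
hospitalization counts (negative binomial), and heavy-tailed expenditures
(log-normal base plus per-event costs), for both a prior and a follow year
sharing each person's rates.  Practice risk tiers are simulated under three
scoring modes — clinical intuition (noisy view of the latent severity), pure
algorithm (quantile tiers of the toy HCC-style score), and adjudication
(algorithm tier, stochastically corrected toward the latent tier).

The shipped defaults are calibrated so that, at n = 40,000, the population
margins match a typical risk-stratified Medicare-heavy panel: ~57% female,
mean age ~61, diabetes/neoplasm ~11%, heart disease ~10%, psychiatric ~8%,
lung ~5%, ED>=1 ~30%, ED>=2 ~12%, hospitalization>=1 ~14%, spend>=$30k ~9%,
median toy score ~0.60 with IQR ~(0.28, 0.80), and the top decile of
patients carrying about two-thirds of total spend.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .hcc import HccModel, score_population, toy_model
from .tiering import TIER_LEVELS, assign_tiers, fit_cutpoints

__all__ = [
    "ConditionDef",
    "CountModel",
    "ExpenditureModel",
    "GeneratorConfig",
    "SyntheticPopulation",
    "default_config",
    "generate_population",
    "simulate_practice_tiers",
    "latent_quantile_tiers",
    "top_share",
    "gini",
]

PRACTICE_MODES = ("intuition", "algorithm", "adjudication")


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class ConditionDef:
    """One chronic condition: marginal prevalence, severity loading, codes.

    ``risk_loading`` is the logistic slope on the standardized log latent
    severity; the intercept is solved at generation time so the marginal
    prevalence is honoured for any loading.
    """

    name: str
    prevalence: float
    risk_loading: float
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ConfigurationError(
                f"prevalence for {self.name!r} must lie in (0, 1)"
            )
        if self.risk_loading < 0:
            raise ConfigurationError(f"risk loading for {self.name!r} must be >= 0")
        if not self.codes:
            raise ConfigurationError(f"condition {self.name!r} needs >= 1 code")


@dataclass(frozen=True)
class CountModel:
    """Negative-binomial utilization counts: mean = baseline * exp(elasticity * z).

    ``z`` is the standardized log latent severity; ``dispersion`` is the NB
    size parameter (smaller = more overdispersed).
    """

    baseline: float
    elasticity: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.dispersion <= 0 or self.elasticity < 0:
            raise ConfigurationError("count model parameters out of range")


@dataclass(frozen=True)
class ExpenditureModel:
    """Annual spend: exp(log_base + elasticity*z + sigma*eps) + per-event costs."""

    log_base: float
    elasticity: float
    sigma: float
    ed_unit_cost: float
    hosp_unit_cost: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or min(self.ed_unit_cost, self.hosp_unit_cost) < 0:
            raise ConfigurationError("expenditure model parameters out of range")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic practice panel."""

    n_patients: int
    seed: int = 0
    female_fraction: float = 0.57
    age_mean: float = 60.8
    age_sd: float = 19.0
    age_range: tuple[float, float] = (18.0, 98.0)
    condition_defs: tuple[ConditionDef, ...] = ()
    latent_log_mean: float = 0.0
    latent_log_sd: float = 1.0
    ed_model: CountModel = field(default_factory=lambda: CountModel(0.365, 0.95, 1.02))
    hosp_model: CountModel = field(default_factory=lambda: CountModel(0.127, 1.05, 0.55))
    expenditure_model: ExpenditureModel = field(
        default_factory=lambda: ExpenditureModel(7.35, 1.35, 1.38, 1_000.0, 12_000.0)
    )
    practice_mode: str = "adjudication"
    intuition_noise: float = 2.0
    adjudication_prob: float = 0.5
    tier_proportions: tuple[float, float, float, float] = (0.55, 0.25, 0.10, 0.10)
    seen_prior_rate: float = 0.96
    attrition_rate: float = 0.04
    payer_probs: tuple[float, float, float] = (0.088, 0.012, 0.90)  # medicare, dual, other
    unmapped_code_rate: float = 0.05
    rs_year: int = 2015

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name in ("female_fraction", "adjudication_prob", "seen_prior_rate",
                     "attrition_rate", "unmapped_code_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.intuition_noise < 0:
            raise ConfigurationError("intuition_noise must be >= 0")
        if self.latent_log_sd <= 0:
            raise ConfigurationError("latent_log_sd must be positive")
        t = np.asarray(self.tier_proportions, dtype=float)
        if t.shape != (4,) or (t < 0).any() or abs(t.sum() - 1) > 1e-9:
            raise ConfigurationError("tier_proportions must be 4 proportions summing to 1")
        p = np.asarray(self.payer_probs, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ConfigurationError("payer_probs must be 3 proportions summing to 1")
        if self.practice_mode not in PRACTICE_MODES:
            raise ConfigurationError(
                f"practice_mode must be one of {PRACTICE_MODES}, got {self.practice_mode!r}"
            )

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


#: Default condition roster; prevalences mirror a Medicare-heavy panel and
#: the code vocabulary is the toy one shipped with the scoring model.
DEFAULT_CONDITIONS: tuple[ConditionDef, ...] = (
    ConditionDef("diabetes", 0.11, 0.80, ("DM2", "DM1")),
    ConditionDef("diabetes_complicated", 0.03, 1.40, ("DM2C", "DMREN")),
    ConditionDef("neoplasm", 0.11, 0.50, ("NEO_BR", "NEO_PR", "NEO_CO")),
    ConditionDef("metastatic_cancer", 0.02, 1.20, ("MET1",)),
    ConditionDef("heart_disease", 0.10, 0.90, ("CAD", "AFIB")),
    ConditionDef("heart_failure", 0.04, 1.60, ("CHF",)),
    ConditionDef("psychiatric", 0.08, 0.70, ("DEP", "ANX", "SCZ")),
    ConditionDef("lung_disease", 0.05, 0.90, ("COPD", "ASTHMA")),
    ConditionDef("renal_disease", 0.04, 1.30, ("CKD3", "CKD4")),
)


def default_config(n_patients: int = 40_000, seed: int = 20210318) -> GeneratorConfig:
    """The shipped calibration configuration (see module docstring)."""
    return GeneratorConfig(
        n_patients=n_patients, seed=seed, condition_defs=DEFAULT_CONDITIONS
    )


@dataclass(frozen=True)
class SyntheticPopulation:
    """A generated panel: wide patient table plus long diagnosis table."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    config: GeneratorConfig

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(out / "patients.csv", index=False)
        self.diagnoses.to_csv(out / "diagnoses.csv", index=False)


def solve_logit_intercept(prevalence: float, loading: float) -> float:
    """Intercept a with E_z[expit(a + loading*z)] = prevalence, z ~ N(0, 1).

    Solved by Gauss-Hermite quadrature + brentq; deterministic.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(81)
    zs = np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)

    def f(a: float) -> float:
        return float(w @ special.expit(a + loading * zs)) - prevalence

    return optimize.brentq(f, -40.0, 40.0, xtol=1e-12)


def _truncnorm_params(cfg: GeneratorConfig):
    """Truncated-normal age parameters; the location is solved so the
    *realized* (post-truncation) mean equals ``cfg.age_mean``."""
    lo, hi = cfg.age_range
    sd = cfg.age_sd

    def trunc_mean(loc: float) -> float:
        return float(
            stats.truncnorm.mean((lo - loc) / sd, (hi - loc) / sd, loc=loc, scale=sd)
        )

    loc = optimize.brentq(
        lambda m: trunc_mean(m) - cfg.age_mean, lo + 1e-6, hi - 1e-6, xtol=1e-8
    )
    return (lo - loc) / sd, (hi - loc) / sd, loc, sd


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def latent_quantile_tiers(latent_risk, tier_proportions) -> pd.Categorical:
    """Quantile tiers of the latent severity itself (the oracle tiering)."""
    cuts = fit_cutpoints(np.log(np.asarray(latent_risk, dtype=float)), tier_proportions)
    return assign_tiers(np.log(np.asarray(latent_risk, dtype=float)), cuts)


def generate_population(
    config: GeneratorConfig, hcc: HccModel | None = None
) -> SyntheticPopulation:
    """Generate a full panel; identical config + seed gives identical output.

    The practice tier column is filled by :func:`simulate_practice_tiers`
    under ``config.practice_mode``.
    """
    if not config.condition_defs:
        config = config.with_(condition_defs=DEFAULT_CONDITIONS)
    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    z = rng.standard_normal(n)
    lam = np.exp(config.latent_log_mean + config.latent_log_sd * z)
    female = rng.random(n) < config.female_fraction

    a, b, loc, scale = _truncnorm_params(config)
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)

    # conditions: logistic in z, intercept solved for the marginal prevalence
    code_lists: list[list[str]] = [[] for _ in range(n)]
    cond_flags = {}
    for cond in config.condition_defs:
        intercept = solve_logit_intercept(cond.prevalence, cond.risk_loading)
        present = rng.random(n) < special.expit(intercept + cond.risk_loading * z)
        cond_flags[cond.name] = present
        k = len(cond.codes)
        first = rng.integers(0, k, size=n)
        extra = rng.random(n) < 0.25
        second = (first + 1 + rng.integers(0, max(k - 1, 1), size=n)) % k
        for i in np.flatnonzero(present):
            code_lists[i].append(cond.codes[first[i]])
            if k > 1 and extra[i]:
                code_lists[i].append(cond.codes[second[i]])

    junk = rng.random(n) < config.unmapped_code_rate
    junk_code = rng.integers(1, 4, size=n)
    for i in np.flatnonzero(junk):
        code_lists[i].append(f"UNK{junk_code[i]}")

    payer = rng.choice(
        np.array(["medicare", "dual", "other"]), size=n, p=np.asarray(config.payer_probs)
    )
    seen_prior = rng.random(n) < config.seen_prior_rate
    deceased_or_left = rng.random(n) < config.attrition_rate
    rs_day = rng.integers(0, 365, size=n)
    base_date = dt.date(config.rs_year, 1, 1)
    rs_date = [(base_date + dt.timedelta(days=int(d))).isoformat() for d in rs_day]

    # utilization: prior and follow year drawn from the same person-level rates
    mu_ed = config.ed_model.baseline * np.exp(config.ed_model.elasticity * z)
    mu_hosp = config.hosp_model.baseline * np.exp(config.hosp_model.elasticity * z)
    prior_ed = _nb_draw(rng, mu_ed, config.ed_model.dispersion)
    follow_ed = _nb_draw(rng, mu_ed, config.ed_model.dispersion)
    prior_hosp = _nb_draw(rng, mu_hosp, config.hosp_model.dispersion)
    follow_hosp = _nb_draw(rng, mu_hosp, config.hosp_model.dispersion)

    em = config.expenditure_model

    def spend(ed_counts, hosp_counts):
        base = np.exp(em.log_base + em.elasticity * z + em.sigma * rng.standard_normal(n))
        total = base + em.ed_unit_cost * ed_counts + em.hosp_unit_cost * hosp_counts
        return np.round(total, 2)

    prior_expend = spend(prior_ed, prior_hosp)
    follow_expend = spend(follow_ed, follow_hosp)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": np.where(female, "F", "M"),
            "diagnosis_codes": [" ".join(c) for c in code_lists],
            "latent_risk": lam,
            "practice_tier": pd.Categorical(
                [None] * n, categories=list(TIER_LEVELS), ordered=True
            ),
            "rs_date": rs_date,
            "payer_class": payer,
            "seen_prior": seen_prior,
            "deceased_or_left": deceased_or_left,
            "prior_ed": prior_ed.astype(int),
            "follow_ed": follow_ed.astype(int),
            "prior_hosp": prior_hosp.astype(int),
            "follow_hosp": follow_hosp.astype(int),
            "prior_expend": prior_expend,
            "follow_expend": follow_expend,
        }
    )
    for name, flags in cond_flags.items():
        patients[f"has_{name}"] = flags

    diagnoses = (
        patients[["patient_id", "diagnosis_codes"]]
        .assign(code=lambda d: d["diagnosis_codes"].str.split())
        .explode("code")
        .dropna(subset=["code"])[["patient_id", "code"]]
        .reset_index(drop=True)
    )

    patients = simulate_practice_tiers(patients, config, hcc=hcc)
    return SyntheticPopulation(patients=patients, diagnoses=diagnoses, config=config)


def simulate_practice_tiers(
    patients: pd.DataFrame,
    config: GeneratorConfig,
    hcc: HccModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fill ``practice_tier`` according to the configured scoring mode.

    * ``intuition`` — quantile tier of log latent severity plus Normal noise
      with sd ``intuition_noise`` (the practice sees true risk imperfectly).
    * ``algorithm`` — quantile tier of the HCC-style score computed from the
      *observed* diagnosis codes only.
    * ``adjudication`` — start from the algorithm tier; with probability
      ``adjudication_prob`` a reviewer replaces it by the latent-risk tier.

    Randomness is seeded from ``config.seed`` (offset) unless ``seed`` is
    given, so adjudication at probability 0 reproduces the algorithm tiers
    exactly.
    """
    if config.practice_mode not in PRACTICE_MODES:
        raise ConfigurationError(f"unknown practice mode {config.practice_mode!r}")
    if "latent_risk" not in patients.columns:
        raise ValueError("latent_risk column required to simulate practice tiers")
    rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
    out = patients.copy()
    n = len(out)
    log_lam = np.log(out["latent_risk"].to_numpy(dtype=float))

    if config.practice_mode == "intuition":
        noisy = log_lam + rng.standard_normal(n) * config.intuition_noise
        cuts = fit_cutpoints(noisy, config.tier_proportions)
        out["practice_tier"] = assign_tiers(noisy, cuts)
        return out

    # algorithm and adjudication both need the algorithmic score
    model = hcc if hcc is not None else toy_model()
    diagnoses = (
        out[["patient_id", "diagnosis_codes"]]
        .assign(code=lambda d: d["diagnosis_codes"].str.split())
        .explode("code")
        .dropna(subset=["code"])[["patient_id", "code"]]
    )
    scores = score_population(out, diagnoses, model)
    cuts = fit_cutpoints(scores.to_numpy(), config.tier_proportions)
    algo = assign_tiers(scores.to_numpy(), cuts)
    if config.practice_mode == "algorithm":
        out["practice_tier"] = algo
        return out

    adjudicate = rng.random(n) < config.adjudication_prob
    latent = latent_quantile_tiers(out["latent_risk"], config.tier_proportions)
    codes = np.where(adjudicate, latent.codes, algo.codes)
    out["practice_tier"] = pd.Categorical.from_codes(
        codes, categories=list(TIER_LEVELS), ordered=True
    )
    return out


def top_share(values, fraction: float = 0.10) -> float:
    """Share of the total carried by the top ``fraction`` of observations."""
    x = np.sort(np.asarray(values, dtype=float))[::-1]
    total = x.sum()
    if total <= 0:
        raise ValueError("total must be positive")
    k = max(int(np.ceil(fraction * x.size)), 1)
    return float(x[:k].sum() / total)


def gini(values) -> float:
    """Gini coefficient of a nonnegative vector (concentration of spend)."""
    x = np.sort(np.asarray(values, dtype=float))
    if (x < 0).any():
        raise ValueError("values must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("total must be positive")
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * total))
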