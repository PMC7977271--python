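"""Hierarchical-condition-category (HCC) style risk scoring.

An HCC-type score summarises a patient's expected future utilization as the
sum of a demographic weight (an age-band x sex cell) and one weight per
*surviving* condition category.  Diagnosis codes map many-to-one onto
condition categories; hierarchy rules then suppress milder categories when a
dominant (more severe) related category is present, so a patient with both
"diabetes with complications" and "diabetes" is only credited the former.

The module ships a small toy model (:func:`toy_model`) in the same three-file
CSV format it accepts for user-supplied tables, so the scoring path is
desk-testable without any licensed code system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HccModel",
    "RiskScore",
    "load_model",
    "toy_model",
    "map_codes_to_ccs",
    "apply_hierarchies",
    "compute_score",
    "score_population",
]

logger = logging.getLogger(__name__)


class ModelValidationError(ValueError):
    """Raised when the three model tables are mutually inconsistent."""


@dataclass(frozen=True)
class HccModel:
    """Validated code map, hierarchy rules and coefficient tables.

    Parameters
    ----------
    code_to_cc
        Diagnosis code -> condition category. Every code maps to at most one
        category (enforced at load time).
    hierarchies
        ``(dominant, frozenset of suppressed)`` pairs. The implied directed
        graph must be acyclic.
    cc_weights
        Category -> nonnegative additive weight.
    demographic_weights
        ``(sex, age_band_index)`` -> nonnegative weight.
    age_bands
        Ordered half-open intervals ``[lo, hi)`` covering ``[0, inf)``.
    """

    code_to_cc: dict[str, str]
    hierarchies: tuple[tuple[str, frozenset[str]], ...]
    cc_weights: dict[str, float]
    demographic_weights: dict[tuple[str, int], float]
    age_bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for cat, w in self.cc_weights.items():
            if w < 0:
                raise ModelValidationError(f"negative weight for category {cat!r}")
        for cell, w in self.demographic_weights.items():
            if w < 0:
                raise ModelValidationError(f"negative demographic weight for {cell!r}")
        known = set(self.cc_weights)
        for code, cat in self.code_to_cc.items():
            if cat not in known:
                raise ModelValidationError(
                    f"code {code!r} maps to category {cat!r} absent from coefficients"
                )
        for dom, sup in self.hierarchies:
            missing = ({dom} | set(sup)) - known
            if missing:
                raise ModelValidationError(
                    f"hierarchy references unknown categories: {sorted(missing)}"
                )
        self._check_bands()
        self._check_acyclic()

    def _check_bands(self) -> None:
        prev_hi = 0.0
        for lo, hi in self.age_bands:
            if lo != prev_hi:
                raise ModelValidationError(
                    f"age bands must tile [0, inf): gap/overlap at {lo}"
                )
            if not hi > lo:
                raise ModelValidationError(f"empty age band [{lo}, {hi})")
            prev_hi = hi
        if not np.isinf(prev_hi):
            raise ModelValidationError("age bands must extend to infinity")

    def _check_acyclic(self) -> None:
        edges: dict[str, set[str]] = {}
        for dom, sup in self.hierarchies:
            edges.setdefault(dom, set()).update(sup)
        seen: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(node: str) -> None:
            state = seen.get(node)
            if state == 0:
                raise ModelValidationError(f"cyclic hierarchy involving {node!r}")
            if state == 1:
                return
            seen[node] = 0
            for nxt in edges.get(node, ()):
                visit(nxt)
            seen[node] = 1

        for node in edges:
            visit(node)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self.cc_weights)

    def age_band_index(self, age: float) -> int:
        if age < 0:
            raise ValueError(f"negative age {age}")
        for i, (lo, hi) in enumerate(self.age_bands):
            if lo <= age < hi:
                return i
        raise AssertionError("age bands are exhaustive")  # pragma: no cover

    def age_band_label(self, i: int) -> str:
        lo, hi = self.age_bands[i]
        hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
        return f"{lo:g}-{hi_s}"


@dataclass(frozen=True)
class RiskScore:
    """A scored patient: total score and the categories that survived."""

    patient_id: str
    score: float
    surviving_ccs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be nonnegative")


def _parse_band(label: str) -> tuple[float, float]:
    lo_s, hi_s = label.split("-", 1)
    return float(lo_s), float("inf") if hi_s.strip().lower() == "inf" else float(hi_s)


def load_model(map_file, hierarchy_file, coef_file) -> HccModel:
    """Load and validate a three-file HCC-style model.

    ``map.csv`` has columns (code, cc); ``hierarchy.csv`` has
    (dominant_cc, suppressed_cc) with one pair per row; ``coef.csv`` has
    (kind, key1, key2, weight) where ``kind='cc'`` rows carry the category in
    key1 and ``kind='demo'`` rows carry sex in key1 and an age band
    ``"lo-hi"`` (``hi`` may be ``inf``) in key2.
    """
    cmap = pd.read_csv(map_file, dtype=str)
    hier = pd.read_csv(hierarchy_file, dtype=str)
    coef = pd.read_csv(coef_file, dtype={"kind": str, "key1": str, "key2": str})

    dup = cmap[cmap.duplicated("code", keep=False)]
    if not dup.empty:
        raise ModelValidationError(
            f"duplicate code rows in map file: {sorted(dup['code'].unique())}"
        )
    code_to_cc = dict(zip(cmap["code"], cmap["cc"]))

    cc_rows = coef[coef["kind"] == "cc"]
    if cc_rows["key1"].duplicated().any():
        raise ModelValidationError("duplicate cc coefficient rows")
    cc_weights = dict(zip(cc_rows["key1"], cc_rows["weight"].astype(float)))

    demo_rows = coef[coef["kind"] == "demo"]
    bands = sorted({_parse_band(b) for b in demo_rows["key2"]})
    band_index = {b: i for i, b in enumerate(bands)}
    demographic_weights = {
        (row.key1, band_index[_parse_band(row.key2)]): float(row.weight)
        for row in demo_rows.itertuples()
    }
    if len(demographic_weights) != len(demo_rows):
        raise ModelValidationError("duplicate demographic coefficient rows")

    hierarchies_map: dict[str, set[str]] = {}
    for row in hier.itertuples():
        hierarchies_map.setdefault(row.dominant_cc, set()).add(row.suppressed_cc)
    hierarchies = tuple(
        (dom, frozenset(sup)) for dom, sup in sorted(hierarchies_map.items())
    )

    return HccModel(
        code_to_cc=code_to_cc,
        hierarchies=hierarchies,
        cc_weights=cc_weights,
        demographic_weights=demographic_weights,
        age_bands=tuple(bands),
    )


def toy_model() -> HccModel:
    """The small licensing-free model shipped with the package (~9 categories)."""
    root = resources.files("riskstrat").joinpath("models", "toy")
    with resources.as_file(root) as p:
        return load_model(
            Path(p) / "map.csv", Path(p) / "hierarchy.csv", Path(p) / "coef.csv"
        )


def map_codes_to_ccs(codes, model: HccModel) -> frozenset[str]:
    """Map diagnosis codes to condition categories; unmapped codes are skipped.

    Unmapped codes are not an error — real EHR feeds are dirty — but the count
    is logged so silent data loss is visible.
    """
    mapped = set()
    n_unmapped = 0
    for code in set(codes):
        cat = model.code_to_cc.get(code)
        if cat is None:
            n_unmapped += 1
        else:
            mapped.add(cat)
    if n_unmapped:
        logger.debug("%d unmapped diagnosis codes skipped", n_unmapped)
    return frozenset(mapped)


def apply_hierarchies(ccs, model: HccModel) -> frozenset[str]:
    """Suppress dominated categories, iterating rules to a fixpoint.

    For each rule (dominant, suppressed-set): if the dominant category is
    present, every suppressed category is removed. Rules are re-applied until
    nothing changes, so chains of rules behave transitively.
    """
    current = set(ccs)
    unknown = current - model.categories
    if unknown:
        raise ValueError(f"categories not in model: {sorted(unknown)}")
    while True:
        nxt = set(current)
        for dom, sup in model.hierarchies:
            # dominance is judged on the categories present at the start of
            # the pass, so a category can suppress others even if it is
            # itself suppressed in the same pass
            if dom in current:
                nxt -= sup
        if nxt == current:
            return frozenset(current)
        current = nxt


def compute_score(
    age: float, sex: str, codes, model: HccModel, patient_id: str = ""
) -> RiskScore:
    """Demographic weight plus the weights of the surviving categories."""
    if sex not in {"F", "M"}:
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    cell = (sex, model.age_band_index(age))
    try:
        score = model.demographic_weights[cell]
    except KeyError:
        raise ModelValidationError(
            f"missing demographic cell for sex={sex}, band {model.age_band_label(cell[1])}"
        ) from None
    surviving = apply_hierarchies(map_codes_to_ccs(codes, model), model)
    score += sum(model.cc_weights[c] for c in surviving)
    return RiskScore(patient_id=str(patient_id), score=score, surviving_ccs=surviving)


def score_population(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    model: HccModel,
) -> pd.Series:
    """Score every patient in a table.

    Parameters
    ----------
    patients
        Must carry ``patient_id``, ``age``, ``sex``.
    diagnoses
        Long format, columns ``patient_id`` and ``code``.

    Returns
    -------
    Series of scores indexed like ``patients``.
    """
    known = diagnoses[diagnoses["code"].isin(model.code_to_cc)]
    n_unmapped = len(diagnoses) - len(known)
    if n_unmapped:
        logger.warning("%d diagnosis rows with unmapped codes skipped", n_unmapped)
    cats = known.assign(cc=known["code"].map(model.code_to_cc))
    by_patient = cats.groupby("patient_id")["cc"].agg(frozenset)

    # demographic part, vectorised over age bands
    edges = [lo for lo, _ in model.age_bands] + [np.inf]
    band = pd.cut(patients["age"], bins=edges, right=False, labels=False)
    demo = np.array(
        [
            model.demographic_weights[(s, int(b))]
            for s, b in zip(patients["sex"], band)
        ]
    )

    cache: dict[frozenset, float] = {}

    def cc_sum(ccs: frozenset) -> float:
        if ccs not in cache:
            surviving = apply_hierarchies(ccs, model)
            cache[ccs] = sum(model.cc_weights[c] for c in surviving)
        return cache[ccs]

    cc_part = (
        patients["patient_id"]
        .map(by_patient)
        .map(lambda s: cc_sum(s) if isinstance(s, frozenset) else 0.0)
    )
    return pd.Series(demo + cc_part.to_numpy(), index=patients.index, name="hcc_score")
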