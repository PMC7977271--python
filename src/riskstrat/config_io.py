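"""YAML round-trip for generator configurations.

The config file mirrors :class:`~riskstrat.synthetic.GeneratorConfig` field
for field; nested blocks hold the condition roster and the three outcome
models.  Any omitted key falls back to the shipped calibrated default, so a
minimal file like ``{n_patients: 5000, seed: 3}`` is valid.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .synthetic import (
    ConditionDef,
    CountModel,
    ExpenditureModel,
    GeneratorConfig,
    default_config,
)

__all__ = ["load_generator_config", "dump_generator_config"]


def _config_to_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["condition_defs"] = [
        {"name": c.name, "prevalence": c.prevalence,
         "risk_loading": c.risk_loading, "codes": list(c.codes)}
        for c in cfg.condition_defs
    ]
    for k in ("ed_model", "hosp_model"):
        d[k] = dataclasses.asdict(getattr(cfg, k))
    d["expenditure_model"] = dataclasses.asdict(cfg.expenditure_model)
    d["tier_proportions"] = list(cfg.tier_proportions)
    d["payer_probs"] = list(cfg.payer_probs)
    d["age_range"] = list(cfg.age_range)
    return d


def dump_generator_config(cfg: GeneratorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_generator_config(path) -> GeneratorConfig:
    """Read a YAML config; missing keys inherit the calibrated defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = default_config(
        n_patients=raw.pop("n_patients", 40_000), seed=raw.pop("seed", 20210318)
    )
    kwargs = {}
    if "condition_defs" in raw:
        kwargs["condition_defs"] = tuple(
            ConditionDef(
                name=c["name"], prevalence=c["prevalence"],
                risk_loading=c["risk_loading"], codes=tuple(c["codes"]),
            )
            for c in raw.pop("condition_defs")
        )
    for k, cls in (("ed_model", CountModel), ("hosp_model", CountModel),
                   ("expenditure_model", ExpenditureModel)):
        if k in raw:
            kwargs[k] = cls(**raw.pop(k))
    for k in ("tier_proportions", "payer_probs", "age_range"):
        if k in raw:
            kwargs[k] = tuple(raw.pop(k))
    kwargs.update(raw)
    return base.with_(**kwargs)
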