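"""YAML configuration loading and serialisation.

A run configuration bundles the risk model, screening effects, economics
and a strategy grid under the keys::

    risk_model: {variance: 0.68}
    effects: {rr_mortality: 0.79, rr_incidence: 1.23, ...}
    economics:
      base_utility: 0.8639
      costs: {psa_test: 11, genotyping: 25, ...}
      treatment_mix: {early: {...}, advanced: {...}}
    strategies:
      - {kind: none}
      - {kind: age_based}
      - {kind: precision, threshold: 0.04}
    cohort: {size: 4480000}
    psa: {draws: 10000, seed: 42}

Every key is optional; omitted values fall back to the built-in defaults
(the published point estimates).  Precedence elsewhere is CLI flag >
YAML > built-in default.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import yaml

from .economics import CostSet, EconParams
from .lifetable import ScreeningEffects
from .riskdist import RiskModel
from .strategies import Strategy

__all__ = ["load_config", "dump_config", "build_components"]


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def _filter_fields(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


def build_components(cfg: dict) -> dict:
    """Materialise model components from a config mapping."""
    risk_model = RiskModel.from_dict(cfg.get("risk_model", {}))
    effects = ScreeningEffects(**_filter_fields(ScreeningEffects, cfg.get("effects", {})))

    econ_cfg = dict(cfg.get("economics", {}))
    costs = CostSet(**_filter_fields(CostSet, econ_cfg.pop("costs", {})))
    if "wtp" in econ_cfg:
        econ_cfg["wtp"] = tuple(econ_cfg["wtp"])
    econ = EconParams(costs=costs, **_filter_fields(EconParams, {**econ_cfg}))

    strategies = None
    if "strategies" in cfg:
        strategies = [Strategy.from_dict(d) for d in cfg["strategies"]]

    return {
        "risk_model": risk_model,
        "effects": effects,
        "econ": econ,
        "strategies": strategies,
        "cohort_size": cfg.get("cohort", {}).get("size", 4_480_000),
        "psa": {"draws": cfg.get("psa", {}).get("draws", 10_000),
                "seed": cfg.get("psa", {}).get("seed", 42)},
    }


def dump_config(risk_model: RiskModel, effects: ScreeningEffects,
                econ: EconParams, strategies: list, path: Union[str, Path]) -> None:
    cfg = {
        "risk_model": risk_model.to_dict(),
        "effects": {
            "rr_mortality": effects.rr_mortality,
            "rr_incidence": effects.rr_incidence,
            "rr_advanced": effects.rr_advanced,
            "overdiagnosis_intercept": effects.overdiagnosis_intercept,
            "overdiagnosis_slope": effects.overdiagnosis_slope,
            "opportunistic_fraction": effects.opportunistic_fraction,
        },
        "economics": {
            "base_utility": econ.base_utility,
            "utility_decline": econ.utility_decline,
            "pc_utility_multiplier": econ.pc_utility_multiplier,
            "discount_rate": econ.discount_rate,
            "wtp": list(econ.wtp),
            "advanced_fraction_clinical": econ.advanced_fraction_clinical,
            "biopsy_positivity": econ.biopsy_positivity,
            "costs": dataclasses.asdict(econ.costs),
            "treatment_mix": econ.treatment_mix,
        },
        "strategies": [s.to_dict() for s in strategies],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
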