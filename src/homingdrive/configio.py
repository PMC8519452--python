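"""Structured-text configuration for rates and scenarios (YAML)."""

from __future__ import annotations

from typing import Any, Dict, Mapping, Optional

import yaml

from .genetics import GENOTYPE_BY_LABEL, DriveRates, derive_rates
from .popmodel import FitnessScheme, ScenarioConfig


def rates_from_mapping(block: Mapping[str, Any]) -> DriveRates:
    """Build DriveRates from a flat key-value block (d_f, d_m, u, p)."""
    missing = {"d_f", "d_m", "u"} - set(block)
    if missing:
        raise ValueError(f"rates config missing keys: {sorted(missing)}")
    return derive_rates(
        float(block["d_f"]), float(block["d_m"]),
        float(block["u"]), float(block.get("p", 0.0)),
    )


def fitness_from_mapping(block: Mapping[str, Any]) -> FitnessScheme:
    return FitnessScheme(
        fecundity_cost_f=float(block.get("fecundity_cost_f", 0.0)),
        somatic_cost_m=float(block.get("somatic_cost_m", 0.0)),
        somatic_cost_f=float(block.get("somatic_cost_f", 0.0)),
    )


def scenario_from_mapping(doc: Mapping[str, Any]) -> ScenarioConfig:
    """Build a ScenarioConfig from a nested config tree.

    Expected keys: label, rates {d_f, d_m, u, p}, fitness {...},
    initial {genotype label -> frequency}, generations.
    """
    rates = rates_from_mapping(doc.get("rates", {}))
    fitness = fitness_from_mapping(doc.get("fitness", {}))
    initial: Optional[Dict] = None
    if "initial" in doc:
        initial = {}
        for label, freq in doc["initial"].items():
            if label not in GENOTYPE_BY_LABEL:
                raise ValueError(f"unknown genotype label {label!r}")
            initial[GENOTYPE_BY_LABEL[label]] = float(freq)
    return ScenarioConfig(
        label=str(doc.get("label", "custom")),
        rates=rates,
        fitness=fitness,
        initial=initial,
        generations=int(doc.get("generations", 12)),
    )


def load_yaml(path: str) -> Dict[str, Any]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path!r} is not a mapping")
    return doc


def load_scenario(path: str) -> ScenarioConfig:
    return scenario_from_mapping(load_yaml(path))


def load_rates(path: str) -> DriveRates:
    doc = load_yaml(path)
    block = doc.get("rates", doc)
    return rates_from_mapping(block)
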