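"""YAML/JSON configuration loading and saving.

The configuration document mirrors the parameter dataclasses key for key:

.. code-block:: yaml

    currency: EUR
    cohort: {n_staff: 1000, horizon_days: 365, initial_distribution: [1, 0, 0]}
    costs: {cost_per_sick_day: 500, cost_per_quit: 75000, psp_cost_per_person: 550}
    hazards:
      no_psp: {q_hie: 0.02, p_dayoff_high: 0.05, ...}
      psp: {q_hie: 0.02, p_dayoff_high: 0.03, ...}

The packaged default (``data/base_case.yaml``) is the published base case.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .fixtures import FixtureBundle
from .model_core import CohortConfig, CostParameters, HazardParameters

__all__ = ["ConfigError", "bundle_to_dict", "bundle_from_dict", "load_config", "save_config", "default_config"]

_HAZARD_KEYS = (
    "q_hie",
    "p_dayoff_high",
    "p_dayoff_low",
    "p_quit_high",
    "p_quit_low",
    "recovery_prob",
)
_COST_KEYS = ("cost_per_sick_day", "cost_per_quit", "psp_cost_per_person")
_COHORT_KEYS = ("n_staff", "horizon_days", "initial_distribution")


class ConfigError(ValueError):
    """Configuration document is missing keys or carries unknown ones."""


def bundle_to_dict(bundle: FixtureBundle) -> dict:
    def hz(h: HazardParameters) -> dict:
        return {k: getattr(h, k) for k in _HAZARD_KEYS}

    return {
        "currency": bundle.currency,
        "cohort": {
            "n_staff": bundle.cohort.n_staff,
            "horizon_days": bundle.cohort.horizon_days,
            "initial_distribution": list(bundle.cohort.initial_distribution),
        },
        "costs": {k: getattr(bundle.costs, k) for k in _COST_KEYS},
        "hazards": {"no_psp": hz(bundle.hazards_no_psp), "psp": hz(bundle.hazards_psp)},
    }


def _take(section: dict, name: str, keys: tuple[str, ...], problems: list[str]) -> dict:
    missing = [f"{name}.{k}" for k in keys if k not in section]
    unknown = [f"{name}.{k}" for k in section if k not in keys]
    problems.extend(f"missing key {k}" for k in missing)
    problems.extend(f"unknown key {k}" for k in unknown)
    return {k: section[k] for k in keys if k in section}


def bundle_from_dict(doc: dict) -> FixtureBundle:
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    problems: list[str] = []
    for section in ("cohort", "costs", "hazards"):
        if section not in doc or not isinstance(doc.get(section), dict):
            problems.append(f"missing section {section}")
    if problems:
        raise ConfigError("; ".join(problems))
    for arm in ("no_psp", "psp"):
        if arm not in doc["hazards"]:
            problems.append(f"missing section hazards.{arm}")
    if problems:
        raise ConfigError("; ".join(problems))

    cohort_kw = _take(doc["cohort"], "cohort", _COHORT_KEYS, problems)
    cost_kw = _take(doc["costs"], "costs", _COST_KEYS, problems)
    hz_a = _take(doc["hazards"]["no_psp"], "hazards.no_psp", _HAZARD_KEYS, problems)
    hz_b = _take(doc["hazards"]["psp"], "hazards.psp", _HAZARD_KEYS, problems)
    if problems:
        raise ConfigError("; ".join(problems))

    cohort_kw["initial_distribution"] = tuple(cohort_kw["initial_distribution"])
    return FixtureBundle(
        hazards_no_psp=HazardParameters(**hz_a),
        hazards_psp=HazardParameters(**hz_b),
        costs=CostParameters(**cost_kw),
        cohort=CohortConfig(**cohort_kw),
        currency=str(doc.get("currency", "EUR")),
    )


def load_config(path: str | Path) -> FixtureBundle:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return bundle_from_dict(doc)


def save_config(bundle: FixtureBundle, path: str | Path) -> None:
    path = Path(path)
    doc = bundle_to_dict(bundle)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def default_config() -> FixtureBundle:
    """The packaged base-case configuration."""
    text = resources.files("psp_econ").joinpath("data/base_case.yaml").read_text()
    return bundle_from_dict(yaml.safe_load(text))
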