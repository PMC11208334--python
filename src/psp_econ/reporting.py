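"""Report generation: annual budget-impact tables, PSA summaries, manifests.

Display tables round day and dropout counts to integers and costs to whole
currency units; serialized JSON keeps full precision.  Every report
references the run manifest written alongside it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_engine import ComparisonResult, ScenarioResult

__all__ = ["RunManifest", "table3_frame", "base_case_report", "write_json"]

MANIFEST_NAME = "manifest.json"

_TABLE_ROWS = (
    ("Sick days", "sick_days_total"),
    ("Dropouts", "dropouts_total"),
    ("Cost of sick days", "cost_sick_days"),
    ("Cost of dropouts", "cost_dropouts"),
    ("Total costs", "cost_hie_total"),
    ("Cost per Person", "hie_cost_per_person"),
)


@dataclass
class RunManifest:
    """Provenance record for a run: config echo, version, seed, timings."""

    config: dict
    master_seed: int | None = None
    version: str = __version__
    started_at: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S%z"))
    runtimes_s: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float) -> None:
        self.runtimes_s[stage] = round(seconds, 3)

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / MANIFEST_NAME
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def table3_frame(no_psp: ScenarioResult, psp: ScenarioResult) -> pd.DataFrame:
    """Annual per-institution report, integer-rounded for display.

    The "Total costs" and "Cost per Person" rows cover HIE-attributable
    costs (sick days + replacements); the program fee appears separately in
    the comparison block.
    """
    rows = {
        label: [round(getattr(no_psp, attr)), round(getattr(psp, attr))]
        for label, attr in _TABLE_ROWS
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["Without PSP", "With PSP"]
    )


def base_case_report(
    no_psp: ScenarioResult,
    psp: ScenarioResult,
    comparison: ComparisonResult,
    currency: str = "EUR",
) -> dict:
    """Full-precision JSON document for a deterministic base-case run."""
    return {
        "currency": currency,
        "manifest": MANIFEST_NAME,
        "scenarios": {
            "no_psp": dataclasses.asdict(no_psp),
            "psp": dataclasses.asdict(psp),
        },
        "comparison": dataclasses.asdict(comparison),
    }


def write_json(doc: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
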