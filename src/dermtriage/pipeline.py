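"""Orchestration: one entry point wiring data -> populations -> endpoints
-> accuracy -> sequential test -> cost impact -> report bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .accuracy import accuracy_report
from .cost import AvoidedActivity, CostParams, cost_impact, derive_avoided_activity
from .fixtures import FIXTURES, make_fixture
from .io import read_lesion_table, write_lesion_table
from .populations import apply_population_filter, summarize_cohort
from .sequential import DesignSpec, run_two_stage_analysis
from .simulate import SimulationConfig, simulate_trial

log = logging.getLogger("dermtriage")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``input_path`` / ``simulation`` / ``fixture`` selects
    the data source.  ``avoided`` optionally supplies externally tallied
    avoided-activity counts (e.g. from a wider pathway population than
    the analysis table); otherwise they are derived from the records.
    """

    input_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    fixture: Optional[str] = None
    population: str = "pp"
    raters: Tuple[str, ...] = ("soc", "ai_a", "ai_b", "ai_rws")
    sequential_rater: str = "ai_a"
    design: DesignSpec = field(default_factory=DesignSpec)
    cost_params: CostParams = field(default_factory=CostParams)
    avoided: Optional[AvoidedActivity] = None
    cost_rater: str = "ai_a"
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        sources = [
            s for s in (self.input_path, self.simulation, self.fixture)
            if s is not None
        ]
        if len(sources) != 1:
            raise ValueError(
                "exactly one of input_path, simulation or fixture must be set"
            )
        if self.fixture is not None and self.fixture not in FIXTURES:
            raise ValueError(f"unknown fixture {self.fixture!r}")


def _load(config: RunConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    if config.input_path is not None:
        lesions, patients, errors = read_lesion_table(config.input_path)
        for err in errors:
            log.warning("row %d dropped: %s", err.row, err.message)
        return lesions, patients
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        return simulate_trial(sim)
    return make_fixture(config.fixture)


def _config_hash(config: RunConfig) -> str:
    text = repr(config)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> Dict[str, object]:
    """Run the whole pipeline; return (and optionally write) the report bundle."""
    config.validate()
    lesions, patients = _load(config)
    population, exclusions = apply_population_filter(lesions, config.population)
    log.info(
        "population %s: %d of %d lesions", config.population,
        len(population), len(lesions),
    )

    summary = summarize_cohort(population, patients)
    report = accuracy_report(population, raters=config.raters)

    phase1 = population[population["phase"] == 1]
    phase2 = population[population["phase"] == 2]
    trial = run_two_stage_analysis(
        phase1, phase2, config.design, config.sequential_rater
    )

    avoided = config.avoided
    if avoided is None:
        avoided = derive_avoided_activity(population, config.cost_rater)
    impact = cost_impact(avoided, config.cost_params)

    bundle: Dict[str, object] = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "population": config.population,
            "config_hash": _config_hash(config),
        },
        "exclusions": exclusions,
        "cohort_summary": summary,
        "accuracy": report,
        "trial_result": {
            "phase1": dataclasses.asdict(trial.phase1),
            "phase2": dataclasses.asdict(trial.phase2),
            "combined_z": trial.combined_z,
            "combined_p": trial.combined_p,
            "threshold": trial.threshold,
            "decision": trial.decision,
        },
        "avoided_activity": dataclasses.asdict(avoided),
        "cost_impact": impact.as_dict(),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_lesion_table(population, out / "population.csv", patients)
        report.to_csv(out / "accuracy_report.csv", index=False)
        serializable = {k: v for k, v in bundle.items() if k != "accuracy"}
        (out / "report.json").write_text(
            json.dumps(serializable, indent=2, default=str)
        )
        (out / "accuracy_report.md").write_text(_markdown_report(report))
    return bundle


def _markdown_report(report: pd.DataFrame) -> str:
    cols = ["rater"] + [c for c in report.columns if c.endswith("_fmt")]
    head = "| " + " | ".join(c.replace("_fmt", "") for c in cols) + " |"
    sep = "|" + "|".join(["---"] * len(cols)) + "|"
    lines = [head, sep]
    for _, row in report.iterrows():
        lines.append("| " + " | ".join(str(row.get(c, "")) for c in cols) + " |")
    return "\n".join(lines) + "\n"
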