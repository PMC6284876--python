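"""End-to-end orchestration: simulate/extract → select → evaluate → report.

The scenario grid is disease × normalization mode × pulse sequence; each
scenario holds one feature table per reader. ``run_extract`` materializes
the tables (deterministic CSV bytes under a fixed seed), ``run_select``
applies the two-reader LASSO consensus, ``run_evaluate`` renders the
study-style report, and ``run_full`` chains all three.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .features import ExtractionConfig, feature_table
from .io import DISEASES, READERS, SEQUENCES
from .selection import DEFAULT_FOLDS, DEFAULT_SEED, select_per_scenario
from .evaluation import evaluate_scenarios
from .synthetic import Cohort, CohortSpec, generate_cohort

logger = logging.getLogger("radtex")

NORMALIZATIONS = ("none", "p1_99")


@dataclass(frozen=True)
class ScenarioConfig:
    """The full pipeline configuration (flat, serializable)."""

    diseases: tuple[str, ...] = DISEASES
    sequences: tuple[str, ...] = SEQUENCES
    normalizations: tuple[str, ...] = NORMALIZATIONS
    n_levels: int = 64
    n_bins: int = 256
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    folds: int = DEFAULT_FOLDS
    seed: int = DEFAULT_SEED

    def to_dict(self) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v
                for k, v in self.__dict__.items()}


def scenario_key(disease: str, normalization: str, sequence: str) -> tuple:
    return (disease, normalization, sequence)


def run_extract(cohort: Cohort, config: ScenarioConfig = ScenarioConfig(),
                out_dir: str | Path | None = None) -> dict:
    """Extract features for every (reader, disease, normalization) table.

    Returns scenario key → {reader: DataFrame}; if ``out_dir`` is given the
    tables are also written as one CSV per (reader, disease, normalization)
    with deterministic formatting.
    """
    tables: dict = {}
    frames: dict = {}
    for normalization in config.normalizations:
        extraction = ExtractionConfig(n_levels=config.n_levels,
                                      n_bins=config.n_bins,
                                      distances=config.distances,
                                      angles=config.angles,
                                      normalization=normalization)
        for disease in config.diseases:
            for reader in READERS:
                rois = cohort.subset(disease=disease, reader=reader)
                if not rois:
                    logger.warning("no ROIs for disease=%s reader=%s; skipped",
                                   disease, reader)
                    continue
                frame = feature_table(rois, extraction)
                frames[(reader, disease, normalization)] = frame
                for sequence in config.sequences:
                    sub = frame[frame["sequence"] == sequence].reset_index(drop=True)
                    if sub.empty:
                        logger.warning("no rows for %s/%s/%s reader %s",
                                       disease, normalization, sequence, reader)
                        continue
                    key = scenario_key(disease, normalization, sequence)
                    tables.setdefault(key, {})[reader] = sub

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (reader, disease, normalization), frame in frames.items():
            name = f"features_{disease}_{normalization}_reader{reader}.csv"
            frame.to_csv(out_dir / name, index=False, float_format="%.12g")
    return tables


def run_select(tables: dict, config: ScenarioConfig = ScenarioConfig(),
               out_path: str | Path | None = None) -> dict:
    """Two-reader LASSO consensus per scenario; optional JSON dump."""
    results = select_per_scenario(tables, folds=config.folds, seed=config.seed,
                                  log=logger.info)
    if out_path is not None:
        payload = {"/".join(map(str, key)): res.to_dict()
                   for key, res in results.items()}
        Path(out_path).write_text(json.dumps(payload, indent=1, sort_keys=True))
    return results


def run_evaluate(results: dict, tables: dict,
                 out_path: str | Path | None = None) -> pd.DataFrame:
    report = evaluate_scenarios(results, tables)
    if out_path is not None:
        report.to_csv(out_path, index=False, float_format="%.6g")
    return report


@dataclass
class ReportBundle:
    tables: dict
    selections: dict
    report: pd.DataFrame
    ledger: dict = field(default_factory=dict)


def run_full(spec: CohortSpec = CohortSpec(),
             config: ScenarioConfig = ScenarioConfig(),
             out_dir: str | Path | None = None) -> ReportBundle:
    """Simulate → extract → select → evaluate, optionally writing the bundle."""
    cohort = generate_cohort(spec)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps({"cohort": {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in spec.__dict__.items()},
                        "pipeline": config.to_dict()}, indent=1, sort_keys=True))
    tables = run_extract(cohort, config,
                         out_dir=None if out_dir is None else out_dir / "features")
    selections = run_select(tables, config,
                            out_path=None if out_dir is None
                            else out_dir / "selection.json")
    report = run_evaluate(selections, tables,
                          out_path=None if out_dir is None
                          else out_dir / "report.csv")
    if out_dir is not None:
        (out_dir / "ground_truth.json").write_text(
            json.dumps(cohort.ledger, indent=1, sort_keys=True))
    return ReportBundle(tables=tables, selections=selections, report=report,
                        ledger=cohort.ledger)
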