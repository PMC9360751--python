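"""End-to-end orchestration: generate or load a cohort, run every analysis
stage, and write a tidy, reproducible result bundle.

A bundle directory contains::

    samples.csv, patients.csv      (synthetic mode only)
    decay_rbc.json, decay_wbc.json, decay_tp.json
    timepoints.csv
    contrasts_<outcome>.csv
    roc_<predictor>_<outcome>.json
    provenance.json

Runs are idempotent for a fixed seed: a single seed feeds a splittable RNG
(numpy SeedSequence) handed to each stage, so toggling one stage never
changes another stage's draws, and two runs with equal seeds produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import __version__
from .cohort_stats import compare_groups, summarize_time_points
from .decay import DecayModelSpec, fit_decay
from .domain import Cohort, ValidationError
from .io import read_cohort_csv, write_patients_csv, write_samples_csv
from .roc import auc, evaluate_cutoff, first_sample_predictor
from .synthetic import ANALYTES, GeneratorConfig, default_config, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

#: Outcome -> statistics compared per time point in the contrasts stage.
CONTRAST_PLAN = {
    "rebleeding": ("rbc", "tp", "pct_monocytes_macrophages", "pct_erythro_siderophages"),
    "ventriculitis": ("cell_index", "wbc", "pct_granulocytes"),
    "dci": ("rbc", "wbc"),
}

#: (predictor, outcome, cutoff) triples evaluated in the ROC stage.
ROC_PLAN = (
    ("cell_index", "ventriculitis", 2.0),
    ("wbc", "dci", 1000.0),
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input mode is active."""

    mode: str = "synthetic"  # "synthetic" | "csv"
    samples_csv: Optional[str] = None
    patients_csv: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=default_config)
    seed: int = 0
    outdir: str = "results"
    stages: Dict[str, bool] = field(
        default_factory=lambda: {
            "data": True, "decay": True, "timepoints": True, "contrasts": True, "roc": True
        }
    )

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValidationError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv" and not (self.samples_csv and self.patients_csv):
            raise ValidationError("csv mode requires samples_csv and patients_csv")
        if self.mode == "synthetic" and (self.samples_csv or self.patients_csv):
            raise ValidationError("synthetic mode must not name input files")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_over = raw.pop("generator", {}) or {}
        gen = default_config()
        scalar_fields = {
            f.name for f in dataclasses.fields(GeneratorConfig)
            if f.name not in ("trajectories", "complications")
        }
        unknown = set(gen_over) - scalar_fields
        if unknown:
            raise ValidationError(f"unknown generator fields {sorted(unknown)}")
        if gen_over:
            gen = dataclasses.replace(gen, **gen_over)
        known = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown run-config fields {sorted(bad)}")
        return cls(generator=gen, **raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""

        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = enc(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def run_all(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the bundle directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stages = config.stages
    if config.mode == "synthetic":
        cohort = generate_cohort(config.generator, seed=config.seed)
        if stages.get("data", True):
            write_samples_csv(cohort, outdir / "samples.csv")
            write_patients_csv(cohort, outdir / "patients.csv")
    else:
        cohort = read_cohort_csv(config.samples_csv, config.patients_csv)
    if stages.get("decay", True):
        for analyte in ANALYTES:
            fit = fit_decay(DecayModelSpec.from_cohort(cohort, analyte))
            fit.to_json(
                outdir / f"decay_{analyte}.json",
                provenance={"seed": config.seed, "config_hash": config.config_hash()},
            )

    if stages.get("timepoints", True):
        summarize_time_points(cohort).table.to_csv(outdir / "timepoints.csv", index=False)

    if stages.get("contrasts", True):
        import pandas as pd

        for outcome, statistics in CONTRAST_PLAN.items():
            parts = []
            for stat in statistics:
                gc = compare_groups(cohort, outcome, stat)
                part = gc.contrasts.copy()
                part.insert(0, "statistic", stat)
                part.insert(1, "transform", gc.transform)
                parts.append(part)
            pd.concat(parts, ignore_index=True).to_csv(
                outdir / f"contrasts_{outcome}.csv", index=False
            )

    if stages.get("roc", True):
        for predictor, outcome, cutoff in ROC_PLAN:
            vals = first_sample_predictor(cohort, predictor)
            labels = np.array(
                [int(p.label(outcome)) for p in cohort if p.patient_id in vals.index]
            )
            result = evaluate_cutoff(
                vals.to_numpy(), labels, cutoff, predictor=predictor, outcome=outcome
            )
            result.auc = auc(vals.to_numpy(), labels)
            _write_json(outdir / f"roc_{predictor}_{outcome}.json", result.to_dict())

    _write_json(
        outdir / "provenance.json",
        {
            "package": "csfdecay",
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "config_hash": config.config_hash(),
            "n_patients": len(cohort),
            "n_samples": cohort.n_samples,
            "stages": {k: bool(v) for k, v in stages.items()},
        },
    )
    return outdir
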