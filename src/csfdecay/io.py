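"""CSV serialisation of cohorts and tidy analysis frames.

Two files describe a cohort:

``samples.csv`` — one row per CSF sample with fixed header::

    patient_id, day, rbc_csf, wbc_csf, tp, wbc_blood, rbc_blood,
    cum_drainage, q1_granulocytes, ..., q4_erythro_siderophages

(16 cytology columns: quadrants q1..q4 x the four cell classes). Missing
blood counts / cytology are empty fields, never zeros.

``patients.csv`` — one row per patient::

    patient_id, age, sex, rebleeding, rebleeding_onset_day,
    ventriculitis, ventriculitis_onset_day, dci, dci_onset_day

Complication flags are 0/1; onset days are empty when absent. Ventriculitis
onset is counted in days after EVD insertion, the others after SAH onset.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .domain import (
    CYTOLOGY_CLASSES,
    BloodCount,
    Cohort,
    Complication,
    CSFSample,
    CytologyGrid,
    Patient,
    ValidationError,
    assign_time_point,
)

CYTOLOGY_COLUMNS = [f"q{q}_{cls}" for q in range(1, 5) for cls in CYTOLOGY_CLASSES]

SAMPLE_COLUMNS = [
    "patient_id",
    "day",
    "rbc_csf",
    "wbc_csf",
    "tp",
    "wbc_blood",
    "rbc_blood",
    "cum_drainage",
    *CYTOLOGY_COLUMNS,
]

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "rebleeding",
    "rebleeding_onset_day",
    "ventriculitis",
    "ventriculitis_onset_day",
    "dci",
    "dci_onset_day",
]

OUTCOMES = ("rebleeding", "ventriculitis", "dci")


def samples_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Raw per-sample table in the samples.csv dialect."""
    rows = []
    for patient in cohort:
        for s in patient.samples:
            row = {
                "patient_id": s.patient_id,
                "day": s.day,
                "rbc_csf": s.rbc_csf,
                "wbc_csf": s.wbc_csf,
                "tp": s.tp,
                "wbc_blood": s.blood.wbc_blood if s.blood else np.nan,
                "rbc_blood": s.blood.rbc_blood if s.blood else np.nan,
                "cum_drainage": s.cum_drainage,
            }
            if s.cytology is not None:
                grid = s.cytology.as_array()
                for q in range(4):
                    for c, cls in enumerate(CYTOLOGY_CLASSES):
                        row[f"q{q + 1}_{cls}"] = grid[q, c]
            rows.append(row)
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def labels_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-patient labels table in the patients.csv dialect."""
    rows = []
    for p in cohort:
        row = {"patient_id": p.patient_id, "age": p.age, "sex": p.sex}
        for outcome in OUTCOMES:
            comp: Complication = getattr(p, outcome)
            row[outcome] = int(comp.present)
            row[f"{outcome}_onset_day"] = comp.onset_day if comp.present else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS)


def analysis_frame(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-sample frame with derived statistics for downstream stats.

    Adds ``cell_index`` (NaN where not computable), the four subpopulation
    percentages ``pct_<class>`` (NaN without cytology), and ``time_point``
    (NaN beyond day 22) to the raw sample columns, plus outcome labels
    broadcast to sample rows.
    """
    records = []
    for patient in cohort:
        for s in patient.samples:
            rec = {
                "patient_id": s.patient_id,
                "day": s.day,
                "rbc": s.rbc_csf,
                "wbc": s.wbc_csf,
                "tp": s.tp,
                "cum_drainage": s.cum_drainage,
                "cell_index": np.nan,
            }
            ci = s.cell_index
            if ci is not None:
                rec["cell_index"] = ci
            profile = s.subpopulations
            for cls in CYTOLOGY_CLASSES:
                rec[f"pct_{cls}"] = profile.as_dict()[cls] if profile else np.nan
            tp_idx = assign_time_point(s.day)
            rec["time_point"] = tp_idx if tp_idx is not None else np.nan
            for outcome in OUTCOMES:
                rec[outcome] = int(patient.label(outcome))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def write_samples_csv(cohort: Cohort, path) -> None:
    samples_to_frame(cohort).to_csv(path, index=False)


def write_patients_csv(cohort: Cohort, path) -> None:
    labels_to_frame(cohort).to_csv(path, index=False)


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_cohort_csv(samples_path, patients_path) -> Cohort:
    """Assemble a Cohort from the samples.csv / patients.csv pair.

    Raises ValidationError when the two files disagree on patient ids or a
    required column is missing.
    """
    samples = pd.read_csv(samples_path)
    patients = pd.read_csv(patients_path)
    for col in SAMPLE_COLUMNS[:8]:
        if col not in samples.columns:
            raise ValidationError(f"samples file missing column {col!r}")
    for col in ("patient_id", "rebleeding", "ventriculitis", "dci"):
        if col not in patients.columns:
            raise ValidationError(f"patients file missing column {col!r}")

    sample_ids = set(samples["patient_id"].astype(str))
    patient_ids = set(patients["patient_id"].astype(str))
    if not sample_ids <= patient_ids:
        orphans = sorted(sample_ids - patient_ids)
        raise ValidationError(f"samples reference unknown patient ids: {orphans}")

    by_id = {}
    for _, row in patients.iterrows():
        pid = str(row["patient_id"])
        comps = {}
        for outcome in OUTCOMES:
            present = bool(int(row[outcome]))
            onset = _opt(row.get(f"{outcome}_onset_day"))
            comps[outcome] = Complication(present, onset if present else None)
        by_id[pid] = Patient(
            patient_id=pid,
            age=float(row.get("age", np.nan)),
            sex=str(row.get("sex", "")),
            samples=[],
            **comps,
        )

    for _, row in samples.sort_values(["patient_id", "day"]).iterrows():
        pid = str(row["patient_id"])
        blood = None
        if _opt(row["wbc_blood"]) is not None and _opt(row["rbc_blood"]) is not None:
            blood = BloodCount(rbc_blood=float(row["rbc_blood"]), wbc_blood=float(row["wbc_blood"]))
        cyto = None
        if all(c in samples.columns for c in CYTOLOGY_COLUMNS):
            vals = [_opt(row[c]) for c in CYTOLOGY_COLUMNS]
            if all(v is not None for v in vals):
                grid = np.array(vals, dtype=float).reshape(4, 4)
                cyto = CytologyGrid(tuple(map(tuple, grid.astype(int).tolist())))
        by_id[pid].samples.append(
            CSFSample(
                patient_id=pid,
                day=float(row["day"]),
                rbc_csf=float(row["rbc_csf"]),
                wbc_csf=float(row["wbc_csf"]),
                tp=float(row["tp"]),
                cytology=cyto,
                blood=blood,
                cum_drainage=float(row["cum_drainage"]),
            )
        )

    cohort_patients = []
    for pid in patients["patient_id"].astype(str):
        p = by_id[pid]
        # re-validate ordering invariants now that samples are attached
        cohort_patients.append(
            Patient(
                patient_id=p.patient_id,
                age=p.age,
                sex=p.sex,
                rebleeding=p.rebleeding,
                ventriculitis=p.ventriculitis,
                dci=p.dci,
                samples=p.samples,
            )
        )
    return Cohort(cohort_patients)
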