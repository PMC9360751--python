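"""Prediction of later SAH complications from first-collection CSF values.

The predictor is the patient's earliest sample within time point 1 (days
1-4 after onset). Fixed cutoffs use strict inequality — a value exactly at
the cutoff is a negative call — matching the clinical convention of
reporting thresholds as "> c". The AUC is the trapezoidal area over all
thresholds, identical to the Mann-Whitney probability that a randomly
chosen case exceeds a randomly chosen control (ties counted half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .domain import Cohort, ValidationError
from .io import OUTCOMES, analysis_frame

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "first_sample_predictor", "evaluate_cutoff", "auc"]


@dataclass
class ROCResult:
    """Confusion counts and summary metrics at one cutoff.

    Sensitivity and specificity are percentages; ``auc`` is filled by
    :func:`auc` callers when wanted (cutoff evaluation alone leaves None).
    """

    predictor: str
    outcome: str
    cutoff: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    n: int
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity_percent": self.sensitivity,
            "specificity_percent": self.specificity,
            "n": self.n,
            "auc": self.auc,
        }


def first_sample_predictor(cohort: Cohort, statistic: str) -> pd.Series:
    """Per-patient value of ``statistic`` at the earliest time-point-1 sample.

    Patients without a usable sample in days 1-4 (or with an undefined
    statistic there, e.g. a cell index without a blood count) are excluded;
    the exclusion count is logged.
    """
    frame = analysis_frame(cohort)
    if frame.empty:
        return pd.Series(dtype=float, name=statistic)
    tp1 = frame[frame.time_point == 1].sort_values(["patient_id", "day"])
    first = tp1.groupby("patient_id", as_index=True).first()
    if statistic not in first.columns:
        raise ValidationError(f"unknown statistic {statistic!r}")
    vals = first[statistic].dropna()
    n_excluded = len(cohort) - len(vals)
    if n_excluded:
        logger.info(
            "first_sample_predictor(%s): %d patient(s) without a usable "
            "time-point-1 value excluded", statistic, n_excluded,
        )
    return vals


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValidationError("labels contain a single class; metrics undefined")


def evaluate_cutoff(
    values: Sequence[float],
    labels: Sequence[int],
    cutoff: float,
    direction: str = "greater",
    predictor: str = "",
    outcome: str = "",
) -> ROCResult:
    """2x2 confusion table and sensitivity/specificity at a fixed cutoff.

    ``direction="greater"``: positive call iff value > cutoff (strict);
    ``"less"``: value < cutoff.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValidationError("values and labels must align")
    _check_two_classes(y)
    if direction == "greater":
        call = v > cutoff
    elif direction == "less":
        call = v < cutoff
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    tp = int((call & (y == 1)).sum())
    fp = int((call & (y == 0)).sum())
    fn = int((~call & (y == 1)).sum())
    tn = int((~call & (y == 0)).sum())
    return ROCResult(
        predictor=predictor,
        outcome=outcome,
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        n=len(y),
    )


def auc(values: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve over all distinct thresholds.

    Equals the Mann-Whitney probability P(value_case > value_control) with
    ties counted one half — an identity exercised against a pair-counting
    oracle in the test suite.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    return float(roc_auc_score(y, v))
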