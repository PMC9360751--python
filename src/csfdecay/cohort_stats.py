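"""Longitudinal descriptive statistics and between-group comparisons.

Samples are grouped into the six protocol time points (days 1-4, 5-8, 9-11,
12-15, 16-18, 19-22 after SAH onset). When a patient contributes more than
one sample to a bin, the within-bin mean represents the patient, so no
patient is double-counted in a summary cell or a group contrast.

Group contrasts use a linear model on the (log-transformed where
appropriate) statistic with fixed effects for time point and for the group
within each time point, mirroring how per-time-point differences between
complication groups are usually assessed in small longitudinal cohorts.
Overall outcome associations use logistic regression of the patient-level
label on repeated measurements with a cluster-robust (patient-clustered)
sandwich variance, G/(G-1) small-sample scaling and t(G-1) p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .domain import Cohort, ValidationError
from .io import CYTOLOGY_CLASSES, OUTCOMES, analysis_frame

__all__ = [
    "STATISTICS",
    "LOG_STATISTICS",
    "TimePointTable",
    "GroupComparison",
    "OutcomeAssociation",
    "summarize_time_points",
    "peak_day",
    "compare_groups",
    "outcome_association",
]

#: Per-sample statistics summarised at each time point.
STATISTICS = ("rbc", "wbc", "tp", "cell_index") + tuple(f"pct_{c}" for c in CYTOLOGY_CLASSES)

#: Strictly positive, right-skewed statistics analysed on the log scale;
#: subpopulation percentages stay untransformed.
LOG_STATISTICS = frozenset({"rbc", "wbc", "tp", "cell_index"})


@dataclass
class TimePointTable:
    """Tidy per-time-point summaries: n, median, IQR per statistic."""

    table: pd.DataFrame  # columns: time_point, statistic, n, median, q1, q3

    def cell(self, time_point: int, statistic: str) -> pd.Series:
        t = self.table
        row = t[(t.time_point == time_point) & (t.statistic == statistic)]
        if row.empty:
            raise KeyError((time_point, statistic))
        return row.iloc[0]

    def median_days(self) -> dict:
        return {
            int(r.time_point): r.median
            for r in self.table[self.table.statistic == "day"].itertuples()
        }


@dataclass
class GroupComparison:
    """Per-time-point group contrasts for one outcome and one statistic."""

    outcome: str
    statistic: str
    transform: str  # "log" or "identity"
    contrasts: pd.DataFrame  # time_point, n_without, n_with, estimate, se, p, estimable


@dataclass
class OutcomeAssociation:
    """Cluster-robust logistic association of an outcome with a predictor."""

    outcome: str
    predictor: str
    transform: str
    estimate: float  # log-odds per unit predictor
    se: float
    p_value: float
    n_obs: int
    n_clusters: int
    converged: bool


def _patient_bin_means(cohort: Cohort) -> pd.DataFrame:
    """One row per (patient, time point): mean of each statistic and of day."""
    frame = analysis_frame(cohort)
    frame = frame.dropna(subset=["time_point"])
    frame["time_point"] = frame["time_point"].astype(int)
    cols = ["day", *STATISTICS]
    grouped = (
        frame.groupby(["patient_id", "time_point"], as_index=False)[cols + list(OUTCOMES)]
        .mean()
    )
    for outcome in OUTCOMES:
        grouped[outcome] = grouped[outcome].round().astype(int)
    return grouped


def summarize_time_points(cohort: Cohort) -> TimePointTable:
    """Median and IQR of each statistic at each protocol time point.

    Samples beyond day 22 are excluded; empty bins are reported with n=0
    and no value. ``statistic == "day"`` rows carry the median sampling day
    of each bin.
    """
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    per_patient = _patient_bin_means(cohort)
    rows = []
    for tp in range(1, 7):
        sub = per_patient[per_patient.time_point == tp]
        for stat in ("day", *STATISTICS):
            vals = sub[stat].dropna().to_numpy()
            if len(vals) == 0:
                rows.append(
                    dict(time_point=tp, statistic=stat, n=0, median=np.nan, q1=np.nan, q3=np.nan)
                )
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append(
                    dict(time_point=tp, statistic=stat, n=len(vals), median=med, q1=q1, q3=q3)
                )
    return TimePointTable(pd.DataFrame(rows))


def peak_day(cohort: Cohort, analyte: str) -> float:
    """Median across patients of the day each patient's maximum is observed.

    Ties are broken to the earliest day; patients with fewer than two
    samples are excluded.
    """
    attr = {"rbc": "rbc_csf", "wbc": "wbc_csf", "tp": "tp"}.get(analyte, analyte)
    days = []
    for p in cohort:
        if p.n_samples < 2:
            continue
        vals = [getattr(s, attr) for s in p.samples]
        days.append(p.samples[int(np.argmax(vals))].day)
    if not days:
        raise ValidationError("no patient with >= 2 samples")
    return float(np.median(days))


def compare_groups(
    cohort: Cohort, outcome: str, statistic: str, transform: Optional[str] = None
) -> GroupComparison:
    """Per-time-point contrasts between patients with and without an outcome.

    Fits one linear model: response ~ time-point fixed effects + a group
    indicator within each time point where both groups are present. The
    coefficient of each within-time-point group indicator is the contrast
    (group-with minus group-without) at that time point, with its OLS
    standard error and two-sided t-test p-value. Time points where a group
    is absent are reported as not estimable.
    """
    import statsmodels.api as sm

    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    if transform is None:
        transform = "log" if statistic in LOG_STATISTICS else "identity"

    data = _patient_bin_means(cohort).dropna(subset=[statistic]).copy()
    if data.empty:
        raise ValidationError(f"no data for statistic {statistic!r}")
    y = data[statistic].to_numpy(float)
    if transform == "log":
        if (y <= 0).any():
            raise ValidationError("log transform requires strictly positive values")
        y = np.log(y)
    group = data[outcome].to_numpy(int)
    tps = data["time_point"].to_numpy(int)
    present = sorted(set(tps))
    estimable = [
        t for t in present
        if (group[tps == t] == 1).any() and (group[tps == t] == 0).any()
    ]

    cols, names = [], []
    for t in present[1:]:
        cols.append((tps == t).astype(float))
        names.append(f"tp{t}")
    for t in estimable:
        cols.append(((tps == t) & (group == 1)).astype(float))
        names.append(f"group_tp{t}")
    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((len(y), 1))
    res = sm.OLS(y, X).fit()

    rows = []
    for t in range(1, 7):
        n0 = int(((tps == t) & (group == 0)).sum())
        n1 = int(((tps == t) & (group == 1)).sum())
        if t in estimable:
            j = 1 + names.index(f"group_tp{t}")
            rows.append(
                dict(
                    time_point=t, n_without=n0, n_with=n1,
                    estimate=float(res.params[j]), se=float(res.bse[j]),
                    p=float(res.pvalues[j]), estimable=True,
                )
            )
        else:
            rows.append(
                dict(
                    time_point=t, n_without=n0, n_with=n1,
                    estimate=np.nan, se=np.nan, p=np.nan, estimable=False,
                )
            )
    return GroupComparison(outcome, statistic, transform, pd.DataFrame(rows))


def outcome_association(
    cohort: Cohort, outcome: str, predictor: str, transform: Optional[str] = None
) -> OutcomeAssociation:
    """Logistic regression of a patient outcome on repeated CSF measurements.

    Each sample contributes one row; the variance is the cluster sandwich
    over patients with G/(G-1) scaling (G = number of clusters) and the
    p-value uses a t reference with G-1 degrees of freedom. Complete
    separation or non-convergence is flagged (``converged=False``) instead
    of reporting a spurious estimate.
    """
    import statsmodels.api as sm

    if outcome not in OUTCOMES:
        raise ValidationError(f"unknown outcome {outcome!r}")
    if transform is None:
        transform = "log" if predictor in LOG_STATISTICS else "identity"

    frame = analysis_frame(cohort).dropna(subset=[predictor]).copy()
    labels = frame[outcome].to_numpy(int)
    if labels.min() == labels.max():
        raise ValidationError(f"outcome {outcome!r} does not vary across patients")
    x = frame[predictor].to_numpy(float)
    if transform == "log":
        if (x <= 0).any():
            raise ValidationError("log transform requires strictly positive predictor")
        x = np.log(x)
    X = np.column_stack([np.ones_like(x), x])
    groups, _ = pd.factorize(frame["patient_id"].to_numpy())
    n_clusters = int(groups.max()) + 1

    import warnings

    model = sm.Logit(labels, X)
    try:
        with warnings.catch_warnings():
            # separation manifests as warnings + runaway params; we detect
            # and flag it below instead of surfacing noise
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        converged = False
        res = None
    if res is not None and np.abs(res.params).max() > 50:
        converged = False  # quasi-separation: runaway coefficients
    if not converged:
        return OutcomeAssociation(
            outcome, predictor, transform, float("nan"), float("nan"),
            float("nan"), len(labels), n_clusters, False,
        )

    params = res.params
    scores = model.score_obs(params)  # n x k
    meat = np.zeros((X.shape[1], X.shape[1]))
    for g in range(n_clusters):
        sg = scores[groups == g].sum(axis=0)
        meat += np.outer(sg, sg)
    bread = np.linalg.inv(-model.hessian(params))
    cov = bread @ meat @ bread * (n_clusters / (n_clusters - 1))
    se = math.sqrt(cov[1, 1])
    tstat = params[1] / se
    p = 2.0 * float(sps.t.sf(abs(tstat), n_clusters - 1))
    return OutcomeAssociation(
        outcome, predictor, transform, float(params[1]), se, p,
        len(labels), n_clusters, True,
    )
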