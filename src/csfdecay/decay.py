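"""Log-linear fixed-effects decay model for CSF analytes.

The analyte level of patient *i* at *t* days after SAH onset is modelled as

    y_it = exp(c_i) * exp(-lambda * t) * exp(-delta * Q_it) * exp(e_it)

where ``lambda`` is the per-day decay parameter, ``delta`` the decay per mL
of cumulative EVD drainage ``Q_it``, and ``c_i`` a patient-specific starting
level. Taking logs gives a linear panel model

    ln(y_it) = c_i - lambda * t - delta * Q_it + e_it

estimated by ordinary least squares with one intercept per patient. Two
numerically identical routes are provided: the within (demeaning) estimator
and explicit patient dummies via statsmodels. The decay rate is reported as
a percentage per day, 100 * (1 - exp(-lambda)).

Zero or non-positive values cannot enter the multiplicative model; they are
excluded from the fit and counted in the result (an optional +1 offset mode
exists but is off by default). Patients left with fewer than two usable
observations are dropped with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .domain import Cohort, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DecayModelSpec",
    "DecayFit",
    "EstimationError",
    "fit_decay",
    "percent_per_day",
    "back_extrapolate",
]


class EstimationError(RuntimeError):
    """The model cannot be estimated (rank deficiency, too few df, ...)."""


@dataclass
class DecayModelSpec:
    """Observations and options for one analyte's decay fit.

    ``observations`` is a tidy frame with columns ``patient_id``, ``day``,
    ``cum_drainage`` and ``value``.
    """

    analyte: str
    observations: pd.DataFrame
    include_drainage: bool = True
    offset: float = 0.0  # optional +1 mode for zero-inflated analytes

    REQUIRED = ("patient_id", "day", "cum_drainage", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.observations.columns]
        if missing:
            raise ValidationError(f"observations missing columns {missing}")

    @classmethod
    def from_cohort(
        cls, cohort: Cohort, analyte: str, include_drainage: bool = True, offset: float = 0.0
    ) -> "DecayModelSpec":
        attr = {"rbc": "rbc_csf", "wbc": "wbc_csf", "tp": "tp"}.get(analyte)
        if attr is None:
            raise ValidationError(f"unknown analyte {analyte!r}")
        rows = [
            {
                "patient_id": p.patient_id,
                "day": s.day,
                "cum_drainage": s.cum_drainage,
                "value": getattr(s, attr),
            }
            for p in cohort
            for s in p.samples
        ]
        return cls(analyte, pd.DataFrame(rows), include_drainage, offset)


@dataclass
class DecayFit:
    """Estimates and diagnostics of one log-linear decay fit."""

    analyte: str
    lambda_hat: float
    lambda_se: float
    lambda_p: float
    delta_hat: Optional[float]
    delta_se: Optional[float]
    delta_p: Optional[float]
    intercepts: Dict[str, float]
    percent_per_day: float
    n_obs: int
    n_patients: int
    n_excluded_nonpositive: int
    n_dropped_patients: int
    resid_sd: float
    method: str

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "analyte", "lambda_hat", "lambda_se", "lambda_p", "delta_hat",
            "delta_se", "delta_p", "percent_per_day", "n_obs", "n_patients",
            "n_excluded_nonpositive", "n_dropped_patients", "resid_sd", "method",
        )}
        d["intercepts"] = dict(sorted(self.intercepts.items()))
        return d

    def to_json(self, path, provenance: Optional[dict] = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def percent_per_day(lam: float) -> float:
    """Decay rate as a percentage per day: 100 * (1 - exp(-lambda)).

    Monotone increasing in lambda and bounded above by 100; negative for
    growing (lambda < 0) series.
    """
    return 100.0 * (1.0 - math.exp(-lam))


def back_extrapolate(observed_value: float, elapsed_days: float, lam: float) -> float:
    """Estimate the level at bleeding onset from a later measurement.

    Inverts the exponential decay: value_at_onset = observed * exp(+lambda *
    elapsed_days). Intended use: estimating the RBC count at the time of the
    bleed from a delayed lumbar puncture, given the decay rate and the time
    since symptom onset.
    """
    if observed_value is None or not observed_value > 0:
        raise ValidationError(f"observed value must be > 0, got {observed_value}")
    if elapsed_days is None or elapsed_days < 0:
        raise ValidationError(f"elapsed_days must be >= 0, got {elapsed_days}")
    return observed_value * math.exp(lam * elapsed_days)


def _prepare(spec: DecayModelSpec):
    obs = spec.observations.copy()
    obs["value"] = obs["value"] + spec.offset
    nonpos = obs["value"] <= 0
    n_excluded = int(nonpos.sum())
    if n_excluded:
        dropped_all = (
            obs.groupby("patient_id")["value"].apply(lambda v: (v <= 0).all())
        )
        for pid in dropped_all[dropped_all].index:
            logger.warning(
                "%s: all observations non-positive for patient %s; patient dropped",
                spec.analyte, pid,
            )
        obs = obs[~nonpos]
    sizes = obs.groupby("patient_id")["day"].transform("size")
    n_dropped = int(obs.loc[sizes < 2, "patient_id"].nunique())
    if n_dropped:
        logger.warning(
            "%s: dropping %d patient(s) with <2 usable observations",
            spec.analyte, n_dropped,
        )
    obs = obs[sizes >= 2]
    if obs.empty:
        raise EstimationError(f"{spec.analyte}: no usable observations")
    if (obs.groupby("patient_id")["day"].nunique() < 2).all():
        raise EstimationError(f"{spec.analyte}: no within-patient time variation")
    return obs, n_excluded, n_dropped


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = abs(np.corrcoef(X, rowvar=False)[0, 1]) if X.shape[1] == 2 else float("nan")
        raise EstimationError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}): columns "
            f"{list(names)} are collinear after the within transformation "
            f"(|corr| = {corr:.6f})"
        )


def _fit_within(obs: pd.DataFrame, slopes):
    """Within (demeaning) estimator with correct fixed-effects df."""
    y = np.log(obs["value"].to_numpy(float))
    X = obs[list(slopes)].to_numpy(float)
    groups = obs["patient_id"].to_numpy()
    codes, uniques = pd.factorize(groups)
    n_groups = len(uniques)

    def demean(a):
        a = np.asarray(a, float)
        if a.ndim == 1:
            means = np.bincount(codes, weights=a) / np.bincount(codes)
            return a - means[codes]
        return np.column_stack([demean(a[:, j]) for j in range(a.shape[1])])

    Xd, yd = demean(X), demean(y)
    _check_rank(Xd, slopes)
    XtX = Xd.T @ Xd
    beta = np.linalg.solve(XtX, Xd.T @ yd)
    resid = yd - Xd @ beta
    dof = len(y) - n_groups - len(slopes)
    if dof < 1:
        raise EstimationError(f"insufficient degrees of freedom ({dof})")
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(XtX)
    # intercepts: c_i = mean_i(ln y) - beta' mean_i(x)
    y_means = np.bincount(codes, weights=y) / np.bincount(codes)
    x_means = np.vstack(
        [np.bincount(codes, weights=X[:, j]) / np.bincount(codes) for j in range(X.shape[1])]
    ).T
    intercepts = {str(pid): float(y_means[k] - x_means[k] @ beta) for k, pid in enumerate(uniques)}
    return beta, np.sqrt(np.diag(cov)), dof, math.sqrt(s2), intercepts, n_groups, len(y)


def _fit_dummy(obs: pd.DataFrame, slopes):
    """Patient-dummy OLS via statsmodels (oracle-equivalent to within)."""
    import statsmodels.api as sm

    y = np.log(obs["value"].to_numpy(float))
    codes, uniques = pd.factorize(obs["patient_id"].to_numpy())
    D = np.eye(len(uniques))[codes]
    X = np.column_stack([obs[list(slopes)].to_numpy(float), D])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(
            f"design is rank deficient: columns {list(slopes)} collinear with "
            "the patient dummies or each other"
        )
    res = sm.OLS(y, X).fit()
    k = len(slopes)
    beta = res.params[:k]
    se = res.bse[:k]
    intercepts = {str(pid): float(res.params[k + j]) for j, pid in enumerate(uniques)}
    return (
        beta,
        se,
        int(res.df_resid),
        math.sqrt(float(res.mse_resid)),
        intercepts,
        len(uniques),
        len(y),
    )


def fit_decay(spec: DecayModelSpec, method: str = "within") -> DecayFit:
    """Estimate (lambda, delta, c_i) by fixed-effects OLS on ln(y).

    method
        ``"within"`` (demeaning, default) or ``"dummy"`` (explicit patient
        indicator columns). The two are algebraically identical; both are
        exposed so either can serve as the oracle for the other.

    Two-sided p-values come from conventional OLS t-tests (cluster-robust
    errors are reserved for the logistic outcome models).
    """
    if method not in ("within", "dummy"):
        raise ValidationError(f"unknown method {method!r}")
    obs, n_excluded, n_dropped = _prepare(spec)
    slopes = ["day", "cum_drainage"] if spec.include_drainage else ["day"]
    fitter = _fit_within if method == "within" else _fit_dummy
    beta, se, dof, resid_sd, intercepts, n_patients, n_obs = fitter(obs, slopes)

    lam = -float(beta[0])
    lam_se = float(se[0])
    lam_p = 2.0 * float(sps.t.sf(abs(lam / lam_se), dof)) if lam_se > 0 else float("nan")
    if spec.include_drainage:
        delta = -float(beta[1])
        delta_se = float(se[1])
        delta_p = 2.0 * float(sps.t.sf(abs(delta / delta_se), dof)) if delta_se > 0 else float("nan")
    else:
        delta = delta_se = delta_p = None

    return DecayFit(
        analyte=spec.analyte,
        lambda_hat=lam,
        lambda_se=lam_se,
        lambda_p=min(lam_p, 1.0) if not math.isnan(lam_p) else lam_p,
        delta_hat=delta,
        delta_se=delta_se,
        delta_p=delta_p,
        intercepts=intercepts,
        percent_per_day=percent_per_day(lam),
        n_obs=n_obs,
        n_patients=n_patients,
        n_excluded_nonpositive=n_excluded,
        n_dropped_patients=n_dropped,
        resid_sd=resid_sd,
        method=method,
    )
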