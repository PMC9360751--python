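"""Replicated simulation studies over seeded synthetic cohorts.

These drive both the test suite and the reproduction script: decay-rate
recovery (mean fitted percent-per-day across replicates of the default
cohort), peak-timing emulation (median per-patient peak day), type-I error
of the cluster-robust logistic association under the generator's null, and
the empirical drainage median.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np

from .cohort_stats import outcome_association, peak_day
from .decay import DecayModelSpec, fit_decay
from .synthetic import (
    ANALYTES,
    GeneratorConfig,
    daily_drainage_volumes,
    default_config,
    disable_effects,
    generate_cohort,
)

__all__ = [
    "replicate_seeds",
    "decay_recovery_means",
    "peak_day_medians",
    "cluster_logistic_type1_rate",
    "drainage_median",
]


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """n decorrelated 31-bit child seeds derived from one base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return (state % np.uint32(2**31)).astype(np.int64)


def decay_recovery_means(
    config: Optional[GeneratorConfig] = None,
    n_reps: int = 200,
    base_seed: int = 0,
    analytes: Sequence[str] = ANALYTES,
) -> Dict[str, float]:
    """Mean percent-per-day decay over seeded replicates of the default cohort.

    Each replicate generates a fresh cohort and fits the log-linear
    fixed-effects model (time + cumulative drainage) per analyte.
    """
    config = config or default_config()
    sums = {a: 0.0 for a in analytes}
    for seed in replicate_seeds(base_seed, n_reps):
        cohort = generate_cohort(config, seed=int(seed))
        for a in analytes:
            sums[a] += fit_decay(DecayModelSpec.from_cohort(cohort, a)).percent_per_day
    return {a: s / n_reps for a, s in sums.items()}


def peak_day_medians(
    config: Optional[GeneratorConfig] = None,
    n_reps: int = 100,
    base_seed: int = 0,
    analytes: Sequence[str] = ("wbc", "tp"),
) -> Dict[str, float]:
    """Median over replicates of the per-cohort median per-patient peak day."""
    config = config or default_config()
    acc = {a: [] for a in analytes}
    for seed in replicate_seeds(base_seed, n_reps):
        cohort = generate_cohort(config, seed=int(seed))
        for a in analytes:
            acc[a].append(peak_day(cohort, a))
    return {a: float(np.median(v)) for a, v in acc.items()}


def cluster_logistic_type1_rate(
    config: Optional[GeneratorConfig] = None,
    n_reps: int = 500,
    base_seed: int = 0,
    outcome: str = "dci",
    predictor: str = "wbc",
    alpha: float = 0.05,
) -> float:
    """Type-I error of the cluster-robust logistic association under the null.

    The null cohort carries outcome labels at the configured prevalences but
    no effects, so predictor and outcome are independent; the rejection rate
    at level alpha should sit near alpha.
    """
    null_config = disable_effects(config or default_config())
    hits = 0
    usable = 0
    for seed in replicate_seeds(base_seed, n_reps):
        cohort = generate_cohort(null_config, seed=int(seed))
        labels = [p.label(outcome) for p in cohort]
        if all(labels) or not any(labels):
            continue
        res = outcome_association(cohort, outcome, predictor)
        if not res.converged:
            continue
        usable += 1
        hits += res.p_value < alpha
    if usable == 0:
        raise RuntimeError("no usable replicates")
    return hits / usable


def drainage_median(
    config: Optional[GeneratorConfig] = None, n_draws: int = 100_000, base_seed: int = 0
) -> float:
    """Empirical median of daily EVD drainage draws from the generator."""
    config = config or default_config()
    rng = np.random.default_rng(np.random.SeedSequence(base_seed))
    return float(np.median(daily_drainage_volumes(config, rng, n_draws)))
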