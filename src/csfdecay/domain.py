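"""Domain model for serial ventricular CSF measurements after subarachnoid hemorrhage.

Patients with spontaneous SAH who require an external ventricular drain (EVD)
have CSF drawn repeatedly (typically twice weekly) for routine diagnostics.
Each draw yields red and white cell counts, total protein, and a cytology
slide read in four quadrants; a paired peripheral blood count allows the
*cell index* — the CSF WBC:RBC ratio normalised by the blood WBC:RBC ratio —
which corrects CSF pleocytosis for blood admixture (≈1 when all CSF cells
derive from contaminating blood).

This module holds the record types, the per-sample derived statistics, and
the protocol time-point binning used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CYTOLOGY_CLASSES",
    "TIME_POINT_BINS",
    "UndefinedValueError",
    "ValidationError",
    "BloodCount",
    "CytologyGrid",
    "SubpopulationProfile",
    "CSFSample",
    "Complication",
    "Patient",
    "Cohort",
    "cell_index",
    "chamber_to_per_ul",
    "subpopulation_proportions",
    "assign_time_point",
]

#: White-cell subpopulations scored on the cytospin slide, in canonical order.
CYTOLOGY_CLASSES = (
    "granulocytes",
    "lymphocytes",
    "monocytes_macrophages",
    "erythro_siderophages",
)

#: Protocol time points 1-6: inclusive day ranges since SAH onset.
TIME_POINT_BINS = ((1, 4), (5, 8), (9, 11), (12, 15), (16, 18), (19, 22))


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class UndefinedValueError(ValueError):
    """A derived statistic is mathematically undefined for these inputs.

    Distinct from a value of zero: e.g. the cell index with no CSF red
    cells, or subpopulation proportions of an all-empty slide.
    """


@dataclass(frozen=True)
class BloodCount:
    """Paired peripheral blood counts, cells per µL."""

    rbc_blood: float
    wbc_blood: float

    def __post_init__(self) -> None:
        if not (self.rbc_blood > 0 and self.wbc_blood > 0):
            raise ValidationError(
                f"blood counts must be strictly positive, got "
                f"rbc={self.rbc_blood}, wbc={self.wbc_blood}"
            )


@dataclass(frozen=True)
class CytologyGrid:
    """Cell counts per visual field: 4 slide quadrants x 4 cell classes.

    ``counts[q, c]`` is the number of cells of class ``CYTOLOGY_CLASSES[c]``
    seen in one spot of quadrant ``q`` at x400 magnification.
    """

    counts: tuple  # 4 rows of 4 non-negative ints

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (4, 4):
            raise ValidationError(f"cytology grid must be 4x4, got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("cytology counts must be integers")
            arr = arr.astype(int)
        if (arr < 0).any():
            raise ValidationError("cytology counts must be non-negative")
        object.__setattr__(self, "counts", tuple(map(tuple, arr.tolist())))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class SubpopulationProfile:
    """Relative proportion (%) of each white-cell class; sums to 100."""

    percents: tuple  # aligned with CYTOLOGY_CLASSES

    def __post_init__(self) -> None:
        p = np.asarray(self.percents, dtype=float)
        if p.shape != (4,):
            raise ValidationError("profile needs exactly 4 percentages")
        if (p < 0).any():
            raise ValidationError("percentages must be non-negative")
        if abs(p.sum() - 100.0) > 1e-9:
            raise ValidationError(f"percentages must sum to 100, got {p.sum()!r}")
        object.__setattr__(self, "percents", tuple(p.tolist()))

    def as_dict(self) -> dict:
        return dict(zip(CYTOLOGY_CLASSES, self.percents))


@dataclass
class CSFSample:
    """One ventricular CSF measurement.

    day
        Days since SAH onset (>= 1).
    rbc_csf, wbc_csf
        Cell counts per µL ('/3' convention already applied).
    tp
        Total protein concentration; mg/dL by convention (configurable at
        the cohort level — the unit never enters any computation).
    cum_drainage
        Cumulative EVD drainage volume (mL) at sampling time.
    """

    patient_id: str
    day: float
    rbc_csf: float
    wbc_csf: float
    tp: float
    cytology: Optional[CytologyGrid] = None
    blood: Optional[BloodCount] = None
    cum_drainage: float = 0.0

    def __post_init__(self) -> None:
        if not self.day >= 1:
            raise ValidationError(f"sample day must be >= 1, got {self.day}")
        for name in ("rbc_csf", "wbc_csf", "tp", "cum_drainage"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be a finite non-negative number, got {v}")

    @property
    def cell_index(self) -> Optional[float]:
        """Cell index, or None where it is not computable (absence propagates)."""
        if self.blood is None or self.rbc_csf <= 0:
            return None
        return cell_index(self.wbc_csf, self.rbc_csf, self.blood)

    @property
    def subpopulations(self) -> Optional[SubpopulationProfile]:
        if self.cytology is None or self.cytology.as_array().sum() == 0:
            return None
        return subpopulation_proportions(self.cytology)


@dataclass(frozen=True)
class Complication:
    """A boolean complication label with the day of onset when present.

    Onset for ventriculitis is conventionally counted in days after EVD
    insertion; rebleeding and DCI in days after SAH onset.
    """

    present: bool
    onset_day: Optional[float] = None


@dataclass
class Patient:
    """One SAH patient with ordered serial CSF samples and outcome labels."""

    patient_id: str
    age: float
    sex: str
    rebleeding: Complication
    ventriculitis: Complication
    dci: Complication
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [s.day for s in self.samples]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: sample days must be strictly increasing"
            )
        drains = [s.cum_drainage for s in self.samples]
        if any(b < a for a, b in zip(drains, drains[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: cumulative drainage must be non-decreasing"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def span_days(self) -> float:
        if not self.samples:
            return 0.0
        return self.samples[-1].day - self.samples[0].day

    @property
    def meets_inclusion(self) -> bool:
        """At least 3 samples on different days over a period of more than 7 days."""
        return self.n_samples >= 3 and self.span_days > 7

    def label(self, outcome: str) -> bool:
        comp = getattr(self, outcome, None)
        if not isinstance(comp, Complication):
            raise ValidationError(f"unknown outcome {outcome!r}")
        return comp.present


@dataclass
class Cohort:
    """A list of patients plus convenience tidy-frame views (see io module)."""

    patients: list

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.patients)

    def samples_frame(self):
        from . import io

        return io.samples_to_frame(self)

    def labels_frame(self):
        from . import io

        return io.labels_to_frame(self)


def cell_index(wbc_csf: float, rbc_csf: float, blood: BloodCount) -> float:
    """Cell index = (CSF WBC x blood RBC) / (blood WBC x CSF RBC).

    Dimensionless; ≈1 when the CSF WBC:RBC ratio equals the blood ratio,
    i.e. when CSF cells are explained by blood contamination alone.

    Raises
    ------
    UndefinedValueError
        If ``rbc_csf`` is zero/non-positive or no blood count is available:
        the index is then *not computable*, which must never be conflated
        with an index of zero.
    """
    if blood is None:
        raise UndefinedValueError("cell index requires a paired blood count")
    if rbc_csf is None or not rbc_csf > 0:
        raise UndefinedValueError(
            f"cell index undefined for CSF RBC = {rbc_csf} (division by zero)"
        )
    if wbc_csf < 0:
        raise ValidationError(f"CSF WBC must be non-negative, got {wbc_csf}")
    return (wbc_csf * blood.rbc_blood) / (blood.wbc_blood * rbc_csf)


def chamber_to_per_ul(raw_chamber_count: float) -> float:
    """Convert a raw Fuchs-Rosenthal chamber count to cells per µL.

    The chamber holds 3.2 µL but counts are reported by lab convention as
    '/3' cells, i.e. divided by 3 as an approximate correction to a 1 µL
    standard volume. We reproduce the reporting convention, not the chamber
    geometry.
    """
    if raw_chamber_count is None or raw_chamber_count < 0:
        raise ValidationError(f"chamber count must be >= 0, got {raw_chamber_count}")
    return raw_chamber_count / 3.0


def subpopulation_proportions(grid: CytologyGrid) -> SubpopulationProfile:
    """Relative proportion (%) of each cell class from the 4x4 quadrant grid.

    Per class, the mean count across the four quadrants is taken; the
    proportions are the class means normalised to sum to 100.
    """
    arr = grid.as_array()
    class_means = arr.mean(axis=0)
    total = class_means.sum()
    if total == 0:
        raise UndefinedValueError("no cells seen on the slide; proportions undefined")
    return SubpopulationProfile(tuple(100.0 * class_means / total))


def assign_time_point(day: float) -> Optional[int]:
    """Map a sampling day to protocol time point 1-6, or None beyond day 22.

    Bins: days 1-4, 5-8, 9-11, 12-15, 16-18, 19-22. Non-integer days are
    binned by their floor (the protocol periods are integer-day ranges).
    """
    if day is None or not day >= 1:
        raise ValidationError(f"day must be >= 1, got {day}")
    d = math.floor(day)
    for idx, (lo, hi) in enumerate(TIME_POINT_BINS, start=1):
        if lo <= d <= hi:
            return idx
    return None
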