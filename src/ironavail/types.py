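"""Domain types for population-level iron bioavailability estimation.

The central objects are a :class:`Cohort` of survey participants (intakes,
serum ferritin, inflammation markers), a :class:`RequirementDistribution`
giving absorbed-iron requirements (mg/d) at population percentiles, and the
model outputs: a :class:`PrevalenceCurve` (predicted prevalence of inadequate
intakes versus assumed absorption) and an :class:`AbsorptionProfile`
(estimated dietary absorption versus serum ferritin cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "DataError",
    "Individual",
    "Cohort",
    "ExclusionCriteria",
    "ExclusionReport",
    "GroupSummary",
    "SfCumulativeDistribution",
    "AbsorptionGrid",
    "PrevalenceCurve",
    "AbsorptionProfile",
]

#: Analysis groups; all analyses are stratified by sex and menopausal status.
GROUPS = ("men", "premenopausal", "postmenopausal")

SEXES = ("male", "female")
MENOPAUSAL_STATUSES = ("premenopausal", "postmenopausal", "not_applicable")


class DataError(ValueError):
    """Invalid input data (bad file, broken invariant, contract violation)."""


@dataclass
class Individual:
    """One survey participant.

    Optional fields are ``None`` when not measured — missing is never zero.
    Units: age years, weight kg, bmi kg/m^2, iron intakes mg/d, serum
    ferritin (sf) ug/L, hemoglobin g/dL, CRP mg/L, ACT g/L.
    """

    id: str
    study: str
    sex: str
    iron_intake: float
    menopausal_status: str = "not_applicable"
    age: Optional[float] = None
    weight: Optional[float] = None
    bmi: Optional[float] = None
    iron_intake_meat: Optional[float] = None
    sf: Optional[float] = None
    hemoglobin: Optional[float] = None
    crp: Optional[float] = None
    act: Optional[float] = None
    iron_supplement_user: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DataError(f"individual {self.id!r}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.menopausal_status not in MENOPAUSAL_STATUSES:
            raise DataError(
                f"individual {self.id!r}: menopausal_status must be one of "
                f"{MENOPAUSAL_STATUSES}, got {self.menopausal_status!r}"
            )
        if self.sex == "male" and self.menopausal_status != "not_applicable":
            raise DataError(
                f"individual {self.id!r}: males must have menopausal_status='not_applicable'"
            )
        if self.iron_intake is None or self.iron_intake < 0:
            raise DataError(f"individual {self.id!r}: iron_intake must be >= 0")
        if self.sf is not None and self.sf < 0:
            raise DataError(f"individual {self.id!r}: sf must be >= 0 when present")
        if self.age is not None and self.age < 0:
            raise DataError(f"individual {self.id!r}: age must be >= 0")


@dataclass
class Cohort:
    """A labeled, ordered collection of individuals with provenance notes."""

    label: str
    individuals: list[Individual]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"cohort {self.label!r}: duplicate ids {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def with_note(self, note: str) -> "Cohort":
        return replace(self, provenance=[*self.provenance, note])


@dataclass(frozen=True)
class ExclusionCriteria:
    """Inclusion-pipeline thresholds.

    Participants with raised inflammation markers (CRP > ``crp_max`` mg/L or
    ACT > ``act_max`` g/L; strict inequalities), iron-supplement users, and —
    when ``require_sf`` — those without a serum ferritin measurement are
    excluded, in that fixed order. Individuals with neither inflammation
    marker measured are retained.
    """

    crp_max: float = 5.0
    act_max: float = 0.65
    exclude_supplement_users: bool = True
    require_sf: bool = True

    def __post_init__(self) -> None:
        if self.crp_max <= 0 or self.act_max <= 0:
            raise DataError("exclusion thresholds must be > 0")


@dataclass(frozen=True)
class ExclusionReport:
    """Sequential accounting of the exclusion pipeline."""

    n_input: int
    n_excluded_inflammation: int
    n_excluded_supplements: int
    n_excluded_missing_sf: int
    n_retained: int
    excluded_inflammation_ids: tuple[str, ...] = ()
    excluded_supplement_ids: tuple[str, ...] = ()
    excluded_missing_sf_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = (
            self.n_retained
            + self.n_excluded_inflammation
            + self.n_excluded_supplements
            + self.n_excluded_missing_sf
        )
        if total != self.n_input or min(
            self.n_input,
            self.n_excluded_inflammation,
            self.n_excluded_supplements,
            self.n_excluded_missing_sf,
            self.n_retained,
        ) < 0:
            raise DataError("exclusion counts must be non-negative and sum to n_input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_inflammation": self.n_excluded_inflammation,
            "n_excluded_supplements": self.n_excluded_supplements,
            "n_excluded_missing_sf": self.n_excluded_missing_sf,
            "n_retained": self.n_retained,
            "excluded_inflammation_ids": list(self.excluded_inflammation_ids),
            "excluded_supplement_ids": list(self.excluded_supplement_ids),
            "excluded_missing_sf_ids": list(self.excluded_missing_sf_ids),
        }


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- sample SD (n-1 denominator) per variable for one group.

    ``stats`` maps variable name -> (mean, sd, n over individuals with the
    variable present); a variable absent for everyone is omitted, not zero.
    """

    group: str
    n: int
    stats: dict[str, tuple[float, float, int]]


@dataclass
class SfCumulativeDistribution:
    """Percent of a group with serum ferritin strictly below each cutoff."""

    group: str
    cutoffs: np.ndarray
    prevalence_below: np.ndarray

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.prevalence_below = np.asarray(self.prevalence_below, dtype=float)
        if np.any(np.diff(self.cutoffs) <= 0):
            raise DataError("sf cutoffs must be strictly ascending")
        if np.any(np.diff(self.prevalence_below) < 0):
            raise DataError("prevalence_below must be non-decreasing in cutoff")
        if np.any((self.prevalence_below < 0) | (self.prevalence_below > 100)):
            raise DataError("prevalence_below must lie in [0, 100]")


@dataclass
class AbsorptionGrid:
    """Ascending scale of assumed dietary iron absorption percentages."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DataError("absorption grid needs >= 2 values")
        if np.any(np.diff(self.values) <= 0):
            raise DataError("absorption grid must be strictly ascending")
        if self.values[0] <= 0 and not np.isclose(self.values[0], 0.0):
            raise DataError("absorption values must be >= 0")
        if self.values[-1] > 100:
            raise DataError("absorption values must be <= 100")

    @classmethod
    def default(cls, lo: float = 1.0, hi: float = 40.0, step: float = 0.5) -> "AbsorptionGrid":
        """The default 1-40% scale in 0.5% steps (79 points)."""
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n))


@dataclass
class PrevalenceCurve:
    """Predicted prevalence (%) of inadequate intakes along an absorption grid."""

    group: str
    grid: AbsorptionGrid
    prevalence: np.ndarray

    def __post_init__(self) -> None:
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if self.prevalence.shape != self.grid.values.shape:
            raise DataError("prevalence and grid must have the same length")
        if np.any((self.prevalence < 0) | (self.prevalence > 100)):
            raise DataError("prevalence must lie in [0, 100]")
        if np.any(np.diff(self.prevalence) > 1e-9):
            raise DataError("prevalence must be non-increasing along the absorption grid")


@dataclass
class AbsorptionProfile:
    """Estimated dietary absorption (%) at each serum ferritin cutoff.

    ``clamped`` flags cutoffs where the observed prevalence fell outside the
    span of the prevalence curve and the grid endpoint was returned.
    """

    group: str
    sf_cutoffs: np.ndarray
    absorption: np.ndarray
    clamped: np.ndarray

    def __post_init__(self) -> None:
        self.sf_cutoffs = np.asarray(self.sf_cutoffs, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        self.clamped = np.asarray(self.clamped, dtype=bool)
        if not (self.sf_cutoffs.shape == self.absorption.shape == self.clamped.shape):
            raise DataError("profile arrays must share one shape")
        if np.any(np.diff(self.sf_cutoffs) <= 0):
            raise DataError("sf cutoffs must be strictly ascending")


def as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional")
    return arr
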