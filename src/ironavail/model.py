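"""The bioavailability model: prevalence matching over an absorption scale.

The model estimates population-level dietary iron absorption from two
observables — individual iron intakes and the serum ferritin distribution —
plus an absorbed-iron requirement distribution:

1. For each assumed absorption ``a`` on a scale (default 1-40% in 0.5%
   steps), each individual's absorbed iron is ``intake * a / 100``; the
   probability that this fails to meet requirements is read off the
   requirement percentile grid, and averaging over individuals gives the
   predicted prevalence of inadequate intakes at ``a`` (the full-probability
   approach to nutrient adequacy).
2. The observed prevalence of iron insufficiency is the percent of the group
   with serum ferritin strictly below a chosen cutoff.
3. Setting predicted prevalence equal to observed prevalence and inverting
   the (monotone, non-increasing) prevalence-versus-absorption curve yields
   the estimated dietary absorption at that serum ferritin concentration.

The estimate is population-level by design; no individual absorption values
are produced.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .cohort import sf_cumulative_distribution
from .requirements import RequirementDistribution
from .types import (
    AbsorptionGrid,
    AbsorptionProfile,
    Cohort,
    DataError,
    PrevalenceCurve,
    as_float_array,
)

__all__ = [
    "absorbed_iron",
    "predicted_prevalence",
    "prevalence_curve",
    "InversionResult",
    "invert_prevalence",
    "absorption_at_sf",
    "absorption_profile",
]


def absorbed_iron(intake: float, absorption: float) -> float:
    """Absorbed iron (mg/d) from dietary intake at a fractional absorption %."""
    if intake < 0:
        raise DataError("intake must be >= 0")
    if not 0 <= absorption <= 100:
        raise DataError("absorption must be in [0, 100] percent")
    return intake * absorption / 100.0


def _inadequacy_probabilities(
    dist: RequirementDistribution, absorbed: np.ndarray
) -> np.ndarray:
    """Fraction of requirement grid points strictly above each absorbed value."""
    r = dist.requirements
    n_met = np.searchsorted(r, absorbed, side="right")
    return (r.size - n_met) / r.size


def predicted_prevalence(
    intakes: Sequence[float], dist: RequirementDistribution, absorption: float
) -> float:
    """Predicted prevalence (%) of inadequate intakes at one assumed absorption.

    100 x the mean, over individuals, of the probability that the absorbed
    iron ``intake * absorption / 100`` falls short of requirements.
    """
    intakes = as_float_array(intakes, "intakes")
    if intakes.size == 0:
        raise DataError("predicted_prevalence: empty intakes")
    if np.any(intakes < 0):
        raise DataError("intakes must be >= 0")
    absorbed = intakes * absorption / 100.0
    return 100.0 * float(_inadequacy_probabilities(dist, absorbed).mean())


def prevalence_curve(
    intakes: Sequence[float],
    dist: RequirementDistribution,
    grid: AbsorptionGrid | None = None,
    group: str = "",
) -> PrevalenceCurve:
    """Predicted prevalence of inadequacy at every absorption on the grid.

    Non-increasing in absorption by construction: raising absorption raises
    everyone's absorbed iron, which can only lower inadequacy.
    """
    grid = grid or AbsorptionGrid.default()
    intakes = as_float_array(intakes, "intakes")
    if intakes.size == 0:
        raise DataError("prevalence_curve: empty intakes")
    if np.any(intakes < 0):
        raise DataError("intakes must be >= 0")
    absorbed = intakes[:, None] * grid.values[None, :] / 100.0
    prevalence = 100.0 * _inadequacy_probabilities(dist, absorbed).mean(axis=0)
    return PrevalenceCurve(group=group or dist.group, grid=grid, prevalence=prevalence)


class InversionResult(NamedTuple):
    """Absorption estimate plus a flag marking a clamped (out-of-range) target."""

    absorption: float
    clamped: bool


def invert_prevalence(curve: PrevalenceCurve, target: float) -> InversionResult:
    """Absorption at which the prevalence curve crosses a target prevalence.

    Linear interpolation between the bracketing grid points; if a flat
    stretch of the curve ties the target exactly, the smallest absorption is
    returned. Targets above the curve's maximum (or below its minimum) clamp
    to the corresponding grid endpoint and are flagged.
    """
    if not 0 <= target <= 100:
        raise DataError("target prevalence must be in [0, 100]")
    a = curve.grid.values
    p = curve.prevalence  # validated non-increasing
    if target > p[0]:
        return InversionResult(float(a[0]), True)
    if target < p[-1]:
        return InversionResult(float(a[-1]), True)
    for i in range(p.size):
        if np.isclose(p[i], target, rtol=0.0, atol=1e-9):
            return InversionResult(float(a[i]), False)
        if p[i] < target:
            # bracketed: p[i-1] > target > p[i]
            frac = (p[i - 1] - target) / (p[i - 1] - p[i])
            return InversionResult(float(a[i - 1] + frac * (a[i] - a[i - 1])), False)
    raise DataError("invert_prevalence: target not bracketed (invalid curve)")  # pragma: no cover


def absorption_at_sf(
    group_cohort: Cohort,
    dist: RequirementDistribution,
    sf_cutoff: float,
    grid: AbsorptionGrid | None = None,
) -> InversionResult:
    """Estimated dietary absorption (%) at one serum ferritin cutoff.

    Matches the observed prevalence of serum ferritin strictly below the
    cutoff to the predicted prevalence of inadequate intakes, and inverts.
    The cohort must already be filtered (every member has SF measured) and
    single-group.
    """
    cdf = sf_cumulative_distribution(group_cohort, [sf_cutoff])
    p_obs = float(cdf.prevalence_below[0])
    intakes = [ind.iron_intake for ind in group_cohort]
    curve = prevalence_curve(intakes, dist, grid, group=group_cohort.label)
    return invert_prevalence(curve, p_obs)


def absorption_profile(
    group_cohort: Cohort,
    dist: RequirementDistribution,
    sf_cutoffs: Iterable[float],
    grid: AbsorptionGrid | None = None,
    group: str = "",
) -> AbsorptionProfile:
    """Absorption estimates across ascending serum ferritin cutoffs.

    One prevalence curve is computed and reused for all cutoffs. The profile
    is non-increasing in the cutoff wherever no point is clamped: higher
    cutoffs mean higher observed insufficiency prevalence, which the
    monotone curve maps to lower absorption.
    """
    cutoffs = np.asarray(list(sf_cutoffs), dtype=float)
    cdf = sf_cumulative_distribution(group_cohort, cutoffs)
    intakes = [ind.iron_intake for ind in group_cohort]
    curve = prevalence_curve(intakes, dist, grid, group=group_cohort.label)
    results = [invert_prevalence(curve, float(p)) for p in cdf.prevalence_below]
    return AbsorptionProfile(
        group=group or group_cohort.label,
        sf_cutoffs=cutoffs,
        absorption=np.array([r.absorption for r in results]),
        clamped=np.array([r.clamped for r in results]),
    )
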