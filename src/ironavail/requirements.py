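"""Absorbed-iron requirement distributions on population percentile grids.

Physiological iron requirements vary widely across a population (menstrual
blood loss makes the premenopausal distribution strongly right-skewed), so a
single average requirement is not enough to judge adequacy: the model works
with the full requirement distribution, represented as its quantile function
— absorbed iron (mg/d) at each population percentile — interpolated to a
fine grid of half-percentiles (0.5, 1.0, ..., 99.5; 199 points).

Published requirement tables (e.g., the Institute of Medicine percentile
tables) are consumed as CSV input data; they are not re-derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .types import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "FINE_PERCENTILES",
    "RequirementDistribution",
    "load_requirement_table",
    "write_requirement_table",
    "interpolate_to_half_percentiles",
    "probability_of_inadequacy",
]

#: The fine half-percentile grid: 0.5, 1.0, ..., 99.5 (199 points).
FINE_PERCENTILES: np.ndarray = np.round(np.arange(0.5, 100.0, 0.5), 1)


@dataclass
class RequirementDistribution:
    """Absorbed-iron requirement (mg/d) at ascending population percentiles.

    A valid instance is a quantile function: percentiles strictly ascending
    in (0, 100), requirements non-negative and non-decreasing.
    """

    group: str
    percentiles: np.ndarray
    requirements: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.requirements = np.asarray(self.requirements, dtype=float)
        if self.percentiles.shape != self.requirements.shape or self.percentiles.ndim != 1:
            raise DataError("percentiles and requirements must be 1-D arrays of equal length")
        if self.percentiles.size < 2:
            raise DataError("a requirement distribution needs >= 2 percentile points")
        if np.any((self.percentiles <= 0) | (self.percentiles >= 100)):
            bad = self.percentiles[(self.percentiles <= 0) | (self.percentiles >= 100)]
            raise DataError(f"percentiles must lie strictly in (0, 100); got {bad[:5]}")
        diffs = np.diff(self.percentiles)
        if np.any(diffs <= 0):
            raise DataError("percentiles must be strictly ascending (no duplicates)")
        if np.any(self.requirements < 0):
            raise DataError("requirements must be non-negative")
        dec = np.where(np.diff(self.requirements) < 0)[0]
        if dec.size:
            i = int(dec[0])
            raise DataError(
                "requirements must be non-decreasing along percentiles; "
                f"row {i + 1} -> {i + 2}: {self.requirements[i]} -> {self.requirements[i + 1]}"
            )

    @property
    def is_fine_grid(self) -> bool:
        return self.percentiles.size == FINE_PERCENTILES.size and np.allclose(
            self.percentiles, FINE_PERCENTILES
        )


def load_requirement_table(path: str | Path, group: str = "") -> RequirementDistribution:
    """Read a requirement CSV (columns ``percentile``, ``requirement_mg_d``).

    Lines beginning with ``#`` carry provenance and are kept in ``source``.
    Validation errors (non-monotone requirements, percentiles outside
    (0,100), duplicates) are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"requirement table not found: {path}")
    comments = [
        line[1:].strip()
        for line in path.read_text().splitlines()
        if line.startswith("#")
    ]
    df = pd.read_csv(path, comment="#")
    for col in ("percentile", "requirement_mg_d"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    if len(df) < 2:
        raise DataError(f"{path}: need >= 2 rows")
    source = "; ".join(comments) if comments else str(path)
    return RequirementDistribution(
        group=group or path.stem,
        percentiles=df["percentile"].to_numpy(dtype=float),
        requirements=df["requirement_mg_d"].to_numpy(dtype=float),
        source=source,
    )


def write_requirement_table(dist: RequirementDistribution, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if dist.source:
            fh.write(f"# {dist.source}\n")
        fh.write(f"# group: {dist.group}\n")
        pd.DataFrame(
            {"percentile": dist.percentiles, "requirement_mg_d": dist.requirements}
        ).to_csv(fh, index=False)


def interpolate_to_half_percentiles(
    coarse: RequirementDistribution, method: str = "linear"
) -> RequirementDistribution:
    """Interpolate a coarse percentile table to the 199-point fine grid.

    Piecewise-linear in the percentile domain by default (monotone by
    construction on monotone input); ``method='pchip'`` selects a monotone
    cubic. Fine percentiles outside the coarse span are clamped to the
    nearest endpoint value, with a warning — no tail behavior is invented.
    Values at the coarse knots are reproduced exactly; input already on the
    fine grid is returned unchanged.
    """
    if coarse.is_fine_grid:
        return coarse
    p, r = coarse.percentiles, coarse.requirements
    if FINE_PERCENTILES[0] < p[0] or FINE_PERCENTILES[-1] > p[-1]:
        logger.warning(
            "requirement table for %s spans [%g, %g]; clamping flat to cover [0.5, 99.5]",
            coarse.group,
            p[0],
            p[-1],
        )
    if method == "linear":
        fine = np.interp(FINE_PERCENTILES, p, r)
    elif method == "pchip":
        interp = PchipInterpolator(p, r, extrapolate=False)
        fine = interp(np.clip(FINE_PERCENTILES, p[0], p[-1]))
    else:
        raise DataError(f"unknown interpolation method {method!r}")
    # guard against round-off dips breaking monotonicity downstream
    fine = np.maximum.accumulate(fine)
    return RequirementDistribution(
        group=coarse.group,
        percentiles=FINE_PERCENTILES.copy(),
        requirements=fine,
        source=f"{coarse.source} (interpolated to half-percentiles, {method})".strip(),
    )


def probability_of_inadequacy(dist: RequirementDistribution, absorbed: float) -> float:
    """Probability that an absorbed-iron supply fails to meet requirements.

    Step-function evaluation over the percentile grid: the fraction of grid
    points whose requirement strictly exceeds ``absorbed``. A requirement
    exactly equal to the supply counts as met, so the probability is 0 at or
    above the top grid value and 1 below the bottom one.
    """
    if absorbed < 0:
        raise DataError("absorbed iron must be >= 0")
    r = dist.requirements
    # count of requirements > absorbed, via the sorted (monotone) grid
    n_met = int(np.searchsorted(r, absorbed, side="right"))
    return (r.size - n_met) / r.size
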