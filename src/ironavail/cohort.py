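"""Reading, filtering, stratifying, pooling and summarizing survey cohorts.

Implements the inclusion pipeline used to prepare nutrition-survey data for
the bioavailability model: exclude participants with raised inflammation
markers (serum ferritin is an acute-phase reactant and overstates iron
stores during inflammation), exclude iron-supplement users (supplemental
iron cannot be apportioned into the measured intake), and require a serum
ferritin measurement. Analyses are stratified by sex and menopausal status
into three groups: men, premenopausal women, postmenopausal women.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    GROUPS,
    Cohort,
    DataError,
    ExclusionCriteria,
    ExclusionReport,
    GroupSummary,
    Individual,
    SfCumulativeDistribution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "apply_exclusions",
    "stratify",
    "group_of",
    "combine_cohorts",
    "group_summary",
    "pooled_mean",
    "sf_cumulative_distribution",
]

#: Canonical CSV column -> Individual field. Files with other headers are
#: read by passing a ``column_map`` with the same field names as values.
COHORT_COLUMNS: dict[str, str] = {
    "id": "id",
    "study": "study",
    "sex": "sex",
    "menopausal_status": "menopausal_status",
    "age": "age",
    "weight_kg": "weight",
    "bmi": "bmi",
    "iron_intake_mg_d": "iron_intake",
    "iron_meat_mg_d": "iron_intake_meat",
    "sf_ug_l": "sf",
    "hb_g_dl": "hemoglobin",
    "crp_mg_l": "crp",
    "act_g_l": "act",
    "iron_supplement": "iron_supplement_user",
}

_MANDATORY_FIELDS = ("id", "sex", "iron_intake")
_NUMERIC_FIELDS = (
    "age",
    "weight",
    "bmi",
    "iron_intake",
    "iron_intake_meat",
    "sf",
    "hemoglobin",
    "crp",
    "act",
)

#: Per-variable summary columns of the descriptive table.
SUMMARY_VARIABLES = (
    "age",
    "weight",
    "bmi",
    "hemoglobin",
    "sf",
    "iron_intake",
    "iron_intake_meat",
)


def _parse_float(cell: str, field: str, row: int) -> Optional[float]:
    if cell is None or cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise DataError(f"row {row}: cannot parse {field}={cell!r} as a number") from exc


def _parse_bool(cell: str, row: int) -> Optional[bool]:
    if cell is None or cell == "":
        return None
    low = cell.strip().lower()
    if low in ("true", "1", "yes", "y"):
        return True
    if low in ("false", "0", "no", "n"):
        return False
    raise DataError(f"row {row}: cannot parse iron_supplement={cell!r} as a boolean")


def read_cohort(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    label: Optional[str] = None,
) -> Cohort:
    """Read a cohort from a CSV file (UTF-8, header row, empty cell = missing).

    ``column_map`` maps file column names to :class:`Individual` field names;
    by default the canonical header (:data:`COHORT_COLUMNS`) is expected.
    Columns for ``id``, ``sex`` and ``iron_intake`` are mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"cohort file not found: {path}")
    cmap = dict(column_map) if column_map is not None else dict(COHORT_COLUMNS)

    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    field_to_col = {f: c for c, f in cmap.items() if c in df.columns}
    for fieldname in _MANDATORY_FIELDS:
        if fieldname not in field_to_col:
            raise DataError(
                f"{path}: missing mandatory column for field {fieldname!r} "
                f"(expected column {_expected_column(cmap, fieldname)!r})"
            )

    individuals: list[Individual] = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # 1-based with header line
        get = lambda f: rec.get(field_to_col[f], "").strip() if f in field_to_col else ""
        sex = get("sex").lower()
        status = get("menopausal_status").lower() or "not_applicable"
        kwargs: dict = {
            "id": get("id"),
            "study": get("study") or (label or path.stem),
            "sex": sex,
            "menopausal_status": status,
            "iron_supplement_user": _parse_bool(get("iron_supplement_user"), row),
        }
        for f in _NUMERIC_FIELDS:
            kwargs[f] = _parse_float(get(f), f, row)
        if kwargs["iron_intake"] is None:
            raise DataError(f"row {row}: iron_intake is empty")
        individuals.append(Individual(**kwargs))

    return Cohort(
        label=label or path.stem,
        individuals=individuals,
        provenance=[f"read {len(individuals)} rows from {path}"],
    )


def _expected_column(cmap: Mapping[str, str], fieldname: str) -> str:
    for col, f in cmap.items():
        if f == fieldname:
            return col
    return fieldname


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort as a DataFrame in the canonical CSV column layout."""
    rows = []
    for ind in cohort:
        rows.append(
            {
                "id": ind.id,
                "study": ind.study,
                "sex": ind.sex,
                "menopausal_status": ind.menopausal_status,
                "age": ind.age,
                "weight_kg": ind.weight,
                "bmi": ind.bmi,
                "iron_intake_mg_d": ind.iron_intake,
                "iron_meat_mg_d": ind.iron_intake_meat,
                "sf_ug_l": ind.sf,
                "hb_g_dl": ind.hemoglobin,
                "crp_mg_l": ind.crp,
                "act_g_l": ind.act,
                "iron_supplement": ind.iron_supplement_user,
            }
        )
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical cohort CSV (empty cells for missing values)."""
    df = cohort_to_frame(cohort)
    df["iron_supplement"] = df["iron_supplement"].map(
        {True: "true", False: "false"}, na_action="ignore"
    )
    df.to_csv(path, index=False, na_rep="")


def apply_exclusions(
    cohort: Cohort, criteria: ExclusionCriteria = ExclusionCriteria()
) -> tuple[Cohort, ExclusionReport]:
    """Run the sequential exclusion pipeline.

    Stage order is fixed: (1) inflammation — excluded iff CRP is measured and
    strictly exceeds ``crp_max``, OR ACT is measured and strictly exceeds
    ``act_max`` (participants with neither marker measured are retained);
    (2) iron-supplement users; (3) missing serum ferritin. The report counts
    each participant once, at the first stage that removed them.
    """
    if len(cohort) == 0:
        raise DataError("apply_exclusions: cohort is empty")
    inflamed: list[str] = []
    supplements: list[str] = []
    missing_sf: list[str] = []
    kept: list[Individual] = []
    for ind in cohort:
        if (ind.crp is not None and ind.crp > criteria.crp_max) or (
            ind.act is not None and ind.act > criteria.act_max
        ):
            inflamed.append(ind.id)
        elif criteria.exclude_supplement_users and ind.iron_supplement_user is True:
            supplements.append(ind.id)
        elif criteria.require_sf and ind.sf is None:
            missing_sf.append(ind.id)
        else:
            kept.append(ind)

    report = ExclusionReport(
        n_input=len(cohort),
        n_excluded_inflammation=len(inflamed),
        n_excluded_supplements=len(supplements),
        n_excluded_missing_sf=len(missing_sf),
        n_retained=len(kept),
        excluded_inflammation_ids=tuple(inflamed),
        excluded_supplement_ids=tuple(supplements),
        excluded_missing_sf_ids=tuple(missing_sf),
    )
    note = (
        f"exclusions (crp>{criteria.crp_max}, act>{criteria.act_max}, "
        f"supplements={criteria.exclude_supplement_users}, require_sf={criteria.require_sf}): "
        f"{report.n_input} -> {report.n_retained}"
    )
    filtered = Cohort(label=cohort.label, individuals=kept, provenance=[*cohort.provenance, note])
    return filtered, report


def group_of(ind: Individual) -> str:
    """Analysis group of one individual; raises for unclassified women."""
    if ind.sex == "male":
        return "men"
    if ind.menopausal_status in ("premenopausal", "postmenopausal"):
        return ind.menopausal_status
    raise DataError(
        f"individual {ind.id!r}: female without menopausal classification "
        "(menopausal_status must be premenopausal or postmenopausal)"
    )


def stratify(cohort: Cohort) -> dict[str, Cohort]:
    """Partition into {men, premenopausal, postmenopausal}, preserving order.

    Menopausal status is an input classification, never inferred from age;
    a female with status ``not_applicable`` is a hard error listing the ids.
    """
    unclassified = [
        ind.id
        for ind in cohort
        if ind.sex == "female" and ind.menopausal_status == "not_applicable"
    ]
    if unclassified:
        raise DataError(
            f"cohort {cohort.label!r}: females without menopausal classification: "
            f"{unclassified[:10]}"
        )
    out: dict[str, Cohort] = {}
    for group in GROUPS:
        members = [ind for ind in cohort if group_of(ind) == group]
        out[group] = Cohort(
            label=f"{cohort.label}/{group}",
            individuals=members,
            provenance=[*cohort.provenance, f"stratified: {group} (n={len(members)})"],
        )
    return out


def combine_cohorts(cohorts: Sequence[Cohort], label: str = "combined") -> Cohort:
    """Concatenate cohorts; colliding ids are disambiguated by label prefix."""
    if not cohorts:
        raise DataError("combine_cohorts: empty input list")
    seen: set[str] = set()
    merged: list[Individual] = []
    from dataclasses import replace

    for c in cohorts:
        for ind in c:
            new_id = ind.id
            if new_id in seen:
                new_id = f"{c.label}:{ind.id}"
            seen.add(new_id)
            merged.append(replace(ind, id=new_id) if new_id != ind.id else ind)
    provenance = [f"combined from: {', '.join(c.label for c in cohorts)}"]
    return Cohort(label=label, individuals=merged, provenance=provenance)


def group_summary(cohort: Cohort) -> list[GroupSummary]:
    """Descriptive statistics (mean, sample SD, n) per group per variable.

    SDs use the n-1 denominator; each variable is summarized over the
    individuals in whom it was measured, so n can differ across variables.
    Empty groups are omitted with a logged note.
    """
    summaries: list[GroupSummary] = []
    for group, sub in stratify(cohort).items():
        if len(sub) == 0:
            logger.info("group_summary: group %s is empty, omitted", group)
            continue
        stats: dict[str, tuple[float, float, int]] = {}
        for var in SUMMARY_VARIABLES:
            vals = np.array([getattr(ind, var) for ind in sub if getattr(ind, var) is not None])
            if vals.size == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            stats[var] = (float(np.mean(vals)), sd, int(vals.size))
        summaries.append(GroupSummary(group=group, n=len(sub), stats=stats))
    return summaries


def pooled_mean(per_study: Sequence[tuple[float, int]]) -> float:
    """n-weighted pooled mean across studies: sum(n_i * m_i) / sum(n_i)."""
    if not per_study:
        raise DataError("pooled_mean: empty input")
    if any(n < 1 for _, n in per_study):
        raise DataError("pooled_mean: every study must have n >= 1")
    num = sum(n * m for m, n in per_study)
    den = sum(n for _, n in per_study)
    return num / den


def sf_cumulative_distribution(
    cohort: Cohort, cutoffs: Iterable[float], group: Optional[str] = None
) -> SfCumulativeDistribution:
    """Percent of the cohort with serum ferritin strictly below each cutoff.

    The boundary value SF == cutoff counts as sufficient (not below); an
    individual without a serum ferritin measurement is an error — the
    exclusion pipeline must run first.
    """
    cutoffs = np.asarray(list(cutoffs), dtype=float)
    if np.any(np.diff(cutoffs) <= 0):
        raise DataError("cutoffs must be strictly ascending")
    missing = [ind.id for ind in cohort if ind.sf is None]
    if missing:
        raise DataError(f"individuals without serum ferritin: {missing[:10]} (filter first)")
    if len(cohort) == 0:
        raise DataError("sf_cumulative_distribution: empty cohort")
    sf = np.array([ind.sf for ind in cohort], dtype=float)
    prevalence = 100.0 * (sf[:, None] < cutoffs[None, :]).mean(axis=0)
    return SfCumulativeDistribution(
        group=group or cohort.label, cutoffs=cutoffs, prevalence_below=prevalence
    )
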