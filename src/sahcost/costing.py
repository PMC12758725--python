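"""The time-driven activity-based costing engine.

Cost of an activity occurrence = minutes / 60 x headcount x hourly
capacity cost rate of the profession performing it.  Physician occurrences
can be repriced at a seniority grade (resident / specialist / trainer) for
the scenario analysis; nurses and radiographers always carry their mean
survey rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .expansion import (
    ALL_PATHWAYS,
    ExpandedPathway,
    PathwayKey,
    expand_pathway,
    person_minutes_by_profession,
)
from .parameters import Profession, StudyConfig, WageTable

__all__ = [
    "CostBreakdown",
    "DifferenceTable",
    "activity_cost",
    "pathway_cost",
    "arm_difference",
    "results_tables",
]

GRADE_NAMES = ("resident", "specialist", "trainer")


@dataclass(frozen=True)
class CostBreakdown:
    pathway: PathwayKey
    per_profession: Mapping[Profession, float]
    total: float


@dataclass(frozen=True)
class DifferenceTable:
    """Cost of the no-clazosentan arm minus the clazosentan arm."""

    modality: str
    svsp: bool
    per_profession: Mapping[Profession, float]
    per_grade: Mapping[str, float]
    total: float


def activity_cost(minutes: float, headcount: int, rate: float) -> float:
    """Labour cost in yen of one occurrence: minutes/60 x headcount x rate."""
    if minutes <= 0:
        raise ValueError(f"minutes must be positive, got {minutes}")
    if headcount < 1:
        raise ValueError(f"headcount must be >= 1, got {headcount}")
    if rate <= 0:
        raise ValueError(f"hourly rate must be positive, got {rate}")
    return minutes / 60.0 * headcount * rate


def _rates(wages: WageTable, grade: str = "mean") -> dict[Profession, float]:
    rates = {p: wages.mean_rate(p) for p in Profession}
    if grade != "mean":
        rates[Profession.PHYSICIAN] = wages.grade_rate(grade)
    return rates


def pathway_cost(
    pathway: ExpandedPathway, wages: WageTable, grade: str = "mean"
) -> CostBreakdown:
    """Total labour cost of one expanded pathway, by profession.

    ``grade`` selects the physician rate ("mean" or a seniority grade);
    nurse and radiographer occurrences are always priced at their mean
    survey rates.
    """
    rates = _rates(wages, grade)
    per_prof = {p: 0.0 for p in Profession}
    for occ in pathway.occurrences:
        per_prof[occ.profession] += activity_cost(
            occ.minutes, occ.headcount, rates[occ.profession]
        )
    return CostBreakdown(
        pathway=pathway.key,
        per_profession=per_prof,
        total=sum(per_prof.values()),
    )


def arm_difference(
    config: StudyConfig, modality: str, svsp: bool, grade: str = "mean"
) -> DifferenceTable:
    """Between-arm cost difference (no clazosentan minus clazosentan) for
    one modality and vasospasm stratum, decomposed by profession, with the
    physician difference additionally repriced at every seniority grade."""
    minus = expand_pathway(config, PathwayKey(modality, claz=False, svsp=svsp))
    plus = expand_pathway(config, PathwayKey(modality, claz=True, svsp=svsp))
    cost_minus = pathway_cost(minus, config.wages, grade)
    cost_plus = pathway_cost(plus, config.wages, grade)
    per_prof = {
        p: cost_minus.per_profession[p] - cost_plus.per_profession[p]
        for p in Profession
    }
    # grade repricing is linear in the physician person-minute difference
    pm_minus = person_minutes_by_profession(minus)[Profession.PHYSICIAN]
    pm_plus = person_minutes_by_profession(plus)[Profession.PHYSICIAN]
    minutes_diff = pm_minus - pm_plus
    per_grade = {
        name: minutes_diff / 60.0 * config.wages.grade_rate(name)
        for name in GRADE_NAMES
    }
    return DifferenceTable(
        modality=modality,
        svsp=svsp,
        per_profession=per_prof,
        per_grade=per_grade,
        total=cost_minus.total - cost_plus.total,
    )


def results_tables(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """All deterministic result tables as tidy DataFrames.

    ``totals``: total cost and between-arm difference for each of the
    eight strata. ``profession_differences``: between-arm differences per
    profession. ``grade_differences``: the physician difference repriced
    at each seniority grade.
    """
    rows = []
    for key in ALL_PATHWAYS:
        breakdown = pathway_cost(expand_pathway(config, key), config.wages)
        diff = arm_difference(config, key.modality, key.svsp)
        rows.append(
            {
                "stratum": "svsp+" if key.svsp else "svsp-",
                "modality": key.modality,
                "arm": "claz+" if key.claz else "claz-",
                "total": round(breakdown.total, 2),
                "difference": round(diff.total, 2),
                **{
                    p.value: round(breakdown.per_profession[p], 2)
                    for p in Profession
                },
            }
        )
    totals = pd.DataFrame(rows)

    prof_rows, grade_rows = [], []
    for svsp in (False, True):
        for modality in ("coiling", "clipping"):
            diff = arm_difference(config, modality, svsp)
            stratum = "svsp+" if svsp else "svsp-"
            prof_rows.append(
                {
                    "stratum": stratum,
                    "modality": modality,
                    **{
                        p.value: round(diff.per_profession[p], 2)
                        for p in Profession
                    },
                }
            )
            grade_rows.append(
                {
                    "stratum": stratum,
                    "modality": modality,
                    **{g: round(diff.per_grade[g], 2) for g in GRADE_NAMES},
                }
            )
    return {
        "totals": totals,
        "profession_differences": pd.DataFrame(prof_rows),
        "grade_differences": pd.DataFrame(grade_rows),
    }
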