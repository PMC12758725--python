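"""Turn the care-process map into explicit per-day activity occurrences.

A pathway is one stratum of the model: surgical modality (coiling or
clipping) x clazosentan arm x symptomatic-vasospasm status.  Expansion
resolves each activity's day schedule against the phase windows of that
stratum, applies the arm/modality applicability filters, and yields one
:class:`Occurrence` per (activity, day).  Deterministic analyses use the
mode of each activity's triangular time; the sensitivity analysis passes
sampled times through the same machinery.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .parameters import (
    ActivityRule,
    ArmCondition,
    ModalityCondition,
    Phase,
    Profession,
    ScheduleKind,
    StudyConfig,
    Windows,
)

__all__ = [
    "PathwayKey",
    "Occurrence",
    "ExpandedPathway",
    "ALL_PATHWAYS",
    "expand_pathway",
    "person_minutes_by_profession",
    "dump_expansion",
]

MODALITIES = ("coiling", "clipping")


@dataclass(frozen=True)
class PathwayKey:
    """One of the eight strata: modality x clazosentan x vasospasm."""

    modality: str  # "coiling" | "clipping"
    claz: bool
    svsp: bool

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality: {self.modality!r}")

    def label(self) -> str:
        return (
            f"{self.modality}/claz{'+' if self.claz else '-'}"
            f"/svsp{'+' if self.svsp else '-'}"
        )


ALL_PATHWAYS: tuple[PathwayKey, ...] = tuple(
    PathwayKey(m, c, s)
    for m in MODALITIES
    for s in (False, True)
    for c in (False, True)
)


@dataclass(frozen=True)
class Occurrence:
    activity_id: str
    day: int
    minutes: float
    headcount: int
    profession: Profession


@dataclass(frozen=True)
class ExpandedPathway:
    key: PathwayKey
    occurrences: tuple[Occurrence, ...]


def _arm_applies(arm: ArmCondition, claz: bool) -> bool:
    if arm is ArmCondition.BOTH:
        return True
    return claz if arm is ArmCondition.CLAZ_PLUS_ONLY else not claz


def _modality_applies(cond: ModalityCondition, modality: str) -> bool:
    if cond is ModalityCondition.BOTH:
        return True
    return modality == ("coiling" if cond is ModalityCondition.COILING_ONLY else "clipping")


def _phase_window(phase: Phase, windows: Windows, svsp: bool) -> tuple[int, int] | None:
    """Inclusive day window the phase occupies in this stratum, or None."""
    if phase is Phase.DAY0:
        return (0, 0)
    if phase is Phase.SMOOTH:
        return windows.smooth_with_spasm if svsp else windows.smooth_no_spasm
    return windows.spasm if svsp else None


def resolve_days(rule: ActivityRule, windows: Windows, svsp: bool) -> list[int]:
    """Days on which ``rule`` occurs in a stratum with the given vasospasm
    status; scheduled days outside the phase window are clipped away."""
    window = _phase_window(rule.phase, windows, svsp)
    if window is None:
        return []
    lo, hi = window
    kind = rule.schedule.kind
    if kind is ScheduleKind.DAY_ZERO:
        return [0]
    if kind is ScheduleKind.DAILY_OVER_WINDOW:
        return list(range(lo, hi + 1))
    if kind is ScheduleKind.EXPLICIT_DAYS:
        return [d for d in rule.schedule.days if lo <= d <= hi]
    # first_n_days, counted from the window start
    n = rule.schedule.n or 0
    return [d for d in range(lo, min(lo + n, hi + 1))]


def expand_pathway(
    config: StudyConfig,
    key: PathwayKey,
    times: Mapping[str, float] | None = None,
) -> ExpandedPathway:
    """Enumerate every (activity, day) occurrence of one stratum.

    ``times`` overrides the minutes used per activity id (the sensitivity
    analysis passes sampled draws); by default each occurrence carries the
    mode of the activity's triangular time.  The enumeration is
    deterministic: activities in config order, days ascending.
    """
    occurrences: list[Occurrence] = []
    for a in config.activities:
        if not _arm_applies(a.arm, key.claz):
            continue
        if not _modality_applies(a.modality, key.modality):
            continue
        minutes = times[a.id] if times is not None else a.time.mode
        for day in resolve_days(a, config.windows, key.svsp):
            occurrences.append(
                Occurrence(
                    activity_id=a.id,
                    day=day,
                    minutes=minutes,
                    headcount=a.headcount,
                    profession=a.profession,
                )
            )
    return ExpandedPathway(key=key, occurrences=tuple(occurrences))


def person_minutes_by_profession(
    pathway: ExpandedPathway,
) -> dict[Profession, float]:
    """Sum minutes x headcount per profession (zero for absent professions)."""
    totals: dict[Profession, float] = {p: 0.0 for p in Profession}
    for occ in pathway.occurrences:
        totals[occ.profession] += occ.minutes * occ.headcount
    return totals


def dump_expansion(pathways: Iterable[ExpandedPathway], path: str | Path) -> None:
    """Audit dump: one CSV row per occurrence across the given pathways."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pathway", "day", "activity_id", "profession", "headcount", "minutes"]
        )
        for pw in pathways:
            for occ in pw.occurrences:
                writer.writerow(
                    [pw.key.label(), occ.day, occ.activity_id,
                     occ.profession.value, occ.headcount, occ.minutes]
                )
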