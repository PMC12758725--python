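"""Model inputs for the aSAH labour-costing model.

Every quantity the model consumes lives here: the care-process activity
table (triangular activity times in minutes, profession, headcount, phase
and day schedule, arm/modality applicability), the hourly wage table from
the national wage-structure survey (mean rates, age-band distributions and
physician seniority grades), the symptomatic-vasospasm probabilities per
(surgical modality, clazosentan arm), and the acute-phase day windows.

The packaged study parameters ship as a YAML resource and load through
:func:`builtin_parameters`.  User configurations load through
:func:`load_study_config` (YAML, or a CSV bundle) and are checked by
:func:`validate_parameters`, which returns violations rather than raising
so a config can be reported on in full.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Profession",
    "ArmCondition",
    "ModalityCondition",
    "Phase",
    "TriangularMinutes",
    "ScheduleRule",
    "ActivityRule",
    "WageBand",
    "PhysicianGrade",
    "WageTable",
    "DecisionProbabilities",
    "Windows",
    "StudyConfig",
    "Violation",
    "builtin_parameters",
    "load_study_config",
    "save_study_config",
    "validate_parameters",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a study configuration cannot be parsed or is invalid."""


class Profession(str, enum.Enum):
    PHYSICIAN = "physician"
    NURSE = "nurse"
    RADIOGRAPHER = "radiographer"


class ArmCondition(str, enum.Enum):
    BOTH = "both"
    CLAZ_PLUS_ONLY = "claz_plus_only"
    CLAZ_MINUS_ONLY = "claz_minus_only"


class ModalityCondition(str, enum.Enum):
    BOTH = "both"
    COILING_ONLY = "coiling_only"
    CLIPPING_ONLY = "clipping_only"


class Phase(str, enum.Enum):
    """Which segment of the acute stay an activity belongs to.

    ``DAY0`` covers admission-day diagnostics, the operation and immediate
    post-treatment care; ``SMOOTH`` the uncomplicated recovery days;
    ``SPASM`` the rescue-therapy days that replace smooth care when
    symptomatic vasospasm occurs.
    """

    DAY0 = "day0"
    SMOOTH = "smooth"
    SPASM = "spasm"


@dataclass(frozen=True)
class TriangularMinutes:
    """Triangular activity-time distribution in minutes (lower, mode, upper)."""

    mode: float
    lower: float
    upper: float

    @classmethod
    def from_mode(cls, mode: float) -> "TriangularMinutes":
        """Default uncertainty rule: half the mode to twice the mode."""
        return cls(mode=mode, lower=mode / 2.0, upper=2.0 * mode)

    @property
    def mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0


class ScheduleKind(str, enum.Enum):
    DAY_ZERO = "day_zero"
    DAILY_OVER_WINDOW = "daily_over_window"
    EXPLICIT_DAYS = "explicit_days"
    FIRST_N_DAYS = "first_n_days"


@dataclass(frozen=True)
class ScheduleRule:
    """When an activity happens.

    ``day_zero``: once, on the admission/operation day.
    ``daily_over_window``: every day of the phase window it belongs to.
    ``explicit_days``: on the listed days, clipped to the phase window.
    ``first_n_days``: on the first ``n`` days counted from the start of the
    phase window, clipped to that window (the "7 days" style entries).
    """

    kind: ScheduleKind
    days: tuple[int, ...] = ()
    n: int | None = None

    @staticmethod
    def day_zero() -> "ScheduleRule":
        return ScheduleRule(ScheduleKind.DAY_ZERO)

    @staticmethod
    def daily() -> "ScheduleRule":
        return ScheduleRule(ScheduleKind.DAILY_OVER_WINDOW)

    @staticmethod
    def on_days(*days: int) -> "ScheduleRule":
        return ScheduleRule(ScheduleKind.EXPLICIT_DAYS, days=tuple(days))

    @staticmethod
    def first_days(n: int) -> "ScheduleRule":
        return ScheduleRule(ScheduleKind.FIRST_N_DAYS, n=n)


@dataclass(frozen=True)
class ActivityRule:
    """One row of the care-process map."""

    id: str
    label: str
    time: TriangularMinutes
    profession: Profession
    headcount: int
    phase: Phase
    schedule: ScheduleRule
    arm: ArmCondition = ArmCondition.BOTH
    modality: ModalityCondition = ModalityCondition.BOTH


@dataclass(frozen=True)
class WageBand:
    profession: Profession
    age_band: str
    hourly_rate: float  # yen per hour
    weight: float  # percent of the profession's workforce


@dataclass(frozen=True)
class PhysicianGrade:
    name: str  # mean | resident | specialist | trainer
    hourly_rate: float


@dataclass(frozen=True)
class WageTable:
    mean_rates: Mapping[Profession, float]
    bands: tuple[WageBand, ...]
    grades: tuple[PhysicianGrade, ...]

    def mean_rate(self, profession: Profession) -> float:
        return self.mean_rates[profession]

    def bands_for(self, profession: Profession) -> tuple[WageBand, ...]:
        return tuple(b for b in self.bands if b.profession == profession)

    def grade_rate(self, name: str) -> float:
        for g in self.grades:
            if g.name == name:
                return g.hourly_rate
        raise KeyError(f"unknown physician grade: {name!r}")


@dataclass(frozen=True)
class DecisionProbabilities:
    """P(symptomatic vasospasm) per (modality, clazosentan arm)."""

    coiling_claz_plus: float
    coiling_claz_minus: float
    clipping_claz_plus: float
    clipping_claz_minus: float

    def p_svsp(self, modality: str, claz: bool) -> float:
        key = f"{modality}_claz_{'plus' if claz else 'minus'}"
        return getattr(self, key)


@dataclass(frozen=True)
class Windows:
    """Inclusive day windows of the 15-day acute stay (day 0 = admission).

    Without vasospasm the smooth-recovery phase spans the whole
    post-operative window; with vasospasm the spasm phase replaces it from
    its onset day onward.
    """

    smooth_no_spasm: tuple[int, int] = (1, 14)
    smooth_with_spasm: tuple[int, int] = (1, 6)
    spasm: tuple[int, int] = (7, 14)

    @property
    def last_day(self) -> int:
        return max(self.smooth_no_spasm[1], self.spasm[1])


@dataclass(frozen=True)
class StudyConfig:
    activities: tuple[ActivityRule, ...]
    wages: WageTable
    probabilities: DecisionProbabilities
    windows: Windows = field(default_factory=Windows)

    def activity(self, activity_id: str) -> ActivityRule:
        for a in self.activities:
            if a.id == activity_id:
                return a
        raise KeyError(f"unknown activity id: {activity_id!r}")

    # -- plain-record form (serialisation, and the raw feed for the
    #    independent costing oracle used in the test-suite) -------------
    def to_dict(self) -> dict:
        return _config_to_dict(self)


@dataclass(frozen=True)
class Violation:
    where: str  # offending object: activity id, profession, field ...
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.where}: {self.message}"


# ---------------------------------------------------------------------------
# serialisation

def _time_to_dict(t: TriangularMinutes) -> dict:
    return {"mode": t.mode, "lower": t.lower, "upper": t.upper}


def _schedule_to_dict(s: ScheduleRule) -> dict:
    d: dict = {"kind": s.kind.value}
    if s.days:
        d["days"] = list(s.days)
    if s.n is not None:
        d["n"] = s.n
    return d


def _config_to_dict(config: StudyConfig) -> dict:
    return {
        "activities": [
            {
                "id": a.id,
                "label": a.label,
                "time": _time_to_dict(a.time),
                "profession": a.profession.value,
                "headcount": a.headcount,
                "phase": a.phase.value,
                "schedule": _schedule_to_dict(a.schedule),
                "arm": a.arm.value,
                "modality": a.modality.value,
            }
            for a in config.activities
        ],
        "wages": {
            "mean_rates": {p.value: r for p, r in config.wages.mean_rates.items()},
            "bands": [
                {
                    "profession": b.profession.value,
                    "age_band": b.age_band,
                    "hourly_rate": b.hourly_rate,
                    "weight": b.weight,
                }
                for b in config.wages.bands
            ],
            "grades": [
                {"name": g.name, "hourly_rate": g.hourly_rate}
                for g in config.wages.grades
            ],
        },
        "probabilities": {
            "coiling_claz_plus": config.probabilities.coiling_claz_plus,
            "coiling_claz_minus": config.probabilities.coiling_claz_minus,
            "clipping_claz_plus": config.probabilities.clipping_claz_plus,
            "clipping_claz_minus": config.probabilities.clipping_claz_minus,
        },
        "windows": {
            "smooth_no_spasm": list(config.windows.smooth_no_spasm),
            "smooth_with_spasm": list(config.windows.smooth_with_spasm),
            "spasm": list(config.windows.spasm),
        },
    }


_ACTIVITY_FIELDS = {
    "id", "label", "time", "profession", "headcount", "phase",
    "schedule", "arm", "modality",
}
_TOP_FIELDS = {"activities", "wages", "probabilities", "windows"}


def _parse_activity(rec: Mapping, idx: int) -> ActivityRule:
    unknown = set(rec) - _ACTIVITY_FIELDS
    if unknown:
        raise ConfigError(
            f"activities[{idx}] ({rec.get('id', '?')}): unknown fields {sorted(unknown)}"
        )
    try:
        t = rec["time"]
        time = TriangularMinutes(
            mode=float(t["mode"]), lower=float(t["lower"]), upper=float(t["upper"])
        )
        sched = rec["schedule"]
        schedule = ScheduleRule(
            kind=ScheduleKind(sched["kind"]),
            days=tuple(int(d) for d in sched.get("days", ())),
            n=int(sched["n"]) if sched.get("n") is not None else None,
        )
        return ActivityRule(
            id=str(rec["id"]),
            label=str(rec.get("label", rec["id"])),
            time=time,
            profession=Profession(rec["profession"]),
            headcount=int(rec["headcount"]),
            phase=Phase(rec["phase"]),
            schedule=schedule,
            arm=ArmCondition(rec.get("arm", "both")),
            modality=ModalityCondition(rec.get("modality", "both")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(
            f"activities[{idx}] ({rec.get('id', '?')}): {exc}"
        ) from exc


def _config_from_dict(data: Mapping) -> StudyConfig:
    unknown = set(data) - _TOP_FIELDS
    if unknown:
        raise ConfigError(f"unknown top-level fields {sorted(unknown)}")
    try:
        activities = tuple(
            _parse_activity(rec, i) for i, rec in enumerate(data["activities"])
        )
        w = data["wages"]
        wages = WageTable(
            mean_rates={Profession(p): float(r) for p, r in w["mean_rates"].items()},
            bands=tuple(
                WageBand(
                    profession=Profession(b["profession"]),
                    age_band=str(b["age_band"]),
                    hourly_rate=float(b["hourly_rate"]),
                    weight=float(b["weight"]),
                )
                for b in w.get("bands", ())
            ),
            grades=tuple(
                PhysicianGrade(name=str(g["name"]), hourly_rate=float(g["hourly_rate"]))
                for g in w.get("grades", ())
            ),
        )
        p = data["probabilities"]
        probabilities = DecisionProbabilities(
            coiling_claz_plus=float(p["coiling_claz_plus"]),
            coiling_claz_minus=float(p["coiling_claz_minus"]),
            clipping_claz_plus=float(p["clipping_claz_plus"]),
            clipping_claz_minus=float(p["clipping_claz_minus"]),
        )
        win = data.get("windows")
        windows = (
            Windows(
                smooth_no_spasm=tuple(win["smooth_no_spasm"]),  # type: ignore[arg-type]
                smooth_with_spasm=tuple(win["smooth_with_spasm"]),  # type: ignore[arg-type]
                spasm=tuple(win["spasm"]),  # type: ignore[arg-type]
            )
            if win
            else Windows()
        )
    except ConfigError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return StudyConfig(
        activities=activities, wages=wages, probabilities=probabilities, windows=windows
    )


# ---------------------------------------------------------------------------
# validation

def validate_parameters(config: StudyConfig) -> list[Violation]:
    """Check every model-input invariant; return all violations found."""
    v: list[Violation] = []
    seen: set[str] = set()
    last = config.windows.last_day
    for a in config.activities:
        if a.id in seen:
            v.append(Violation(a.id, "duplicate activity id"))
        seen.add(a.id)
        t = a.time
        if not (t.lower > 0 and t.mode > 0 and t.upper > 0):
            v.append(Violation(a.id, "triangular times must be positive"))
        if not (t.lower <= t.mode <= t.upper):
            v.append(
                Violation(a.id, f"requires lower <= mode <= upper, got "
                                f"({t.lower}, {t.mode}, {t.upper})")
            )
        if a.headcount < 1:
            v.append(Violation(a.id, "headcount must be >= 1"))
        s = a.schedule
        if s.kind is ScheduleKind.EXPLICIT_DAYS:
            if not s.days:
                v.append(Violation(a.id, "explicit_days schedule needs days"))
            elif list(s.days) != sorted(set(s.days)):
                v.append(Violation(a.id, "explicit days must be strictly increasing"))
            elif s.days[0] < 0 or s.days[-1] > last:
                v.append(Violation(a.id, f"explicit days must lie in 0..{last}"))
        if s.kind is ScheduleKind.FIRST_N_DAYS and (s.n is None or s.n < 1):
            v.append(Violation(a.id, "first_n_days schedule needs n >= 1"))

    for p in Profession:
        if p not in config.wages.mean_rates:
            v.append(Violation(p.value, "missing mean rate"))
        elif config.wages.mean_rates[p] <= 0:
            v.append(Violation(p.value, "mean rate must be positive"))
        bands = config.wages.bands_for(p)
        if not bands:
            v.append(Violation(p.value, "no wage bands"))
            continue
        total = sum(b.weight for b in bands)
        if abs(total - 100.0) > 0.1:
            v.append(Violation(p.value, f"band weights sum to {total}, expected 100"))
        for b in bands:
            if b.hourly_rate <= 0:
                v.append(Violation(f"{p.value}/{b.age_band}", "rate must be positive"))

    for g in config.wages.grades:
        if g.hourly_rate <= 0:
            v.append(Violation(f"grade/{g.name}", "rate must be positive"))

    pr = config.probabilities
    for name in (
        "coiling_claz_plus", "coiling_claz_minus",
        "clipping_claz_plus", "clipping_claz_minus",
    ):
        p_val = getattr(pr, name)
        if not (0.0 <= p_val <= 1.0):
            v.append(Violation(f"probabilities/{name}", f"{p_val} outside [0, 1]"))

    for lo, hi, name in (
        (*config.windows.smooth_no_spasm, "smooth_no_spasm"),
        (*config.windows.smooth_with_spasm, "smooth_with_spasm"),
        (*config.windows.spasm, "spasm"),
    ):
        if lo > hi or lo < 0:
            v.append(Violation(f"windows/{name}", f"invalid window ({lo}, {hi})"))
    return v


# ---------------------------------------------------------------------------
# loaders

_BUILTIN_RESOURCE = "builtin.yaml"


def builtin_parameters() -> StudyConfig:
    """The packaged study parameters: wage survey, care-process map,
    vasospasm probabilities and acute-phase windows.

    Deterministic and side-effect-free; two calls compare equal.
    """
    text = (
        resources.files("sahcost").joinpath("data", _BUILTIN_RESOURCE).read_text()
    )
    config = _config_from_dict(yaml.safe_load(text))
    problems = validate_parameters(config)
    if problems:  # pragma: no cover - packaged data is valid by construction
        raise ConfigError("; ".join(map(str, problems)))
    return config


def load_study_config(path: str | Path, format: str | None = None) -> StudyConfig:
    """Load and validate a study configuration.

    ``format`` is ``"yaml"`` (a single file) or ``"csv-bundle"`` (a
    directory holding ``activities.csv``, ``wage_bands.csv``,
    ``grades.csv`` and ``probabilities.csv``); inferred from the path when
    omitted.  Raises :class:`ConfigError` listing every violated invariant.
    """
    path = Path(path)
    if format is None:
        format = "csv-bundle" if path.is_dir() else "yaml"
    if format == "yaml":
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping at top level")
        config = _config_from_dict(data)
    elif format == "csv-bundle":
        config = _load_csv_bundle(path)
    else:
        raise ConfigError(f"unknown config format: {format!r}")
    problems = validate_parameters(config)
    if problems:
        raise ConfigError(
            f"{path}: invalid configuration:\n  "
            + "\n  ".join(str(p) for p in problems)
        )
    return config


def save_study_config(config: StudyConfig, path: str | Path) -> None:
    """Write a config as YAML (the inverse of the YAML loader)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def _read_csv(path: Path) -> list[dict]:
    if not path.exists():
        raise ConfigError(f"missing bundle file: {path}")
    with path.open(newline="") as fh:
        return list(csv.DictReader(fh))


def _load_csv_bundle(directory: Path) -> StudyConfig:
    acts = []
    for i, row in enumerate(_read_csv(directory / "activities.csv")):
        days = tuple(int(d) for d in row["days"].split(";")) if row.get("days") else ()
        acts.append(
            {
                "id": row["id"],
                "label": row.get("label") or row["id"],
                "time": {
                    "mode": float(row["mode"]),
                    "lower": float(row["lower"]),
                    "upper": float(row["upper"]),
                },
                "profession": row["profession"],
                "headcount": int(row["headcount"]),
                "phase": row["phase"],
                "schedule": {
                    "kind": row["schedule_kind"],
                    "days": list(days),
                    "n": int(row["n"]) if row.get("n") else None,
                },
                "arm": row.get("arm") or "both",
                "modality": row.get("modality") or "both",
            }
        )
    mean_rates: dict[str, float] = {}
    bands = []
    for row in _read_csv(directory / "wage_bands.csv"):
        if row["age_band"] == "mean":
            mean_rates[row["profession"]] = float(row["hourly_rate"])
        else:
            bands.append(
                {
                    "profession": row["profession"],
                    "age_band": row["age_band"],
                    "hourly_rate": float(row["hourly_rate"]),
                    "weight": float(row["weight"]),
                }
            )
    grades = [
        {"name": row["name"], "hourly_rate": float(row["hourly_rate"])}
        for row in _read_csv(directory / "grades.csv")
    ]
    probs: dict[str, float] = {}
    for row in _read_csv(directory / "probabilities.csv"):
        probs[f"{row['modality']}_claz_{row['arm']}"] = float(row["p_svsp"])
    return _config_from_dict(
        {
            "activities": acts,
            "wages": {"mean_rates": mean_rates, "bands": bands, "grades": grades},
            "probabilities": probs,
        }
    )


def save_csv_bundle(config: StudyConfig, directory: str | Path) -> None:
    """Write a config as the four-file CSV bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    d = config.to_dict()
    with (directory / "activities.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "label", "mode", "lower", "upper", "profession", "headcount",
             "phase", "schedule_kind", "days", "n", "arm", "modality"]
        )
        for a in d["activities"]:
            s = a["schedule"]
            w.writerow(
                [a["id"], a["label"], a["time"]["mode"], a["time"]["lower"],
                 a["time"]["upper"], a["profession"], a["headcount"], a["phase"],
                 s["kind"], ";".join(map(str, s.get("days", ()))),
                 s.get("n") if s.get("n") is not None else "",
                 a["arm"], a["modality"]]
            )
    with (directory / "wage_bands.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["profession", "age_band", "hourly_rate", "weight"])
        for p, r in d["wages"]["mean_rates"].items():
            w.writerow([p, "mean", r, ""])
        for b in d["wages"]["bands"]:
            w.writerow([b["profession"], b["age_band"], b["hourly_rate"], b["weight"]])
    with (directory / "grades.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "hourly_rate"])
        for g in d["wages"]["grades"]:
            w.writerow([g["name"], g["hourly_rate"]])
    with (directory / "probabilities.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["modality", "arm", "p_svsp"])
        p = d["probabilities"]
        for modality in ("coiling", "clipping"):
            for arm in ("plus", "minus"):
                w.writerow([modality, arm, p[f"{modality}_claz_{arm}"]])
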