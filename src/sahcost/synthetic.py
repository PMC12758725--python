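"""Random synthetic care-process configurations, and a naive costing oracle.

The generator emits study configurations with the same structure as the
packaged one — triangular activity times built by the half/double rule,
day-0 / smooth / spasm phases, day schedules, arm-substitution pairs and
modality-specific activities — so properties of the expansion and
costing pipeline can be exercised on inputs it was not written against.

:func:`oracle_cost` recomputes a pathway total by brute force from the
plain-record (dict) form of a configuration, sharing no code with
``expand_pathway``/``pathway_cost``; it exists for cross-checking in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    ActivityRule,
    ArmCondition,
    DecisionProbabilities,
    ModalityCondition,
    Phase,
    PhysicianGrade,
    Profession,
    ScheduleRule,
    StudyConfig,
    TriangularMinutes,
    WageBand,
    WageTable,
    Windows,
    validate_parameters,
)

__all__ = ["GeneratorSpec", "generate_random_study", "oracle_cost"]


@dataclass(frozen=True)
class GeneratorSpec:
    n_activities: int = 10
    professions: tuple[Profession, ...] = tuple(Profession)
    max_headcount: int = 3
    smooth_days: int = 14  # uncomplicated recovery window length
    pre_spasm_days: int = 6  # smooth days before spasm onset
    p_modality_specific: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_activities < 1:
            raise ValueError("n_activities must be >= 1")
        if not self.professions:
            raise ValueError("at least one profession required")
        if self.max_headcount < 1:
            raise ValueError("max_headcount must be >= 1")
        if self.smooth_days < 1 or self.pre_spasm_days < 1:
            raise ValueError("window lengths must be >= 1")
        if self.pre_spasm_days >= self.smooth_days:
            raise ValueError("spasm onset must precede the end of the stay")


def _random_schedule(rng: np.random.Generator, lo: int, hi: int) -> ScheduleRule:
    kind = rng.choice(["daily", "explicit", "first_n"])
    if kind == "daily":
        return ScheduleRule.daily()
    if kind == "explicit":
        k = int(rng.integers(1, min(4, hi - lo + 1) + 1))
        days = sorted(rng.choice(range(lo, hi + 1), size=k, replace=False).tolist())
        return ScheduleRule.on_days(*days)
    return ScheduleRule.first_days(int(rng.integers(1, hi - lo + 2)))


def generate_random_study(spec: GeneratorSpec) -> StudyConfig:
    """Generate a validating random study configuration.

    Deterministic under ``spec.seed``.  With two or more activities the
    output always contains at least one arm-substitution pair (a
    clazosentan-arm activity and its longer no-clazosentan sibling) and,
    with three or more, at least one scheduled (non-daily) activity.
    """
    rng = np.random.default_rng(spec.seed)
    windows = Windows(
        smooth_no_spasm=(1, spec.smooth_days),
        smooth_with_spasm=(1, spec.pre_spasm_days),
        spasm=(spec.pre_spasm_days + 1, spec.smooth_days),
    )
    acts: list[ActivityRule] = []

    def rand_time() -> TriangularMinutes:
        return TriangularMinutes.from_mode(float(rng.integers(1, 25) * 5))

    def rand_prof() -> Profession:
        return spec.professions[int(rng.integers(len(spec.professions)))]

    def rand_modality() -> ModalityCondition:
        if rng.random() < spec.p_modality_specific:
            specific = (ModalityCondition.COILING_ONLY, ModalityCondition.CLIPPING_ONLY)
            return specific[int(rng.integers(2))]
        return ModalityCondition.BOTH

    i = 0
    if spec.n_activities >= 2:  # guaranteed arm-substitution pair
        prof = rand_prof()
        base = rand_time()
        acts.append(
            ActivityRule(
                id="act0_claz", label="paired activity (clazosentan arm)",
                time=base, profession=prof, headcount=1, phase=Phase.SMOOTH,
                schedule=ScheduleRule.daily(), arm=ArmCondition.CLAZ_PLUS_ONLY,
            )
        )
        acts.append(
            ActivityRule(
                id="act1_noclaz", label="paired activity (control arm)",
                time=TriangularMinutes.from_mode(base.mode * 2),
                profession=prof, headcount=1, phase=Phase.SMOOTH,
                schedule=ScheduleRule.daily(), arm=ArmCondition.CLAZ_MINUS_ONLY,
            )
        )
        i = 2
    if spec.n_activities >= 3:  # guaranteed scheduled (non-daily) activity
        lo, hi = windows.smooth_no_spasm
        day = int(rng.integers(lo, hi + 1))
        acts.append(
            ActivityRule(
                id="act2_scheduled", label="scheduled activity",
                time=rand_time(), profession=rand_prof(),
                headcount=int(rng.integers(1, spec.max_headcount + 1)),
                phase=Phase.SMOOTH, schedule=ScheduleRule.on_days(day),
                modality=rand_modality(),
            )
        )
        i = 3
    while i < spec.n_activities:
        phase = tuple(Phase)[int(rng.integers(len(Phase)))]
        if phase is Phase.DAY0:
            schedule = ScheduleRule.day_zero()
        else:
            lo, hi = (
                windows.smooth_no_spasm if phase is Phase.SMOOTH else windows.spasm
            )
            schedule = _random_schedule(rng, lo, hi)
        acts.append(
            ActivityRule(
                id=f"act{i}", label=f"random activity {i}",
                time=rand_time(), profession=rand_prof(),
                headcount=int(rng.integers(1, spec.max_headcount + 1)),
                phase=phase, schedule=schedule,
                arm=ArmCondition.BOTH, modality=rand_modality(),
            )
        )
        i += 1

    mean_rates = {
        p: float(np.round(rng.uniform(1500, 9000), 1)) for p in Profession
    }
    bands: list[WageBand] = []
    for p in Profession:
        k = int(rng.integers(2, 6))
        w = rng.dirichlet(np.full(k, 2.0)) * 100.0  # positive, sums to 100
        for b in range(k):
            bands.append(
                WageBand(
                    profession=p, age_band=f"band{b}",
                    hourly_rate=float(np.round(rng.uniform(1200, 9500), 1)),
                    weight=float(w[b]),
                )
            )
    p_plus = rng.uniform(0.05, 0.45, size=2)
    p_minus = p_plus + rng.uniform(0.05, 0.4, size=2)
    config = StudyConfig(
        activities=tuple(acts),
        wages=WageTable(
            mean_rates=mean_rates,
            bands=tuple(bands),
            grades=(
                PhysicianGrade("mean", mean_rates[Profession.PHYSICIAN]),
                PhysicianGrade("resident", float(np.round(rng.uniform(1500, 4000), 1))),
                PhysicianGrade("specialist", float(np.round(rng.uniform(4000, 7000), 1))),
                PhysicianGrade("trainer", float(np.round(rng.uniform(7000, 9500), 1))),
            ),
        ),
        probabilities=DecisionProbabilities(
            coiling_claz_plus=float(p_plus[0]),
            coiling_claz_minus=float(min(p_minus[0], 1.0)),
            clipping_claz_plus=float(p_plus[1]),
            clipping_claz_minus=float(min(p_minus[1], 1.0)),
        ),
        windows=windows,
    )
    problems = validate_parameters(config)
    if problems:  # pragma: no cover - generator must produce valid configs
        raise AssertionError("generator produced invalid config: "
                             + "; ".join(map(str, problems)))
    return config


def oracle_cost(
    raw_config: dict,
    modality: str,
    claz: bool,
    svsp: bool,
    grade: str = "mean",
) -> float:
    """Brute-force pathway total from the plain-record config form.

    Walks every day of the stay and every raw activity record and adds
    minutes/60 x headcount x rate whenever the record applies to that day
    under this stratum.  Written independently of the expansion/costing
    modules; intended for cross-checks in tests only.
    """
    wages = raw_config["wages"]
    rate_of: dict[str, float] = dict(wages["mean_rates"])
    if grade != "mean":
        rate_of["physician"] = next(
            g["hourly_rate"] for g in wages["grades"] if g["name"] == grade
        )
    win = raw_config.get("windows") or {
        "smooth_no_spasm": [1, 14], "smooth_with_spasm": [1, 6], "spasm": [7, 14],
    }
    smooth = win["smooth_with_spasm"] if svsp else win["smooth_no_spasm"]
    spasm = win["spasm"] if svsp else None
    last_day = max(win["smooth_no_spasm"][1], win["spasm"][1])

    total = 0.0
    for day in range(0, last_day + 1):
        for rec in raw_config["activities"]:
            arm = rec.get("arm", "both")
            if arm == "claz_plus_only" and not claz:
                continue
            if arm == "claz_minus_only" and claz:
                continue
            mod = rec.get("modality", "both")
            if mod == "coiling_only" and modality != "coiling":
                continue
            if mod == "clipping_only" and modality != "clipping":
                continue
            phase = rec["phase"]
            if phase == "day0":
                window = (0, 0)
            elif phase == "smooth":
                window = tuple(smooth)
            elif spasm is not None:
                window = tuple(spasm)
            else:
                continue
            if not (window[0] <= day <= window[1]):
                continue
            sched = rec["schedule"]
            kind = sched["kind"]
            if kind == "day_zero":
                happens = day == 0
            elif kind == "daily_over_window":
                happens = True
            elif kind == "explicit_days":
                happens = day in sched.get("days", [])
            elif kind == "first_n_days":
                happens = day < window[0] + (sched.get("n") or 0)
            else:  # pragma: no cover
                raise ValueError(f"unknown schedule kind {kind!r}")
            if happens:
                total += (
                    rec["time"]["mode"] / 60.0
                    * rec["headcount"]
                    * rate_of[rec["profession"]]
                )
    return total
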