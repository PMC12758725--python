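"""Probabilistic sensitivity analysis of the labour-cost model.

Each Monte Carlo iteration redraws every activity time from its
triangular distribution and every hourly wage from the survey's age-band
distribution (a categorical draw weighted by each band's workforce
share), recosts all eight pathways, and the run is summarised by mean,
SD and the 2.5th/97.5th percentiles per pathway.

Sampling granularity is configurable.  By default one time is drawn per
activity per iteration (shared across all of that activity's occurrences
and across pathways) and one wage per profession per iteration; the
alternative reading — an independent draw per occurrence — is available
via :class:`PSAConfig`.  Randomness comes from a single seed: the root
``SeedSequence`` is split into fixed-purpose streams (activity times,
wages, then one stream per pathway for per-occurrence draws) so results
for one pathway do not shift when another is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .costing import pathway_cost
from .expansion import ALL_PATHWAYS, ExpandedPathway, PathwayKey, expand_pathway
from .parameters import Profession, StudyConfig, TriangularMinutes, WageTable

__all__ = [
    "PSAConfig",
    "PSASummary",
    "sample_triangular",
    "sample_wage",
    "psa_cost_matrix",
    "psa_run",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 10_000
    seed: int = 0
    grade: str | None = None  # fix the physician rate at a grade instead of sampling
    time_granularity: str = "activity"  # "activity" | "occurrence"
    wage_granularity: str = "iteration"  # "iteration" | "occurrence"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.time_granularity not in ("activity", "occurrence"):
            raise ValueError(f"unknown time granularity {self.time_granularity!r}")
        if self.wage_granularity not in ("iteration", "occurrence"):
            raise ValueError(f"unknown wage granularity {self.wage_granularity!r}")


@dataclass(frozen=True)
class PSASummary:
    pathway: PathwayKey
    mean: float
    sd: float
    p2_5: float
    p97_5: float


def _triangular_ppf(
    u: np.ndarray, lower: np.ndarray, mode: np.ndarray, upper: np.ndarray
) -> np.ndarray:
    """Inverse CDF of the triangular distribution, elementwise.

    Degenerate parameter sets (lower == upper) return the mode, so point
    distributions pass through unchanged.
    """
    lower = np.asarray(lower, dtype=float)
    mode = np.asarray(mode, dtype=float)
    upper = np.asarray(upper, dtype=float)
    width = upper - lower
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(width > 0, (mode - lower) / np.where(width > 0, width, 1.0), 1.0)
        left = lower + np.sqrt(u * width * (mode - lower))
        right = upper - np.sqrt((1.0 - u) * width * (upper - mode))
    x = np.where(u < fc, left, right)
    return np.where(width > 0, x, mode)


def sample_triangular(
    t: TriangularMinutes, rng: np.random.Generator, size: int | tuple | None = None
) -> float | np.ndarray:
    """Draw from Triangular(lower, mode, upper) by inversion."""
    u = rng.random(size)
    out = _triangular_ppf(np.asarray(u), t.lower, t.mode, t.upper)
    return float(out) if size is None else out


def sample_wage(
    profession: Profession,
    wages: WageTable,
    rng: np.random.Generator,
    size: int | tuple | None = None,
) -> float | np.ndarray:
    """Draw an hourly rate: an age band chosen with probability equal to
    its workforce share, returning that band's rate."""
    bands = wages.bands_for(profession)
    rates = np.array([b.hourly_rate for b in bands])
    weights = np.array([b.weight for b in bands])
    idx = rng.choice(len(bands), size=size, p=weights / weights.sum())
    out = rates[idx]
    return float(out) if size is None else out


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, list]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + len(ALL_PATHWAYS))
    time_rng = np.random.default_rng(children[0])
    wage_rng = np.random.default_rng(children[1])
    pathway_rngs = [np.random.default_rng(c) for c in children[2:]]
    return time_rng, wage_rng, pathway_rngs


def psa_cost_matrix(
    config: StudyConfig, psa: PSAConfig
) -> tuple[np.ndarray, tuple[PathwayKey, ...]]:
    """Per-iteration total cost of every pathway.

    Returns ``(costs, keys)`` with ``costs`` of shape
    ``(n_iterations, 8)`` aligned with ``keys``.
    """
    n = psa.n_iterations
    time_rng, wage_rng, pathway_rngs = _streams(psa.seed)
    acts = config.activities
    act_index = {a.id: i for i, a in enumerate(acts)}

    # shared draws (consumed in a fixed order regardless of granularity,
    # then used or ignored, to keep streams stable across settings)
    lo = np.array([a.time.lower for a in acts])
    mo = np.array([a.time.mode for a in acts])
    up = np.array([a.time.upper for a in acts])
    act_times = _triangular_ppf(time_rng.random((n, len(acts))), lo, mo, up)

    prof_rates: dict[Profession, np.ndarray] = {}
    for p in Profession:
        if p is Profession.PHYSICIAN and psa.grade is not None:
            prof_rates[p] = np.full(n, config.wages.grade_rate(psa.grade))
        else:
            prof_rates[p] = np.asarray(sample_wage(p, config.wages, wage_rng, size=n))

    pathways = [expand_pathway(config, key) for key in ALL_PATHWAYS]
    costs = np.empty((n, len(ALL_PATHWAYS)))
    for j, (key, pw) in enumerate(zip(ALL_PATHWAYS, pathways)):
        occ = pw.occurrences
        hc = np.array([o.headcount for o in occ], dtype=float)
        prof = [o.profession for o in occ]
        if psa.time_granularity == "activity":
            cols = np.array([act_index[o.activity_id] for o in occ])
            minutes = act_times[:, cols]  # (n, n_occ)
        else:
            olo = np.array([config.activity(o.activity_id).time.lower for o in occ])
            omo = np.array([config.activity(o.activity_id).time.mode for o in occ])
            oup = np.array([config.activity(o.activity_id).time.upper for o in occ])
            minutes = _triangular_ppf(
                pathway_rngs[j].random((n, len(occ))), olo, omo, oup
            )
        if psa.wage_granularity == "iteration":
            rates = np.column_stack([prof_rates[p] for p in prof])  # (n, n_occ)
        else:
            rates = np.empty((n, len(occ)))
            for p in Profession:
                mask = np.array([q is p for q in prof])
                if not mask.any():
                    continue
                if p is Profession.PHYSICIAN and psa.grade is not None:
                    rates[:, mask] = config.wages.grade_rate(psa.grade)
                else:
                    rates[:, mask] = sample_wage(
                        p, config.wages, pathway_rngs[j], size=(n, int(mask.sum()))
                    )
        costs[:, j] = (minutes * hc * rates).sum(axis=1) / 60.0
    return costs, ALL_PATHWAYS


def psa_run(config: StudyConfig, psa: PSAConfig) -> dict[PathwayKey, PSASummary]:
    """Run the PSA and summarise each pathway's cost distribution."""
    costs, keys = psa_cost_matrix(config, psa)
    out: dict[PathwayKey, PSASummary] = {}
    for j, key in enumerate(keys):
        col = costs[:, j]
        out[key] = PSASummary(
            pathway=key,
            mean=float(col.mean()),
            sd=float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            p2_5=float(np.percentile(col, 2.5)),
            p97_5=float(np.percentile(col, 97.5)),
        )
    return out


def summaries_to_frame(summaries: Mapping[PathwayKey, PSASummary]) -> pd.DataFrame:
    rows = [
        {
            "modality": k.modality,
            "arm": "claz+" if k.claz else "claz-",
            "stratum": "svsp+" if k.svsp else "svsp-",
            "mean": s.mean,
            "sd": s.sd,
            "p2.5": s.p2_5,
            "p97.5": s.p97_5,
        }
        for k, s in summaries.items()
    ]
    return pd.DataFrame(rows)
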