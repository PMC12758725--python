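"""Decision-tree expectation and cohort Monte Carlo.

After the operation a patient either recovers smoothly or develops
symptomatic vasospasm, with arm- and modality-specific probabilities
taken from the clazosentan trial.  The closed form gives the expected
per-patient cost of an arm; the cohort simulation propagates parameter
uncertainty (one sensitivity-analysis draw per outer iteration) and
sampling uncertainty (binomial vasospasm counts in a finite cohort) into
the distribution of the between-arm savings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .expansion import ALL_PATHWAYS, MODALITIES, PathwayKey
from .parameters import DecisionProbabilities, StudyConfig
from .psa import PSAConfig, psa_cost_matrix

__all__ = [
    "CohortConfig",
    "SavingsSummary",
    "expected_cost_closed_form",
    "closed_form_savings",
    "simulate_cohort",
    "savings_to_frame",
]


@dataclass(frozen=True)
class CohortConfig:
    n_outer: int = 1_000
    cohort_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer < 1 or self.cohort_size < 1:
            raise ValueError("iteration counts must be >= 1")


@dataclass(frozen=True)
class SavingsSummary:
    modality: str
    mean_cost_claz_minus: float
    mean_cost_claz_plus: float
    savings_mean: float
    savings_p2_5: float
    savings_p97_5: float


def expected_cost_closed_form(
    costs: Mapping[PathwayKey, float],
    probabilities: DecisionProbabilities,
    modality: str,
    claz: bool,
) -> float:
    """Expected per-patient cost of one arm:
    p_svsp x cost(svsp+) + (1 - p_svsp) x cost(svsp-)."""
    p = probabilities.p_svsp(modality, claz)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability {p} outside [0, 1]")
    c_pos = costs[PathwayKey(modality, claz, svsp=True)]
    c_neg = costs[PathwayKey(modality, claz, svsp=False)]
    return p * c_pos + (1.0 - p) * c_neg


def closed_form_savings(
    costs: Mapping[PathwayKey, float],
    probabilities: DecisionProbabilities,
    modality: str,
) -> float:
    """Expected savings of the clazosentan arm over the control arm."""
    return expected_cost_closed_form(
        costs, probabilities, modality, claz=False
    ) - expected_cost_closed_form(costs, probabilities, modality, claz=True)


def simulate_cohort(
    config: StudyConfig,
    cohort: CohortConfig = CohortConfig(),
    psa: PSAConfig | None = None,
) -> dict[str, SavingsSummary]:
    """Cohort Monte Carlo of the decision tree.

    Per outer iteration one parameter set is drawn (every activity time
    and wage, as in the sensitivity analysis) and shared by all patients
    of that iteration; the number developing vasospasm in each arm is
    binomial with the arm's probability.  The per-patient mean cost of
    each arm and the between-arm savings are summarised over outer
    iterations by their mean and 2.5/97.5 percentiles.
    """
    if psa is None:
        psa = PSAConfig(n_iterations=cohort.n_outer, seed=cohort.seed)
    elif psa.n_iterations != cohort.n_outer:
        raise ValueError("psa.n_iterations must equal cohort.n_outer")
    costs, keys = psa_cost_matrix(config, psa)
    col = {key: j for j, key in enumerate(keys)}
    rng = np.random.default_rng(np.random.SeedSequence(cohort.seed).spawn(3)[2])

    out: dict[str, SavingsSummary] = {}
    for modality in MODALITIES:
        arm_mean: dict[bool, np.ndarray] = {}
        for claz in (False, True):
            p = config.probabilities.p_svsp(modality, claz)
            n_svsp = rng.binomial(cohort.cohort_size, p, size=cohort.n_outer)
            c_pos = costs[:, col[PathwayKey(modality, claz, svsp=True)]]
            c_neg = costs[:, col[PathwayKey(modality, claz, svsp=False)]]
            arm_mean[claz] = (
                n_svsp * c_pos + (cohort.cohort_size - n_svsp) * c_neg
            ) / cohort.cohort_size
        savings = arm_mean[False] - arm_mean[True]
        out[modality] = SavingsSummary(
            modality=modality,
            mean_cost_claz_minus=float(arm_mean[False].mean()),
            mean_cost_claz_plus=float(arm_mean[True].mean()),
            savings_mean=float(savings.mean()),
            savings_p2_5=float(np.percentile(savings, 2.5)),
            savings_p97_5=float(np.percentile(savings, 97.5)),
        )
    return out


def savings_to_frame(summaries: Mapping[str, SavingsSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "modality": s.modality,
                "mean_cost_claz-": s.mean_cost_claz_minus,
                "mean_cost_claz+": s.mean_cost_claz_plus,
                "savings_mean": s.savings_mean,
                "savings_p2.5": s.savings_p2_5,
                "savings_p97.5": s.savings_p97_5,
            }
            for s in summaries.values()
        ]
    )
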