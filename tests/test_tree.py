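"""Decision-tree expectation and cohort Monte Carlo."""

import dataclasses

import numpy as np
import pytest

from sahcost import (
    ALL_PATHWAYS,
    CohortConfig,
    PSAConfig,
    PathwayKey,
    closed_form_savings,
    expand_pathway,
    expected_cost_closed_form,
    pathway_cost,
    simulate_cohort,
)
from sahcost.psa import psa_cost_matrix


@pytest.fixture(scope="module")
def det_costs(paper_config):
    return {
        key: pathway_cost(expand_pathway(paper_config, key), paper_config.wages).total
        for key in ALL_PATHWAYS
    }


class TestClosedForm:
    def test_boundary_probabilities(self, paper_config, det_costs):
        p0 = dataclasses.replace(paper_config.probabilities, coiling_claz_plus=0.0)
        assert expected_cost_closed_form(det_costs, p0, "coiling", True) == (
            det_costs[PathwayKey("coiling", True, False)]
        )
        p1 = dataclasses.replace(paper_config.probabilities, coiling_claz_plus=1.0)
        assert expected_cost_closed_form(det_costs, p1, "coiling", True) == (
            det_costs[PathwayKey("coiling", True, True)]
        )

    def test_out_of_range_probability_rejected(self, paper_config, det_costs):
        bad = dataclasses.replace(paper_config.probabilities, coiling_claz_plus=1.5)
        with pytest.raises(ValueError, match="probability"):
            expected_cost_closed_form(det_costs, bad, "coiling", True)

    def test_savings_against_direct_arithmetic(self, paper_config):
        """Evaluated at the printed pathway totals the expected coiling
        savings are ~106,432.5 yen (0.288x602,564.35 + 0.712x229,228.38
        - 0.136x563,409.00 - 0.864x177,885.40)."""
        printed = {
            PathwayKey("coiling", False, True): 602_564.35,
            PathwayKey("coiling", False, False): 229_228.38,
            PathwayKey("coiling", True, True): 563_409.00,
            PathwayKey("coiling", True, False): 177_885.40,
        }
        expected = (
            0.288 * 602_564.35 + 0.712 * 229_228.38
            - 0.136 * 563_409.00 - 0.864 * 177_885.40
        )
        got = closed_form_savings(printed, paper_config.probabilities, "coiling")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(106_432.5, abs=1.0)


class TestCohortSimulation:
    def test_converges_to_closed_form_with_degenerate_psa(
        self, paper_config, degenerate_paper_config
    ):
        """With point parameter draws only binomial noise remains, so the
        simulated mean savings match the closed form within 3 SE."""
        cfg = degenerate_paper_config
        det = {
            key: pathway_cost(expand_pathway(cfg, key), cfg.wages).total
            for key in ALL_PATHWAYS
        }
        cohort = CohortConfig(n_outer=400, cohort_size=10_000, seed=29)
        result = simulate_cohort(cfg, cohort)
        for modality in ("coiling", "clipping"):
            expected = closed_form_savings(det, cfg.probabilities, modality)
            # binomial SE of the savings over outer iterations
            se_terms = 0.0
            for claz in (False, True):
                p = cfg.probabilities.p_svsp(modality, claz)
                gap = det[PathwayKey(modality, claz, True)] - det[
                    PathwayKey(modality, claz, False)
                ]
                se_terms += gap**2 * p * (1 - p) / cohort.cohort_size
            se = np.sqrt(se_terms / cohort.n_outer)
            assert abs(result[modality].savings_mean - expected) < 3 * se

    def test_zero_probability_gap_centres_savings_at_zero(
        self, degenerate_paper_config
    ):
        cfg = degenerate_paper_config
        # same vasospasm risk in both arms and identical arm costs
        probs = dataclasses.replace(
            cfg.probabilities,
            coiling_claz_plus=0.2, coiling_claz_minus=0.2,
            clipping_claz_plus=0.3, clipping_claz_minus=0.3,
        )
        acts = tuple(a for a in cfg.activities if not a.id.endswith("_noclaz"))
        both = tuple(dataclasses.replace(a, arm=type(a.arm).BOTH) for a in acts)
        cfg = dataclasses.replace(cfg, activities=both, probabilities=probs)
        result = simulate_cohort(cfg, CohortConfig(300, 5_000, seed=41))
        for summary in result.values():
            assert summary.savings_p2_5 < 0 < summary.savings_p97_5
            # pure binomial noise: 3 SE of the mean savings is ~500 yen here
            assert abs(summary.savings_mean) < 600

    def test_clipping_saves_more_than_coiling(self, paper_config):
        result = simulate_cohort(paper_config, CohortConfig(500, 5_000, seed=8))
        assert result["clipping"].savings_mean > result["coiling"].savings_mean

    def test_savings_monotone_in_probability_gap(self, paper_config):
        means = []
        for p_minus in (0.2, 0.3, 0.4):
            probs = dataclasses.replace(
                paper_config.probabilities,
                coiling_claz_plus=0.1, coiling_claz_minus=p_minus,
            )
            cfg = dataclasses.replace(paper_config, probabilities=probs)
            result = simulate_cohort(cfg, CohortConfig(300, 5_000, seed=55))
            means.append(result["coiling"].savings_mean)
        assert means[0] < means[1] < means[2]

    def test_seeded_reproducibility(self, paper_config):
        a = simulate_cohort(paper_config, CohortConfig(100, 1_000, seed=3))
        b = simulate_cohort(paper_config, CohortConfig(100, 1_000, seed=3))
        assert a == b

    def test_interval_covers_closed_form_at_psa_means(self, paper_config):
        """Repeated reduced-scale runs: the 95% interval contains the
        closed form evaluated at the PSA-mean costs in >= 90% of runs."""
        costs, keys = psa_cost_matrix(paper_config, PSAConfig(2_000, seed=77))
        psa_mean = {k: float(c) for k, c in zip(keys, costs.mean(axis=0))}
        covered = 0
        runs = 10
        for i in range(runs):
            result = simulate_cohort(
                paper_config, CohortConfig(n_outer=200, cohort_size=2_000, seed=100 + i)
            )
            s = result["coiling"]
            target = closed_form_savings(psa_mean, paper_config.probabilities, "coiling")
            covered += s.savings_p2_5 <= target <= s.savings_p97_5
        assert covered >= 0.9 * runs
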