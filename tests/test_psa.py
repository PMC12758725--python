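"""Monte Carlo sensitivity analysis: samplers, summaries, reproducibility."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sahcost import (
    ALL_PATHWAYS,
    PSAConfig,
    Profession,
    TriangularMinutes,
    expand_pathway,
    pathway_cost,
    psa_run,
    sample_triangular,
    sample_wage,
)
from sahcost.parameters import WageBand, WageTable
from sahcost.psa import psa_cost_matrix


class TestTriangularSampler:
    def test_degenerate_distribution_returns_mode(self):
        t = TriangularMinutes(mode=30, lower=30, upper=30)
        rng = np.random.default_rng(0)
        assert np.all(sample_triangular(t, rng, size=100) == 30.0)

    def test_sample_mean_matches_closed_form(self):
        t = TriangularMinutes(mode=90, lower=45, upper=180)
        rng = np.random.default_rng(7)
        draws = sample_triangular(t, rng, size=100_000)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 105.0) < 3 * se  # (45+90+180)/3

    def test_fixed_seed_reproduces_draw_sequence(self):
        t = TriangularMinutes.from_mode(60)
        a = sample_triangular(t, np.random.default_rng(5), size=1000)
        b = sample_triangular(t, np.random.default_rng(5), size=1000)
        assert np.array_equal(a, b)

    @settings(derandomize=True, max_examples=50)
    @given(
        mode=st.floats(min_value=1, max_value=1000),
        u=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_draws_stay_within_support(self, mode, u):
        t = TriangularMinutes.from_mode(mode)
        draws = sample_triangular(t, np.random.default_rng(u), size=64)
        assert np.all((draws >= t.lower) & (draws <= t.upper))


class TestWageSampler:
    def test_single_band_always_returned(self):
        wages = WageTable(
            mean_rates={p: 1000.0 for p in Profession},
            bands=(WageBand(Profession.NURSE, "only", 1234.5, 100.0),),
            grades=(),
        )
        draws = sample_wage(Profession.NURSE, wages, np.random.default_rng(0), 50)
        assert np.all(draws == 1234.5)

    def test_band_frequencies_match_weights(self, paper_config):
        rng = np.random.default_rng(11)
        draws = sample_wage(Profession.NURSE, paper_config.wages, rng, 100_000)
        for band in paper_config.wages.bands_for(Profession.NURSE):
            p = band.weight / 100.0
            se = np.sqrt(p * (1 - p) / len(draws))
            observed = np.mean(draws == band.hourly_rate)
            assert abs(observed - p) < 3 * se

    def test_physician_long_run_mean_is_weighted_rate(self, paper_config):
        # independent oracle: direct weighted sum over the survey bands
        bands = paper_config.wages.bands_for(Profession.PHYSICIAN)
        expected = sum(b.hourly_rate * b.weight for b in bands) / 100.0
        rng = np.random.default_rng(13)
        draws = sample_wage(Profession.PHYSICIAN, paper_config.wages, rng, 200_000)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se


class TestPSARun:
    def test_degenerate_run_equals_deterministic(self, degenerate_paper_config):
        cfg = degenerate_paper_config
        summaries = psa_run(cfg, PSAConfig(n_iterations=1, seed=3))
        for key, s in summaries.items():
            det = pathway_cost(expand_pathway(cfg, key), cfg.wages).total
            assert s.mean == pytest.approx(det, rel=1e-12)
            assert s.sd == 0.0

    def test_percentiles_bracket_mean(self, paper_config):
        for s in psa_run(paper_config, PSAConfig(2000, seed=5)).values():
            assert s.p2_5 < s.mean < s.p97_5

    def test_claz_minus_costs_more_within_stratum(self, paper_config):
        s = psa_run(paper_config, PSAConfig(5000, seed=9))
        for key, summary in s.items():
            if key.claz:
                other = next(
                    v for k, v in s.items()
                    if k.modality == key.modality and k.svsp == key.svsp and not k.claz
                )
                assert summary.mean < other.mean

    def test_bit_identical_under_fixed_seed(self, paper_config):
        a, _ = psa_cost_matrix(paper_config, PSAConfig(500, seed=21))
        b, _ = psa_cost_matrix(paper_config, PSAConfig(500, seed=21))
        assert np.array_equal(a, b)

    def test_summary_invariant_to_iteration_order(self, paper_config):
        costs, keys = psa_cost_matrix(paper_config, PSAConfig(1000, seed=2))
        perm = np.random.default_rng(0).permutation(costs.shape[0])
        assert np.percentile(costs[perm], 97.5, axis=0) == pytest.approx(
            np.percentile(costs, 97.5, axis=0)
        )
        assert costs[perm].mean(axis=0) == pytest.approx(costs.mean(axis=0))

    def test_mean_exceeds_mode_cost_under_default_time_rule(self, paper_config):
        """With every triangle built by the half/double rule the expected
        time is 7/6 of the mode, so PSA means exceed mode-based totals."""
        acts = tuple(
            dataclasses.replace(a, time=TriangularMinutes.from_mode(a.time.mode))
            for a in paper_config.activities
        )
        cfg = dataclasses.replace(paper_config, activities=acts)
        summaries = psa_run(cfg, PSAConfig(4000, seed=17))
        for key, s in summaries.items():
            det = pathway_cost(expand_pathway(cfg, key), cfg.wages).total
            assert s.mean > det

    @pytest.mark.parametrize(
        "psa_kwargs",
        [
            {"time_granularity": "occurrence"},
            {"wage_granularity": "occurrence"},
            {"time_granularity": "occurrence", "wage_granularity": "occurrence"},
        ],
    )
    def test_alternative_granularities_agree_in_expectation(
        self, paper_config, psa_kwargs
    ):
        """Per-occurrence sampling changes variance, not the mean."""
        base = psa_run(paper_config, PSAConfig(4000, seed=31))
        alt = psa_run(paper_config, PSAConfig(4000, seed=31, **psa_kwargs))
        for key in ALL_PATHWAYS:
            assert alt[key].mean == pytest.approx(base[key].mean, rel=0.02)

    def test_fixed_grade_prices_physicians_at_grade(self, degenerate_paper_config):
        cfg = degenerate_paper_config
        s = psa_run(cfg, PSAConfig(1, seed=0, grade="trainer"))
        for key, summary in s.items():
            det = pathway_cost(expand_pathway(cfg, key), cfg.wages, "trainer").total
            assert summary.mean == pytest.approx(det, rel=1e-12)
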