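"""Distribution fitting, OWSA, scenarios, PSA and acceptability curves."""

import math

import numpy as np
import pytest
from scipy import stats

from hfcea.params import ParameterSpec
from hfcea.sensitivity import (
    BUILTIN_SCENARIOS,
    ScenarioSpec,
    ceac,
    evaluate_pair,
    fit_beta,
    fit_dirichlet,
    fit_gamma,
    owsa,
    run_psa,
    run_scenario,
    sample_parameter_set,
)

WTP = 11008.07


class TestDistributionFits:
    def test_beta_degenerate_range_is_fixed(self):
        assert fit_beta(0.5, 0.5, 0.5) is None

    def test_gamma_moment_identities(self):
        shape, scale = fit_gamma(1785.36, 964.07, 3209.47)
        sd = (3209.47 - 964.07) / (2 * 1.96)
        assert shape * scale == pytest.approx(1785.36)
        assert shape * scale**2 == pytest.approx(sd**2)
        assert (shape, scale) == pytest.approx((1785.36**2 / sd**2, sd**2 / 1785.36))

    def test_beta_mean_preserved_and_quantiles_recover_range(self):
        # NYHA II utility row: the fitted Beta's 95% central interval should
        # land on the declared range within 10% of its half-width
        a, b = fit_beta(0.18, 0.17325, 0.18725)
        d = stats.beta(a, b)
        assert d.mean() == pytest.approx(0.18, abs=1e-9)
        half = (0.18725 - 0.17325) / 2
        assert d.ppf(0.025) == pytest.approx(0.17325, abs=0.1 * half)
        assert d.ppf(0.975) == pytest.approx(0.18725, abs=0.1 * half)

    def test_beta_impossible_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            fit_beta(0.001, -3.0, 3.0)

    def test_dirichlet_concentration(self):
        alpha = fit_dirichlet([0.008, 0.981, 0.010, 0.001], 1000.0)
        assert np.allclose(alpha, [8.0, 981.0, 10.0, 1.0])
        with pytest.raises(ValueError):
            fit_dirichlet([0.5, 0.5, 0.5, 0.5])


class TestOWSA:
    def test_entries_sorted_and_base_case_restored(self, defaults):
        before = defaults.to_dict()
        entries = owsa(defaults, "dapa")
        assert defaults.to_dict() == before  # no state leakage
        spreads = [e.spread for e in entries if not math.isnan(e.spread)]
        assert spreads == sorted(spreads, reverse=True)
        assert len(entries) == len(defaults.parameter_specs)

    def test_collapsed_ranges_reproduce_base_icer(self, defaults):
        base = evaluate_pair(defaults, "dapa").icer
        collapsed = [
            ParameterSpec(s.path, s.mean, s.mean, s.mean, s.distribution)
            for s in defaults.parameter_specs
        ]
        for e in owsa(defaults, "dapa", collapsed):
            assert e.icer_at_low == pytest.approx(base)
            assert e.icer_at_high == pytest.approx(base)
            assert e.spread == pytest.approx(0.0, abs=1e-9)

    def test_discount_rate_bounds_bracket_base_case(self, defaults):
        base = evaluate_pair(defaults, "dapa").icer
        spec = next(
            s for s in defaults.parameter_specs if s.path == "settings.annual_discount"
        )
        (entry,) = owsa(defaults, "dapa", [spec])
        assert entry.icer_at_low < base < entry.icer_at_high

    def test_cv_mortality_dominates_empagliflozin_tornado(self, defaults):
        """Control-2 CV mortality at its low bound pushes the ICER past GDP."""
        entries = {e.path: e for e in owsa(defaults, "empa")}
        e = entries["arms.control2.cv_death_per_cycle"]
        assert e.icer_at_low > defaults.settings.gdp_per_capita
        top_two = [x.path for x in owsa(defaults, "empa")[:2]]
        assert set(top_two) == {
            "arms.control2.cv_death_per_cycle",
            "arms.empagliflozin.cv_death_per_cycle",
        }

    def test_invalid_perturbation_flagged_not_clamped(self, defaults):
        bad = ParameterSpec(
            "arms.dapagliflozin.cv_death_per_cycle", 0.0165, 0.0165, 1.5, "beta"
        )
        (entry,) = owsa(defaults, "dapa", [bad])
        assert entry.invalid
        assert entry.icer_at_high is None
        assert math.isnan(entry.spread)


class TestScenarios:
    def test_empty_overrides_equal_base(self, defaults):
        base = evaluate_pair(defaults, "dapa")
        res = run_scenario(defaults, ScenarioSpec("noop", {}), "dapa")
        assert res.icer == pytest.approx(base.icer)

    def test_unknown_override_path_rejected(self, defaults):
        from hfcea.params import ConfigError

        with pytest.raises(ConfigError):
            run_scenario(
                defaults, ScenarioSpec("bad", {"arms.dapagliflozin.typo": 1}), "dapa"
            )

    def test_icer_decreases_with_hospitalization_cost(self, defaults):
        levels = [
            "hosp_cost_town",
            "hosp_cost_county",
            "hosp_cost_municipal",
            "hosp_cost_provincial",
            "hosp_cost_ministerial",
        ]
        for pair in ("dapa", "empa"):
            icers = [
                run_scenario(defaults, BUILTIN_SCENARIOS[lab], pair).icer
                for lab in levels
            ]
            assert all(a > b for a, b in zip(icers, icers[1:]))

    def test_horizon_20_scenario(self, defaults):
        res = run_scenario(defaults, BUILTIN_SCENARIOS["horizon_20"], "dapa")
        short = run_scenario(defaults, BUILTIN_SCENARIOS["horizon_5"], "dapa")
        assert res.icer < short.icer


class TestPSA:
    def test_same_seed_identical_output(self, defaults):
        a = run_psa(defaults, "dapa", n_draws=25, seed=11)
        b = run_psa(defaults, "dapa", n_draws=25, seed=11)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)
        assert a.sampled.equals(b.sampled)
        c = run_psa(defaults, "dapa", n_draws=25, seed=12)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_degenerate_distributions_reproduce_base_case(self, defaults):
        p = defaults.copy()
        p.parameter_specs = [
            ParameterSpec(s.path, s.mean, s.mean, s.mean, "fixed")
            for s in p.parameter_specs
        ]
        from dataclasses import replace

        p.settings = replace(p.settings, sample_nyha_matrix=False)
        base = evaluate_pair(p, "dapa")
        psa = run_psa(p, "dapa", n_draws=5, seed=0)
        assert np.allclose(psa.delta_cost, base.incremental_cost)
        assert np.allclose(psa.delta_qaly, base.incremental_qaly)
        assert psa.probability_ce(WTP) in (0.0, 1.0)

    def test_sampled_parameter_means_converge(self, defaults):
        """Monte-Carlo means of every sampled input approach the base means."""
        rng = np.random.default_rng(2024)
        n = 10_000
        draws: dict[str, list] = {s.path: [] for s in defaults.parameter_specs}
        from hfcea.sensitivity import _sample_value

        for s in defaults.parameter_specs:
            if s.distribution == "fixed" or s.is_degenerate:
                continue
            vals = np.array([_sample_value(s, rng) for _ in range(n)])
            sd = (s.high - s.low) / (2 * 1.96)
            se = sd / math.sqrt(n)
            assert abs(vals.mean() - s.mean) < 3 * se, s.path

    def test_nyha_rows_sampled_jointly_with_structural_zeros(self, defaults):
        rng = np.random.default_rng(7)
        drawn, overrides = sample_parameter_set(defaults, rng)
        rows = drawn.nyha_matrix.rows
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)
        assert rows[0, 3] == 0.0 and rows[3, 0] == 0.0  # zeros preserved
        assert not np.allclose(rows, defaults.nyha_matrix.rows)
        assert "nyha_matrix.row2" in overrides


class TestCEAC:
    def test_definition_at_zero_and_threshold(self, defaults):
        psa = run_psa(defaults, "dapa", n_draws=60, seed=5)
        curve = ceac(psa, [0.0, WTP])
        assert curve["probability_ce"].iloc[0] == pytest.approx(
            np.mean(psa.delta_cost < 0)
        )
        assert curve["probability_ce"].iloc[1] == pytest.approx(
            psa.probability_ce(WTP)
        )

    def test_monotone_when_all_gains_positive(self, defaults):
        psa = run_psa(defaults, "dapa", n_draws=60, seed=5)
        mask = psa.delta_qaly > 0
        sub = psa.__class__(
            pair=psa.pair,
            seed=psa.seed,
            n_draws=int(mask.sum()),
            delta_cost=psa.delta_cost[mask],
            delta_qaly=psa.delta_qaly[mask],
            sampled=psa.sampled[mask],
        )
        grid = np.linspace(0, 3 * WTP, 30)
        vals = ceac(sub, grid)["probability_ce"].to_numpy()
        assert np.all(np.diff(vals) >= 0)

    def test_step_function_for_degenerate_cloud(self, defaults):
        import pandas as pd

        from hfcea.sensitivity import PSAResult

        psa = PSAResult(
            pair="dapa",
            seed=0,
            n_draws=1,
            delta_cost=np.array([1000.0]),
            delta_qaly=np.array([0.1]),
            sampled=pd.DataFrame(),
        )
        assert psa.probability_ce(9999.0) == 0.0
        assert psa.probability_ce(10001.0) == 1.0

    def test_grid_validation(self, defaults):
        psa = run_psa(defaults, "dapa", n_draws=5, seed=0)
        with pytest.raises(ValueError):
            ceac(psa, [])
        with pytest.raises(ValueError):
            ceac(psa, [-1.0])
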