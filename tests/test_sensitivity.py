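"""Tornado, PSA, CEAC, price scenarios and threshold pricing."""

import numpy as np
import pytest

from psmcea.config import default_config, evaluate, perturbed
from psmcea.costing import ConfigurationError
from psmcea.sensitivity import (ParamSpec, ceac, default_param_specs,
                                draw_parameters, one_way, sample_psa,
                                scenario_price, scenario_table,
                                threshold_price)

N_SMALL = 300  # PSA size for distributional checks
SEED = 20240917


@pytest.fixture(scope="module")
def china_cfg():
    return default_config("china", "overall")


@pytest.fixture(scope="module")
def china_psa(china_cfg):
    return sample_psa(china_cfg, n=N_SMALL, seed=SEED)


class TestOneWay:
    def test_inert_parameter_has_zero_spread(self, china_cfg):
        # hypertension management cost with zero incidence in both arms
        cfg = perturbed(china_cfg, "ae_incidence_switch.hypertension", 0.0)
        spec = ParamSpec("htn cost", "ae_costs.hypertension", 17.824,
                         14.261, 21.387, "gamma")
        entry = one_way(cfg, [spec])[0]
        assert entry.spread == 0.0

    def test_ramucirumab_price_spread_matches_affine_fit(self, china_cfg):
        # ICER is affine in the price, so the spread equals slope x range
        spec = [s for s in default_param_specs(china_cfg)
                if s.path == "prices.ramucirumab"][0]
        entry = one_way(china_cfg, [spec])[0]
        icer = lambda p: evaluate(
            perturbed(china_cfg, spec.path, p)).comparison.icer
        slope = (icer(6.0) - icer(4.0)) / 2.0
        assert entry.spread == pytest.approx(slope * (spec.high - spec.low),
                                             rel=1e-6)

    def test_top_three_influential_parameters(self, china_cfg):
        # utility of PFS, ramucirumab price and patient weight dominate
        top3 = {e.name for e in one_way(china_cfg)[:3]}
        assert top3 == {"utility: pfs", "price: ramucirumab", "patient weight"}

    def test_unresolvable_path_rejected(self, china_cfg):
        bad = ParamSpec("nope", "prices.nonexistent", 1.0, 0.5, 1.5, "gamma")
        with pytest.raises(ConfigurationError):
            one_way(china_cfg, [bad])

    def test_sorted_by_spread(self, china_cfg):
        spreads = [e.spread for e in one_way(china_cfg)]
        assert spreads == sorted(spreads, reverse=True)


class TestParamSpec:
    def test_gamma_moment_match(self):
        spec = ParamSpec("x", "p", 100.0, 80.0, 120.0, "gamma")
        rng = np.random.default_rng(0)
        draws = spec.sampler()(rng, 200000)
        assert draws.mean() == pytest.approx(100.0, rel=0.005)
        assert draws.std() == pytest.approx((120.0 - 80.0) / 3.92, rel=0.02)

    def test_beta_moment_match(self):
        spec = ParamSpec("u", "p", 0.797, 0.64, 0.96, "beta")
        rng = np.random.default_rng(0)
        draws = spec.sampler()(rng, 200000)
        assert draws.mean() == pytest.approx(0.797, rel=0.005)
        assert np.all((draws >= 0) & (draws <= 1))

    def test_beta_infeasible_sd_rejected(self):
        spec = ParamSpec("u", "p", 0.5, 0.0, 1.0, "beta")
        object.__setattr__(spec, "high", 3.0)  # force an oversized range
        with pytest.raises(ConfigurationError):
            spec.sampler()

    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            ParamSpec("u", "p", 1.5, 1.2, 1.8, "beta")


class TestPSA:
    def test_all_fixed_specs_reproduce_base_case(self, china_cfg):
        base = evaluate(china_cfg).comparison
        specs = [ParamSpec("w", "patient.weight", 69.0, 69.0, 69.0, "fixed")]
        psa = sample_psa(china_cfg, specs, n=5, seed=1)
        assert np.allclose(psa.delta_cost, base.delta_cost)
        assert np.allclose(psa.delta_qaly, base.delta_qaly)

    def test_seed_reproducibility_bit_exact(self, china_cfg, china_psa):
        again = sample_psa(china_cfg, n=N_SMALL, seed=SEED)
        assert np.array_equal(again.delta_cost, china_psa.delta_cost)
        assert np.array_equal(again.delta_qaly, china_psa.delta_qaly)

    def test_sampled_means_near_base_values(self, china_cfg):
        # parameter sample means within 2 Monte-Carlo standard errors
        specs = default_param_specs(china_cfg)
        samples = draw_parameters(specs, 2000, seed=3)
        for spec in specs:
            if spec.distribution == "fixed":
                continue
            col = samples[spec.path]
            mcse = col.std() / np.sqrt(len(col))
            assert abs(col.mean() - spec.base) <= 3 * mcse, spec.name

    def test_draw_count_matches_request(self, china_psa):
        assert china_psa.n == N_SMALL


class TestCEAC:
    def test_lambda_zero_is_cost_saving_fraction(self, china_psa):
        df = ceac(china_psa, [0.0])
        expected = float(np.mean(china_psa.delta_cost < 0))
        assert df["probability"].iloc[0] == expected

    def test_large_lambda_is_effective_fraction(self, china_psa):
        df = ceac(china_psa, [1e12])
        expected = float(np.mean(china_psa.delta_qaly > 0))
        assert df["probability"].iloc[0] == expected

    def test_degenerate_draws_probability_zero(self, china_cfg):
        specs = [ParamSpec("w", "patient.weight", 69.0, 69.0, 69.0, "fixed")]
        psa = sample_psa(china_cfg, specs, n=3, seed=1)
        # base case: dC > 0 and ICER far above the WTP threshold
        assert psa.acceptance_probability() == 0.0

    def test_monotone_in_wtp_for_effective_treatment(self, china_psa):
        grid = np.linspace(0.0, 2e6, 9)
        probs = ceac(china_psa, grid)["probability"].to_numpy()
        if np.all(china_psa.delta_qaly > 0):
            assert np.all(np.diff(probs) >= 0)


class TestScenarios:
    def test_multiplier_one_is_identity(self, china_cfg):
        base = evaluate(china_cfg).comparison
        assert scenario_price(china_cfg, 1.0).icer == pytest.approx(base.icer)

    def test_icer_affine_in_multiplier(self, china_cfg):
        icers = {m: scenario_price(china_cfg, m).icer for m in (1.0, 0.75, 0.5)}
        assert icers[0.75] == pytest.approx((icers[1.0] + icers[0.5]) / 2.0,
                                            rel=1e-9)

    def test_three_point_collinearity_tight(self, china_cfg):
        # ICER affine in the ramucirumab unit price to 1e-6 relative
        icers = [scenario_price(china_cfg, m).icer for m in (0.25, 0.625, 1.0)]
        assert icers[1] == pytest.approx((icers[0] + icers[2]) / 2.0, rel=1e-6)

    def test_scenario_table_shape(self, china_cfg):
        df = scenario_table(china_cfg)
        assert list(df["price_multiplier"]) == [1.0, 0.75, 0.5, 0.25]
        assert df["icer"].is_monotonic_decreasing

    def test_invalid_multiplier_rejected(self, china_cfg):
        with pytest.raises(ValueError):
            scenario_price(china_cfg, 0.0)


class TestThresholdPrice:
    def test_acceptance_monotone_in_price_with_crn(self, china_cfg):
        # common random numbers: acceptance probability non-increasing in price
        specs = [s for s in default_param_specs(china_cfg)
                 if s.path != "prices.ramucirumab"]
        samples = draw_parameters(specs, 150, seed=5)
        probs = []
        for mult in (0.05, 0.15, 0.4, 1.0):
            cfg = perturbed(china_cfg, "prices.ramucirumab",
                            china_cfg.prices["ramucirumab"] * mult)
            psa = sample_psa(cfg, specs, samples=samples)
            probs.append(psa.acceptance_probability())
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_finds_fifty_percent_price(self, china_cfg):
        res = threshold_price(china_cfg, 0.5, n=400, seed=9, tol=0.02)
        assert res.converged
        assert 0.0 < res.multiplier < 1.0
        assert res.acceptance_probability == pytest.approx(0.5, abs=0.07)

    def test_unreachable_target_reported(self, china_cfg):
        # at WTP 0 acceptance requires strict cost saving; even a free drug
        # only saves cost in roughly half the draws, so 95% is out of reach
        res = threshold_price(china_cfg, 0.95, wtp=0.0, n=100, seed=9)
        assert res.price_per_mg is None and not res.converged
        assert "zero price" in res.message
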