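import numpy as np
import pytest

from gastric_cea import (ParamSpec, ce_probability, ceac, confidence_ellipse,
                         one_way, run_psa, sample_param)
from gastric_cea.config import base_values, make_model_fn
from gastric_cea.sensitivity import _raw_icer


class TestParamSpec:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, 2.0, 3.0, "gamma")  # median below low

    def test_beta_bounds_enforced(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 1.2, 1.1, 1.3, "beta")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, 0.5, 1.5, "triangular")


class TestSampling:
    def test_fixed_returns_median(self, rng):
        spec = ParamSpec("x", 0.03, 0.0, 0.08, "fixed")
        assert all(sample_param(spec, rng) == 0.03 for _ in range(5))

    def test_beta_moment_matching(self, rng):
        """Mean of moment-matched beta draws equals the target mean within
        3 standard errors (range read as a 95% interval)."""
        spec = ParamSpec("second line", 0.25, 0.2, 0.3, "beta")
        draws = np.array([sample_param(spec, rng) for _ in range(100_000)])
        sd = (0.3 - 0.2) / 3.92
        assert draws.mean() == pytest.approx(0.25,
                                             abs=3 * sd / np.sqrt(draws.size))
        assert draws.std() == pytest.approx(sd, rel=0.05)
        assert np.all((draws > 0) & (draws < 1))

    def test_lognormal_median_preserved(self, rng):
        """The lognormal is parameterised by mu = ln(median): the empirical
        median of draws matches the published median."""
        spec = ParamSpec("oxaliplatin", 232.8, 50.4, 688.7, "lognormal")
        draws = np.array([sample_param(spec, rng) for _ in range(100_000)])
        sigma = (np.log(688.7) - np.log(50.4)) / 3.92
        se_median = 1.2533 * sigma / np.sqrt(draws.size)  # on the log scale
        assert np.log(np.median(draws)) == pytest.approx(np.log(232.8),
                                                         abs=3 * se_median)

    def test_gamma_moment_matching(self, rng):
        spec = ParamSpec("ct", 105.2, 52.6, 157.8, "gamma")
        draws = np.array([sample_param(spec, rng) for _ in range(100_000)])
        sd = (157.8 - 52.6) / 3.92
        assert draws.mean() == pytest.approx(105.2,
                                             abs=3 * sd / np.sqrt(draws.size))
        assert np.all(draws > 0)

    def test_infeasible_beta_falls_back_to_uniform(self, rng):
        # sd far too large for a beta mean of 0.5 -> uniform(low, high)
        wide = ParamSpec("broken", 0.05, 0.0, 1.0, "beta")
        with pytest.warns(RuntimeWarning, match="infeasible"):
            draws = [sample_param(wide, rng) for _ in range(200)]
        assert all(0.0 <= d <= 1.0 for d in draws)


@pytest.fixture(scope="module")
def model_fn(config):
    return make_model_fn(config)


@pytest.fixture(scope="module")
def psa_result(config, model_fn):
    return run_psa(1000, 20131210, config.parameters, model_fn,
                   base_values(config))


class TestPSA:
    def test_reproducible_given_seed(self, config, model_fn):
        a = run_psa(50, 7, config.parameters, model_fn, base_values(config))
        b = run_psa(50, 7, config.parameters, model_fn, base_values(config))
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)
        c = run_psa(50, 8, config.parameters, model_fn, base_values(config))
        assert not np.array_equal(a.costs, c.costs)

    def test_degenerate_psa_equals_base_case(self, config, model_fn,
                                             base_case):
        """With every distribution collapsed to its median the PSA must
        reproduce the deterministic base case exactly."""
        fixed = [ParamSpec(s.name, s.median, s.median, s.median, "fixed",
                           target=s.target) for s in config.parameters]
        psa = run_psa(3, 0, fixed, model_fn, base_values(config))
        for j, arm in enumerate(psa.strategies):
            cost, qaly = base_case.ce.totals[arm]
            np.testing.assert_allclose(psa.costs[:, j], cost, rtol=1e-12)
            np.testing.assert_allclose(psa.qalys[:, j], qaly, rtol=1e-12)

    def test_invalid_inputs_rejected(self, config, model_fn):
        with pytest.raises(ValueError):
            run_psa(0, 1, config.parameters, model_fn, base_values(config))
        with pytest.raises(TypeError):
            run_psa(5, "seed", config.parameters, model_fn,
                    base_values(config))

    def test_ce_probability_complement(self, psa_result):
        p_ab = ce_probability(psa_result, ("XELOX", "S-1"), 13527.0)
        p_ba = ce_probability(psa_result, ("S-1", "XELOX"), 13527.0)
        assert p_ab + p_ba == pytest.approx(1.0)  # ties have measure zero

    def test_ce_probability_at_zero_wtp_is_cost_comparison(self, psa_result):
        p = ce_probability(psa_result, ("XELOX", "S-1"), 0.0)
        cheaper = np.mean(
            psa_result.costs[:, psa_result.strategy_index("XELOX")]
            < psa_result.costs[:, psa_result.strategy_index("S-1")])
        assert p == pytest.approx(float(cheaper))


class TestCEAC:
    def test_probabilities_sum_to_one(self, psa_result, config):
        curves = ceac(psa_result, config.psa.wtp_grid)
        p_cols = [c for c in curves.columns if c.startswith("p_")]
        np.testing.assert_allclose(curves[p_cols].sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_surgery_only_declines_to_zero(self, psa_result, config):
        """SO can only win on cost: its acceptability is (weakly) falling
        in the threshold and vanishes at high willingness-to-pay."""
        curves = ceac(psa_result, config.psa.wtp_grid)
        p_so = curves["p_SO"].to_numpy()
        assert p_so[-1] == 0.0
        assert p_so[0] == p_so.max()
        # no substantial rises along the grid
        assert np.all(np.diff(p_so) <= 0.02)


class TestOneWay:
    def test_zero_range_parameter_ranked_last(self, config, model_fn):
        specs = list(config.parameters[:3]) + [
            ParamSpec("inert", 0.5, 0.5, 0.5, "fixed", target="utility_ps")]
        entries = one_way(specs, model_fn, ("XELOX", "S-1"),
                          base_values(config))
        assert entries[-1].parameter == "inert"
        assert entries[-1].spread == 0.0

    def test_utilities_dominate_ae_costs(self, config, model_fn):
        """The qualitative tornado finding: DFS utilities are the most
        influential inputs, adverse-event costs and risks the least."""
        specs = config.parameters + config.one_way_extra
        entries = one_way(specs, model_fn, ("XELOX", "S-1"),
                          base_values(config))
        ranked = [e.parameter for e in entries]
        assert all("Utility of DFS" in name for name in ranked[:3])
        # the least influential inputs move the ICER by a negligible amount
        top_spread = entries[0].spread
        assert all(e.spread < 0.005 * top_spread for e in entries[-5:])

    def test_cost_parameter_spread_matches_linearity(self, config, model_fn):
        """For a pure cost parameter the QALY increment is unchanged, so the
        tornado spread equals |dC(high) - dC(low)| / dE from two re-runs."""
        spec = next(s for s in config.parameters
                    if s.target == "cost_supportive_care")
        entries = one_way([spec], model_fn, ("XELOX", "S-1"),
                          base_values(config))
        e = entries[0]
        base = base_values(config)
        icers = {}
        for end, v in (("low", spec.low), ("high", spec.high)):
            vals = dict(base)
            vals[spec.target] = v
            icers[end] = _raw_icer(model_fn(vals), "XELOX", "S-1")
        assert e.icer_at_low == pytest.approx(icers["low"], rel=1e-12)
        assert e.spread == pytest.approx(abs(icers["high"] - icers["low"]),
                                         rel=1e-12)


class TestConfidenceEllipse:
    def test_centred_on_circular_points(self):
        ang = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.c_[np.cos(ang), np.sin(ang)]
        ell = confidence_ellipse(pts, level=0.95)
        assert ell.center[0] == pytest.approx(0.0, abs=1e-12)
        assert ell.center[1] == pytest.approx(0.0, abs=1e-12)
        assert ell.semi_axes[0] == pytest.approx(ell.semi_axes[1], rel=1e-6)

    def test_coverage_of_bivariate_normal(self, rng):
        """~95% of an independent sample from the same bivariate normal
        falls inside the 95% ellipse (3-standard-error Monte Carlo band)."""
        n = 20_000
        train = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 1.0]],
                                        size=5_000)
        test = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 1.0]],
                                       size=n)
        ell = confidence_ellipse(train, level=0.95)
        cover = ell.contains(test).mean()
        se = np.sqrt(0.95 * 0.05 / n)
        assert cover == pytest.approx(0.95, abs=3 * se + 0.005)

    def test_degenerate_points_rejected(self):
        pts = np.ones((10, 2))
        with pytest.raises(ValueError, match="singular|degenerate"):
            confidence_ellipse(pts)
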