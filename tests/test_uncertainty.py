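import numpy as np
import pandas as pd
import pytest

from sodiumcea.uncertainty import (
    ParamDistribution,
    default_psa_params,
    run_psa,
    run_scenarios,
    run_tornado,
)


def _degenerate_params(spec):
    return [ParamDistribution(p.name, "normal", 1.0, 0.0)
            for p in default_psa_params(spec)]


class TestParamDistribution:
    def test_multiplier_draws_are_non_negative(self):
        rng = np.random.default_rng(0)
        for kind, loc, scale in [("normal", 1.0, 0.5), ("lognormal", 1.0, 0.3),
                                 ("uniform", 0.0, 2.0), ("beta", 2.0, 2.0)]:
            draws = ParamDistribution("p", kind, loc, scale).sample(rng, 500)
            assert (draws >= 0).all()

    def test_percentiles_bracket_the_median(self):
        p = ParamDistribution("p", "lognormal", 1.0, 0.2)
        assert p.percentile(2.5) < 1.0 < p.percentile(97.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ParamDistribution("p", "cauchy", 0.0, 1.0).percentile(50)


class TestPsa:
    def test_same_seed_reproduces_interval(self, inputs, full_mandatory):
        a = run_psa(inputs, full_mandatory, n_draws=120, seed=5)
        b = run_psa(inputs, full_mandatory, n_draws=120, seed=5)
        assert a.ui95 == b.ui95
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_degenerate_distributions_collapse_to_point(self, inputs,
                                                        full_mandatory):
        res = run_psa(inputs, full_mandatory, n_draws=100, seed=1,
                      params=_degenerate_params(full_mandatory))
        lo, hi = res.ui95["dqaly"]
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(res.point[0], rel=1e-9)

    def test_point_estimate_inside_interval(self, inputs, full_mandatory):
        res = run_psa(inputs, full_mandatory, n_draws=200, seed=2)
        lo, hi = res.ui95["dqaly"]
        assert lo <= res.point[0] <= hi
        clo, chi = res.ui95["dcost"]
        assert clo <= res.point[1] <= chi

    def test_too_few_draws_rejected(self, inputs, full_mandatory):
        with pytest.raises(ValueError):
            run_psa(inputs, full_mandatory, n_draws=50, seed=1)


class TestTornado:
    def test_bars_sorted_and_zero_variance_ranked_last(self, inputs,
                                                       full_mandatory):
        params = default_psa_params(full_mandatory)
        params.append(ParamDistribution("frozen", "normal", 1.0, 0.0))
        res = run_tornado(inputs, full_mandatory, params=params)
        widths = res.table["cost_width"].to_numpy()
        assert (np.diff(widths) <= 1e-9).all()
        assert res.table.iloc[-1]["param"] in ("frozen", "disease_yld")
        frozen = res.table.set_index("param").loc["frozen"]
        assert frozen["cost_width"] == pytest.approx(0.0, abs=1e-6)
        assert frozen["qaly_width"] == pytest.approx(0.0, abs=1e-6)

    def test_widening_a_distribution_widens_only_its_own_bar(self, inputs,
                                                             full_mandatory):
        base_params = [
            ParamDistribution("chd_cost", "lognormal", 1.0, 0.10),
            ParamDistribution("sbp_coeff", "lognormal", 1.0, 0.10),
        ]
        wide_params = [
            ParamDistribution("chd_cost", "lognormal", 1.0, 0.30),
            ParamDistribution("sbp_coeff", "lognormal", 1.0, 0.10),
        ]
        base = run_tornado(inputs, full_mandatory, params=base_params)
        wide = run_tornado(inputs, full_mandatory, params=wide_params)
        b = base.table.set_index("param")
        w = wide.table.set_index("param")
        assert w.loc["chd_cost", "cost_width"] > b.loc["chd_cost", "cost_width"]
        assert w.loc["sbp_coeff", "cost_width"] == pytest.approx(
            b.loc["sbp_coeff", "cost_width"], rel=1e-9)

    def test_effect_and_disease_cost_outrank_minor_cost_params(self, inputs,
                                                               full_mandatory):
        res = run_tornado(inputs, full_mandatory)
        order = list(res.table["param"])
        for major in ("sbp_coeff", "effect_size", "chd_cost", "stroke_cost"):
            assert order.index(major) < order.index("healthy_cost")
        assert order[-1] == "disease_yld"  # no effect on costs at all


@pytest.fixture(scope="module")
def grid(inputs, specs):
    pair = [s for s in specs if s.id == 1]
    return run_scenarios(inputs, pair)


class TestScenarios:
    def test_grid_covers_discounts_and_half_effect(self, grid):
        assert set(grid["discount_rate"]) == {0.0, 0.03, 0.06}
        assert set(grid["half_effect"]) == {False, True}
        # 2 specs + 1 half-effect voluntary variant, at 3 discount rates
        assert len(grid) == 9

    def test_half_effect_gains_less_than_full_effect(self, grid):
        vol = grid[(grid["mode"] == "voluntary") & (grid["discount_rate"] == 0.03)]
        full = vol[~vol["half_effect"]]["dqaly"].iloc[0]
        half = vol[vol["half_effect"]]["dqaly"].iloc[0]
        assert half < full

    def test_gains_anti_monotone_in_discount_rate(self, grid):
        mand = grid[(grid["mode"] == "mandatory") & (~grid["half_effect"])]
        by_rate = mand.set_index("discount_rate")["dqaly"]
        assert by_rate[0.0] > by_rate[0.03] > by_rate[0.06]

    def test_every_cell_is_cost_saving(self, grid):
        assert (grid["net_cost"] < 0).all()
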