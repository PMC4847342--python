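import copy

import numpy as np
import pytest

from sodiumcea import run_cohort
from sodiumcea.economics import (
    COST_COMPONENTS,
    DiscountConfig,
    InterventionCostConfig,
    accrue_costs,
    accrue_qalys,
    discount_factor,
    evaluate_intervention,
    incremental,
    intervention_cost,
)
from sodiumcea.strata import DISEASES, start_age

NO_PROGRAMME_COST = InterventionCostConfig(annual={"mandatory": 0.0,
                                                   "voluntary": 0.0})


class TestDiscounting:
    def test_reference_year_factor_is_one(self):
        assert discount_factor(2011, DiscountConfig(0.03)) == 1.0

    def test_zero_rate_is_always_one(self):
        cfg = DiscountConfig(0.0)
        for year in (2011, 2030, 2070):
            assert discount_factor(year, cfg) == 1.0

    def test_ten_year_closed_form(self):
        assert discount_factor(2021, DiscountConfig(0.03)) == pytest.approx(
            1.03 ** -10)

    def test_year_before_reference_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(2010, DiscountConfig(0.03))


class TestQalyAccrual:
    def test_closed_form_with_full_health_and_no_deaths(self, zero_event_inputs):
        """Weights 1, no deaths, no discounting: QALYs = sum count x years."""
        z = copy.deepcopy(zero_event_inputs)
        z.morbidity.background_pyld[:] = 0.0
        for d in DISEASES:
            z.morbidity.disease_yld_per_case[d][:] = 0.0
        traj = run_cohort(z)
        got = accrue_qalys(traj, z.morbidity, DiscountConfig(0.0)).sum()
        from sodiumcea import strata

        expected = sum(
            z.population.counts[k.indices] * (100 - start_age(k.age_band))
            for k in strata.iter_strata()
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_discounting_monotonicity(self, inputs, comparator_traj):
        q = [accrue_qalys(comparator_traj, inputs.morbidity,
                          DiscountConfig(r)).sum() for r in (0.0, 0.03, 0.06)]
        assert q[0] > q[1] > q[2]


class TestCostAccrual:
    def test_zero_occupancy_costs_nothing(self, inputs, comparator_traj):
        empty = copy.deepcopy(inputs)
        traj = copy.deepcopy(comparator_traj)
        traj.occupancy[:] = 0.0
        traj.flows[:] = 0.0
        total = accrue_costs(traj, empty.costs)["total"]
        assert total.sum() == 0.0

    def test_linearity_in_cost_inputs(self, inputs, comparator_traj):
        doubled = copy.deepcopy(inputs)
        for d in DISEASES:
            doubled.costs.first_year_cost[d] *= 2
            doubled.costs.subsequent_year_cost[d] *= 2
        doubled.costs.healthy_background_cost *= 2
        doubled.costs.last6m_cost *= 2
        base = accrue_costs(comparator_traj, inputs.costs)["total"].sum()
        twice = accrue_costs(comparator_traj, doubled.costs)["total"].sum()
        assert twice == pytest.approx(2 * base, rel=1e-12)

    def test_public_share_scales_all_costs(self, inputs, comparator_traj):
        unscaled = copy.deepcopy(inputs)
        unscaled.costs.public_share_scale = 1.0
        got = accrue_costs(comparator_traj, inputs.costs)["total"].sum()
        raw = accrue_costs(comparator_traj, unscaled.costs)["total"].sum()
        assert got == pytest.approx(raw * 1.2, rel=1e-12)

    def test_old_age_multiplier_reaches_1_3(self, inputs):
        """An 85+ cohort's costs carry the 1.3 age scale, applied once."""
        from sodiumcea import strata

        world = copy.deepcopy(inputs)
        world.population.counts[:] = 0.0
        key = strata.StratumKey("male", 10, "non_maori")  # starts at age 87
        s, b, e = key.indices
        world.population.counts[s, b, e] = 1000.0
        # no disease, near-certain death in the first cycle: the accrual is
        # one year of background cost plus end-of-life cost, hand-computable
        for d in DISEASES:
            world.epi.incidence[d][:] = 0.0
            world.epi.prevalence[d][:] = 0.0
            world.epi.case_fatality[d][:] = 0.0
        world.epi.background_mortality[:] = 50.0
        from sodiumcea.markov import TrendParams

        no_trend = TrendParams(mortality_decline={"maori": 0.0,
                                                  "non_maori": 0.0})
        traj = run_cohort(world, trends=no_trend)
        got = accrue_costs(traj, world.costs, DiscountConfig(0.0))["total"].sum()
        p_die = 1.0 - np.exp(-50.0)
        expected = 1000.0 * (world.costs.healthy_background_cost[s, b, e]
                             + p_die * world.costs.last6m_cost[s, b, e]
                             ) * 1.2 * 1.3
        assert got == pytest.approx(expected, rel=1e-9)


class TestIncremental:
    def test_identical_runs_are_exactly_zero(self, inputs, comparator_traj,
                                             full_mandatory):
        q = accrue_qalys(comparator_traj, inputs.morbidity)
        c = accrue_costs(comparator_traj, inputs.costs)
        res = incremental(q, q, c, c, comparator_traj.counts,
                          full_mandatory, programme_cost=0.0)
        assert res.qalys_gained == 0.0
        assert res.net_cost == 0.0

    def test_net_cost_decomposes_exactly(self, inputs, full_mandatory,
                                         comparator_traj):
        res = evaluate_intervention(inputs, full_mandatory,
                                    comparator_traj=comparator_traj)
        assert res.net_cost == pytest.approx(
            sum(res.cost_components[k] for k in COST_COMPONENTS)
            + res.intervention_cost, rel=1e-12)

    def test_longevity_adds_background_costs(self, inputs, full_mandatory,
                                             comparator_traj):
        """Extra life-years bought by the intervention accrue new costs."""
        res = evaluate_intervention(inputs, full_mandatory,
                                    comparator_traj=comparator_traj)
        assert res.cost_components["healthy_background"] > 0
        # ... but averted disease costs dominate (the run is cost-saving)
        assert res.cost_components["disease_first_year"] < 0
        assert res.cost_components["disease_subsequent"] < 0
        assert res.net_cost < 0

    def test_subgroups_reaggregate_to_total(self, inputs, full_mandatory,
                                            comparator_traj):
        res = evaluate_intervention(inputs, full_mandatory,
                                    comparator_traj=comparator_traj)
        pa = res.per_adult.set_index("group")
        for partition in (("women", "men"), ("maori", "non_maori"),
                          ("age<65", "age65+")):
            total_q = sum(pa.loc[g, "dqaly_per_adult"] * pa.loc[g, "population"]
                          for g in partition)
            assert total_q == pytest.approx(res.qalys_gained, rel=1e-9)
            total_c = sum(pa.loc[g, "dcost_per_adult"] * pa.loc[g, "population"]
                          for g in partition)
            assert total_c == pytest.approx(res.net_cost, rel=1e-9)

    def test_per_adult_gain_larger_for_men_and_maori(self, inputs,
                                                     full_mandatory,
                                                     comparator_traj):
        res = evaluate_intervention(inputs, full_mandatory,
                                    comparator_traj=comparator_traj)
        pa = res.per_adult.set_index("group")["dqaly_per_adult"]
        assert pa["men"] > pa["women"]
        assert pa["maori"] > pa["non_maori"]

    def test_qaly_gain_non_negative_for_risk_reduction(self, inputs, specs,
                                                       comparator_traj):
        for spec in specs:
            res = evaluate_intervention(inputs, spec,
                                        comparator_traj=comparator_traj,
                                        prog_costs=NO_PROGRAMME_COST)
            assert res.qalys_gained >= 0.0


def test_programme_cost_discounted_over_phase_in(full_mandatory, full_voluntary):
    cfg = DiscountConfig(0.03)
    costs = InterventionCostConfig(annual={"mandatory": 1e6, "voluntary": 1e6})
    mand = intervention_cost(full_mandatory, cfg, costs)
    vol = intervention_cost(full_voluntary, cfg, costs)
    assert mand == pytest.approx(sum(1e6 * 1.03 ** -t for t in range(3)))
    assert vol == pytest.approx(sum(1e6 * 1.03 ** -t for t in range(5)))
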