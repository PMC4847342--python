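import math

import numpy as np
import pytest

from sodiumcea import run_cohort
from sodiumcea.markov import (
    CHD,
    DEAD,
    HEALTHY,
    STROKE,
    build_transitions,
    rate_to_prob,
    trend_adjust,
)
from sodiumcea.strata import StratumKey


class TestTrendAdjust:
    def test_base_year_is_identity(self):
        assert trend_adjust(0.05, 2011, 0.02) == pytest.approx(0.05)

    def test_closed_form_at_trend_end(self):
        assert trend_adjust(1.0, 2026, 0.02) == pytest.approx(0.98 ** 15)

    def test_held_constant_after_2026(self):
        assert trend_adjust(1.0, 2040, 0.02) == trend_adjust(1.0, 2026, 0.02)

    def test_year_before_base_rejected(self):
        with pytest.raises(ValueError):
            trend_adjust(1.0, 2010, 0.02)


class TestRateToProb:
    def test_closed_forms(self):
        assert rate_to_prob(0.0) == 0.0
        assert rate_to_prob(math.log(2)) == pytest.approx(0.5)
        assert rate_to_prob(0.01) == pytest.approx(0.00995, abs=1e-5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.1)

    def test_always_a_probability(self):
        rates = np.logspace(-6, np.log10(20), 50)  # up to 20 events/year
        p = rate_to_prob(rates)
        assert ((p >= 0) & (p < 1)).all()


class TestBuildTransitions:
    def test_rows_sum_to_one_and_dead_absorbs(self, inputs):
        for key in (StratumKey("male", 0, "maori"),
                    StratumKey("female", 12, "non_maori")):
            m = build_transitions(key, 2020, inputs.epi)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert ((m >= 0) & (m <= 1)).all()
            assert m[DEAD, DEAD] == 1.0 and m[DEAD, :DEAD].sum() == 0.0
            assert m[CHD, HEALTHY] == 0.0 and m[STROKE, HEALTHY] == 0.0

    def test_unit_relative_risk_matches_comparator(self, inputs):
        key = StratumKey("male", 4, "non_maori")
        base = build_transitions(key, 2018, inputs.epi)
        with_rr = build_transitions(key, 2018, inputs.epi,
                                    rr={"chd": 1.0, "stroke": 1.0})
        np.testing.assert_array_equal(base, with_rr)

    def test_relative_risk_halves_rate_before_conversion(self, inputs):
        key = StratumKey("female", 6, "maori")
        s, b, e = key.indices
        m = build_transitions(key, 2011, inputs.epi, rr={"chd": 0.5})
        expected = 1 - math.exp(-inputs.epi.incidence["chd"][s, b, e] * 0.5)
        assert m[HEALTHY, CHD] == pytest.approx(expected, rel=1e-12)

    def test_all_zero_rates_give_identity(self, zero_event_inputs):
        m = build_transitions(StratumKey("male", 0, "maori"), 2011,
                              zero_event_inputs.epi)
        np.testing.assert_array_equal(m, np.eye(4))

    def test_invalid_relative_risk_rejected(self, inputs):
        with pytest.raises(ValueError):
            build_transitions(StratumKey("male", 0, "maori"), 2011,
                              inputs.epi, rr={"chd": 1.5})

    def test_impossible_probabilities_name_the_stratum_year(self, inputs):
        import copy

        bad = copy.deepcopy(inputs)
        bad.epi.incidence["chd"][:] = 50.0
        bad.epi.incidence["stroke"][:] = 50.0
        bad.epi.background_mortality[:] = 50.0
        with pytest.raises(ValueError, match="2011"):
            build_transitions(StratumKey("male", 0, "maori"), 2011, bad.epi)


class TestRunCohort:
    def test_mass_conservation_every_cycle(self, inputs, comparator_traj):
        totals = comparator_traj.occupancy.sum(axis=2)
        rel_err = np.abs(totals - comparator_traj.counts) / inputs.population.total
        assert rel_err.max() < 1e-9

    def test_occupancy_never_negative(self, comparator_traj):
        assert (comparator_traj.occupancy >= -1e-12).all()

    def test_deterministic(self, inputs, comparator_traj):
        again = run_cohort(inputs)
        np.testing.assert_array_equal(again.occupancy, comparator_traj.occupancy)
        np.testing.assert_array_equal(again.flows, comparator_traj.flows)

    def test_no_deaths_without_fatality_or_mortality(self, zero_event_inputs):
        import copy

        z = copy.deepcopy(zero_event_inputs)
        for d in ("chd", "stroke"):
            z.epi.incidence[d] = zero_event_inputs.epi.incidence[d].copy()
            z.epi.incidence[d][:] = 0.01  # events happen, nobody dies
        traj = run_cohort(z)
        assert traj.flows[:, :, 2].sum() == 0.0
        assert traj.occupancy[-1, :, DEAD].sum() == 0.0

    def test_first_cycle_matches_explicit_matrices(self, inputs, comparator_traj):
        """Engine update == occupancy @ transition matrix, stratum by stratum."""
        from sodiumcea import strata

        for key in (StratumKey("male", 0, "maori"),
                    StratumKey("female", 7, "non_maori"),
                    StratumKey("male", 12, "maori")):
            idx = strata.stratum_index(key)
            m = build_transitions(key, inputs.population.base_year, inputs.epi)
            expected = comparator_traj.occupancy[0, idx] @ m
            np.testing.assert_allclose(comparator_traj.occupancy[1, idx],
                                       expected, rtol=1e-12)

    def test_simulation_stops_at_age_cap(self, comparator_traj):
        assert (comparator_traj.ages[comparator_traj.active] < 100).all()
        last = comparator_traj.n_cycles - 1
        # the oldest stratum (95+) is frozen long before the youngest ends
        assert not comparator_traj.active[last].all()
        assert comparator_traj.active[0].all()


def test_trajectory_frame_shape(inputs):
    small = run_cohort(inputs)
    df = small.to_frame()
    assert set(df.columns) == {"sex", "age_band", "ethnicity", "year",
                               "state", "occupancy"}
    assert df["state"].nunique() == 4
    assert len(df) == (small.n_cycles + 1) * 52 * 4
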