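"""Engine invariants: conservation, capacity, determinism, oracles."""

import numpy as np
import pytest

import opsmodel as om
from opsmodel.model import largest_remainder


class TestLargestRemainder:
    def test_exact_total(self):
        out = largest_remainder(100, np.array([0.333, 0.333, 0.334]))
        assert out.sum() == 100

    def test_within_one_of_exact_share(self):
        props = np.array([0.1, 0.2, 0.3, 0.4])
        out = largest_remainder(1234, props)
        assert out.sum() == 1234
        assert np.all(np.abs(out - 1234 * props) <= 1.0)

    def test_deterministic_tie_break(self):
        a = largest_remainder(5, np.array([0.25, 0.25, 0.25, 0.25]))
        b = largest_remainder(5, np.array([0.25, 0.25, 0.25, 0.25]))
        np.testing.assert_array_equal(a, b)


class TestInitialize:
    def test_baseline_totals(self, baseline, profile):
        state = om.initialize(baseline, profile)
        assert state.not_using.sum() == 55_000
        assert state.treatment.sum() == 12_896  # rounded equilibrium
        assert state.fatal_events == 0 and state.entrants == 0

    def test_single_ring_gets_all_mass(self, baseline, single_ring_profile):
        state = om.initialize(baseline, single_ring_profile)
        assert state.not_using[0] == 55_000

    def test_explicit_treatment_seed(self, baseline, profile):
        p = baseline.replace(initial_treatment_count=5000)
        assert om.initialize(p, profile).treatment.sum() == 5000


class TestStepInvariants:
    def test_conservation_and_capacity_over_steps(self, profile):
        """Alive + dead stays equal to initial + entrants; occupancy obeys
        the capacity bound and is zero outside opening hours."""
        params = om.ModelParameters(
            n_users_initial=3000, ops_capacity=3, new_entrants_per_day=2.0, horizon_days=5
        )
        rng = np.random.default_rng(0)
        state = om.initialize(params, profile)
        initial = state.alive_total
        for t in range(2 * params.steps_per_day):
            state = om.step(state, params, profile, t, rng)
            assert state.alive_total + state.fatal_events == initial + state.entrants
            assert state.using_ops.sum() <= params.ops_capacity
            if t % params.steps_per_day >= params.open_steps_per_day:
                assert state.using_ops.sum() == 0

    def test_no_site_means_no_ops_state(self, profile):
        params = om.ModelParameters(n_users_initial=2000, ops_capacity=0, horizon_days=2)
        rng = np.random.default_rng(1)
        state = om.initialize(params, profile)
        for t in range(params.steps_per_day):
            state = om.step(state, params, profile, t, rng)
            assert state.using_ops.sum() == 0
        assert state.ops_visits == 0

    def test_zero_risk_closed_population_is_static(self, profile):
        params = om.ModelParameters(
            n_users_initial=1000,
            annual_nonfatal_od=0.0,
            annual_fatal_od=0.0,
            new_entrants_per_day=0.0,
            horizon_days=2,
        )
        rng = np.random.default_rng(2)
        state = om.initialize(params, profile)
        initial = state.alive_total
        for t in range(50):
            state = om.step(state, params, profile, t, rng)
        assert state.fatal_events == 0 and state.nonfatal_events == 0
        assert state.alive_total == initial


class TestSimulateYear:
    def test_same_seed_identical(self, small_params, profile):
        a = om.simulate_year(small_params, profile, seed=7)
        b = om.simulate_year(small_params, profile, seed=7)
        assert a.fatal == b.fatal and a.nonfatal == b.nonfatal
        assert a.entrants == b.entrants
        np.testing.assert_array_equal(a.revived_by_ring, b.revived_by_ring)

    def test_single_replicate_matches_batch_of_one(self, small_params, profile):
        single = om.simulate_year(small_params, profile, seed=9)
        batch = om.run_replicates(small_params, profile, 1, seed=9)
        assert batch.table.loc[0, "fatal"] == single.fatal
        assert batch.table.loc[0, "nonfatal"] == single.nonfatal

    def test_fatal_count_near_mean_field(self, small_params, profile):
        fatal_mf, _ = om.expected_annual_events_no_ops(small_params)
        result = om.simulate_year(small_params, profile, seed=3)
        # single replicate within 5 SD of the expectation (Poisson-scale SD)
        assert abs(result.fatal - fatal_mf) < 5 * max(np.sqrt(fatal_mf), 1.0)


class TestRunReplicates:
    def test_same_seed_identical_tables(self, small_params, profile):
        a = om.run_replicates(small_params, profile, 20, seed=5)
        b = om.run_replicates(small_params, profile, 20, seed=5)
        assert a.table.equals(b.table)

    def test_different_master_seeds_agree_within_error(self, small_params, profile):
        a = om.run_replicates(small_params, profile, 150, seed=101)
        b = om.run_replicates(small_params, profile, 150, seed=202)
        se = np.hypot(a.se("nonfatal"), b.se("nonfatal"))
        assert abs(a.mean("nonfatal") - b.mean("nonfatal")) < 3 * se

    def test_counterfactual_bounded_by_ops_overdoses(self, profile):
        params = om.ModelParameters(n_users_initial=20_000, ops_capacity=10, horizon_days=30)
        summary = om.run_replicates(params, profile, 5, seed=8)
        assert (summary.table["averted_tagged"] <= summary.table["ops_od"]).all()


class TestSaturation:
    def test_site_saturated_under_baseline_demand(self, baseline, profile):
        """Demand far exceeds 30 stations, so occupancy pins at capacity and
        expected averted fatalities follow the closed-form product."""
        params = baseline.replace(ops_capacity=30, horizon_days=30)
        summary = om.run_replicates(params, profile, 3, seed=13)
        assert summary.mean("mean_ops_occupancy") == pytest.approx(30.0)
        open_steps = params.open_steps_per_day * params.horizon_days
        expected = 30 * open_steps * params.p_fatal_use
        assert summary.mean("averted_expected") == pytest.approx(expected, rel=1e-12)
        assert summary.mean("ops_visits") == pytest.approx(30 * open_steps)


class TestNoFatalInsideSite:
    def test_all_overdoses_inside_are_reversed(self, single_ring_profile):
        params = om.ModelParameters(
            n_users_initial=400,
            ops_capacity=500,
            ops_hours_per_day=24.0,
            annual_fatal_od=0.9,
            annual_nonfatal_od=0.05,
            new_entrants_per_day=0.0,
            horizon_days=30,
        )
        summary = om.run_replicates(params, single_ring_profile, 4, seed=21)
        assert summary.mean("fatal") == 0.0
        assert summary.mean("ops_od") > 0
        assert summary.mean("nonfatal") == summary.mean("ops_od")


class TestStackedArms:
    def test_single_arm_matches_plain_run(self, small_params, profile):
        plain = om.run_replicates(small_params, profile, 10, seed=17)
        stacked = om.run_replicates_stacked([small_params], profile, 10, seed=17)[0]
        assert plain.table.equals(stacked.table)

    def test_rejects_non_stackable_differences(self, small_params, profile):
        arms = [small_params, small_params.replace(n_users_initial=999)]
        with pytest.raises(ValueError, match="non-stackable"):
            om.run_replicates_stacked(arms, profile, 2, seed=0)

    def test_entry_rate_arms_need_shared_seed_pool(self, small_params, profile):
        arms = [small_params, small_params.replace(annual_treatment_entry=0.25)]
        with pytest.raises(ValueError, match="initial_treatment_count"):
            om.run_replicates_stacked(arms, profile, 2, seed=0)


class TestMicrosim:
    def test_zero_rates_zero_events(self, profile):
        params = om.ModelParameters(
            n_users_initial=50,
            annual_fatal_od=0.0,
            annual_nonfatal_od=0.0,
            new_entrants_per_day=0.0,
            horizon_days=2,
        )
        result = om.simulate_year_microsim(params, profile, seed=0, n_agents=50)
        assert result.fatal == 0 and result.nonfatal == 0

    def test_certain_fatal_first_use(self, single_ring_profile):
        params = om.ModelParameters(
            n_users_initial=1,
            uses_per_day=48,  # uses every step
            annual_fatal_od=1.0,
            annual_nonfatal_od=0.0,
            annual_treatment_entry=0.0,
            annual_relapse=0.5,
            new_entrants_per_day=0.0,
            horizon_days=1,
            ops_capacity=0,
        )
        result = om.simulate_year_microsim(params, single_ring_profile, seed=0, n_agents=1)
        assert result.fatal == 1
        assert result.nonfatal == 0

    def test_same_seed_identical(self, profile):
        params = om.ModelParameters(n_users_initial=100, horizon_days=5)
        a = om.simulate_year_microsim(params, profile, seed=6, n_agents=100)
        b = om.simulate_year_microsim(params, profile, seed=6, n_agents=100)
        assert a.fatal == b.fatal and a.nonfatal == b.nonfatal and a.entrants == b.entrants
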