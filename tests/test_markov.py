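"""Cohort engine: transitions, accumulation, conservation, oracles."""

import numpy as np
import pytest

from thalcea import (
    AgeBandTable,
    HealthState,
    ModelConfig,
    btict_death_probability,
    build_cycle_transitions,
    microsimulate,
    run_cohort,
)

S = HealthState


@pytest.fixture(scope="module")
def band_table(registry):
    return AgeBandTable.from_parameter_set(registry.point_estimate())


class TestAgeBands:
    @pytest.mark.parametrize(
        "age,expected",
        [(0, 0.010), (1, 0.010), (3, 0.003), (10, 0.002), (11, 0.010),
         (20, 0.025), (30, 0.015), (31, 0.345), (40, 0.345), (95, 0.345)],
    )
    def test_lookup_inclusive_bounds(self, band_table, age, expected):
        assert btict_death_probability(age, band_table) == expected

    def test_negative_age_rejected(self, band_table):
        with pytest.raises(ValueError):
            band_table.probability(-1)

    def test_noncontiguous_bands_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            AgeBandTable(bands=((0, 1, 0.01), (3, 5, 0.02), (6, None, 0.1)))


class TestCycleTransitions:
    def test_bt_arm_first_cycle(self, point):
        rows = build_cycle_transitions("bt_ict", 1, ModelConfig(start_age=1), point)
        assert rows[S.BT_ICT][S.DEAD] == pytest.approx(0.010)
        assert rows[S.BT_ICT][S.BT_ICT] == pytest.approx(0.990)

    def test_related_first_cycle_death_then_failure(self, point):
        rows = build_cycle_transitions(
            "related_hsct", 1, ModelConfig(start_age=1), point
        )
        death = rows[S.HSCT_YEAR1][S.DEAD]
        fail = rows[S.HSCT_YEAR1][S.BT_ICT]
        assert death == pytest.approx(0.00902, abs=5e-5)
        assert fail == pytest.approx(0.01264 * (1 - death), rel=1e-3)

    def test_rows_sum_to_one(self, point):
        for arm in ("related_hsct", "unrelated_hsct", "bt_ict"):
            for cycle in (1, 2, 10, 60):
                rows = build_cycle_transitions(
                    arm, cycle, ModelConfig(start_age=5), point
                )
                for state, row in rows.items():
                    assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_hazards_give_pure_progression(self, point):
        quiet = point.replace(
            death_constant=-60.0, failure_constant=-60.0,
            failure_donor_type_coefficient=0.0,
            btict_death_age_0_1=0.0, btict_death_age_2_5=0.0,
        )
        cfg = ModelConfig(start_age=1, background_mortality="none")
        r1 = build_cycle_transitions("related_hsct", 1, cfg, quiet)
        r2 = build_cycle_transitions("related_hsct", 2, cfg, quiet)
        assert r1[S.HSCT_YEAR1][S.HSCT_YEAR2] == pytest.approx(1.0, abs=1e-12)
        assert r2[S.HSCT_YEAR2][S.POST_HSCT] == pytest.approx(1.0, abs=1e-12)

    def test_retransplant_routing(self, point):
        cfg = ModelConfig(start_age=1, max_transplants=2)
        rows = build_cycle_transitions("unrelated_hsct", 1, cfg, point)
        assert S.HSCT_YEAR1 in rows[S.HSCT_YEAR1]  # failure re-enters year 1
        assert rows[S.HSCT_YEAR1][S.HSCT_YEAR1] > 0.1  # unrelated failure risk


class TestRunCohort:
    def test_annuity_identity(self, point):
        """No mortality, utility one, no discounting: QALYs = horizon."""
        params = point.replace(
            death_constant=-60.0, failure_constant=-60.0,
            failure_donor_type_coefficient=0.0,
            utility_hsct_year12=1.0, utility_hsct_post=1.0,
            **{f"btict_death_age_{b}": 0.0
               for b in ("0_1", "2_5", "6_10", "11_15", "16_20", "21_30", "31_plus")},
        )
        cfg = ModelConfig(
            start_age=1, horizon=3, discount_costs=0.0, discount_outcomes=0.0,
            background_mortality="none",
        )
        res = run_cohort("related_hsct", cfg, params)
        assert res.lifetime_qaly == pytest.approx(3.0, abs=1e-12)

    def test_bt_arm_closed_form(self, point):
        """BT-ICT QALYs equal utility x sum of band survival products."""
        cfg = ModelConfig(
            start_age=1, horizon=60, discount_costs=0.0, discount_outcomes=0.0
        )
        res = run_cohort("bt_ict", cfg, point)
        table = AgeBandTable.from_parameter_set(point)
        alive, total = 1.0, 0.0
        for k in range(1, 61):
            total += alive  # cycle-start accrual
            alive *= 1.0 - table.probability(1 + k - 1)
        assert res.lifetime_qaly == pytest.approx(0.61 * total, abs=1e-10)

    def test_discounting_reduces_totals(self, point, base_config):
        res = run_cohort("related_hsct", base_config, point)
        assert res.lifetime_cost < res.lifetime_cost_undiscounted
        assert res.lifetime_qaly < res.lifetime_qaly_undiscounted
        cfg0 = base_config.replace(discount_costs=0.0, discount_outcomes=0.0)
        res0 = run_cohort("related_hsct", cfg0, point)
        assert res0.lifetime_cost == pytest.approx(res0.lifetime_cost_undiscounted)

    def test_null_delta_between_arms(self, point):
        """Equal transitions and payoffs make the arms indistinguishable.

        Shape one turns the Weibull death hazard into a constant per-cycle
        probability, set here (with all band rows) to 2%/year, with
        failure switched off and identical payoffs everywhere.
        """
        p_annual = 0.02
        lam = -np.log(1 - p_annual) / 365.0
        params = point.replace(
            death_constant=np.log(lam), death_age_coefficient=0.0,
            death_ancillary=0.0,
            failure_constant=-60.0, failure_donor_type_coefficient=0.0,
            cost_related_hsct_year1=35788.0, cost_related_hsct_year2=35788.0,
            cost_related_hsct_following=35788.0,
            cost_nonmedical_hsct_year12=2 * 37384.0,
            cost_productivity_hsct_year12=2 * 19171.0,
            utility_hsct_year12=0.61, utility_hsct_post=0.61,
            **{f"btict_death_age_{b}": p_annual
               for b in ("0_1", "2_5", "6_10", "11_15", "16_20", "21_30", "31_plus")},
        )
        cfg = ModelConfig(start_age=1, background_mortality="none")
        hsct = run_cohort("related_hsct", cfg, params)
        bt = run_cohort("bt_ict", cfg, params)
        assert hsct.lifetime_cost == pytest.approx(bt.lifetime_cost, rel=1e-12)
        assert hsct.lifetime_qaly == pytest.approx(bt.lifetime_qaly, rel=1e-12)

    def test_payoff_monotonicity(self, point, base_config):
        base = run_cohort("related_hsct", base_config, point)
        up_util = run_cohort(
            "related_hsct", base_config, point.replace(utility_btict=0.70)
        )
        up_cost = run_cohort(
            "related_hsct", base_config,
            point.replace(cost_related_hsct_following=50000.0),
        )
        assert up_util.lifetime_qaly >= base.lifetime_qaly
        assert up_cost.lifetime_cost >= base.lifetime_cost

    def test_hsct_qalys_decline_with_starting_age(self, point):
        qalys = [
            run_cohort(
                "related_hsct", ModelConfig(start_age=age), point,
                collect_trace=False,
            ).lifetime_qaly
            for age in range(1, 29)
        ]
        assert np.all(np.diff(qalys) < 0)

    @pytest.mark.parametrize("max_transplants", [1, 2])
    def test_occupancy_conserved_each_cycle(self, point, max_transplants):
        cfg = ModelConfig(start_age=5, max_transplants=max_transplants)
        res = run_cohort("unrelated_hsct", cfg, point)
        sums = res.trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-10)
        assert np.all(res.trace.occupancy >= -1e-15)

    def test_trace_roundtrip_csv(self, point, base_config, tmp_path):
        res = run_cohort("related_hsct", base_config, point)
        frame = res.trace.to_frame()
        path = tmp_path / "trace.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        assert len(back) == base_config.horizon
        assert back["cost_discounted"].sum() == pytest.approx(res.lifetime_cost)


class TestMicrosimulationOracle:
    @pytest.mark.parametrize("arm", ["related_hsct", "bt_ict"])
    def test_cohort_matches_individual_simulation(self, point, arm):
        cfg = ModelConfig(start_age=1)
        coh = run_cohort(arm, cfg, point, collect_trace=False)
        micro = microsimulate(arm, cfg, point, n_individuals=150_000, seed=13)
        assert abs(coh.lifetime_cost - micro["cost"]) < 3 * micro["cost_se"]
        assert abs(coh.lifetime_qaly - micro["qaly"]) < 3 * micro["qaly_se"]


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [dict(start_age=0), dict(start_age=29), dict(horizon=0),
         dict(discount_costs=0.07), dict(perspective="martian"),
         dict(max_transplants=3), dict(background_mortality="sometimes")],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelConfig(**kw)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("start_age: 10\ndiscount_costs: 0.0\nperspective: governmental\n")
        cfg = ModelConfig.from_yaml(path)
        assert cfg.start_age == 10
        assert cfg.discount_costs == 0.0
        assert cfg.perspective == "governmental"
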