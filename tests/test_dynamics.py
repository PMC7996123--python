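"""Per-period building blocks: needs, allocation, mixing, conflict, migration."""

import numpy as np
import pytest

from climmigsim import (
    ControllerSet,
    FunctionBank,
    GroupState,
    RandomStream,
    ScenarioSet,
    build_storyline,
    run,
)
from climmigsim.dynamics import (
    allocate_capacity,
    conflict_step,
    effective_service,
    migration_step,
    mixing_adjustment,
    need_for_provision,
)


class TestNeedForProvision:
    @pytest.mark.parametrize(
        "stock, threshold, barrier, pop, expected",
        [
            (49.0, 48.0, 0.0, 2002.0, 2002.0),   # one excess unit per person
            (48.0, 48.0, 0.0, 1000.0, 0.0),      # at the threshold: no need
            (50.0, 48.0, 0.25, 100.0, 150.0),    # barrier blocks a quarter
            (40.0, 48.0, 0.0, 1000.0, 0.0),      # below the threshold
        ],
    )
    def test_population_scaled(self, stock, threshold, barrier, pop, expected):
        assert need_for_provision(stock, threshold, barrier, pop) == pytest.approx(expected)

    def test_population_free_form(self):
        assert need_for_provision(50.0, 48.0, 0.5, per_population=False) == pytest.approx(1.0)

    def test_bad_barrier_rejected(self):
        with pytest.raises(ValueError):
            need_for_provision(50.0, 48.0, 1.5, 10.0)


class TestAllocateCapacity:
    def test_sufficient_capacity_serves_needs(self):
        assert allocate_capacity((100.0, 300.0), 500.0, 1) == (100.0, 300.0)

    def test_shortage_mode1_proportional(self):
        assert allocate_capacity((100.0, 300.0), 200.0, 1) == pytest.approx((50.0, 150.0))

    def test_shortage_mode2_fixed_shares(self):
        got = allocate_capacity((100.0, 300.0), 200.0, 2, shares=(0.3, 0.7))
        assert got == pytest.approx((60.0, 140.0))

    def test_mode2_excess_capped_at_need(self):
        got = allocate_capacity((10.0, 300.0), 200.0, 2, shares=(0.5, 0.5))
        assert got[0] == 10.0  # provision never over-serves a group's need

    def test_mode2_without_shares_rejected(self):
        with pytest.raises(ValueError):
            allocate_capacity((1.0, 1.0), 1.0, 2)

    def test_mode1_conserves_capacity_under_shortage(self):
        needs = (123.4, 567.8)
        got = allocate_capacity(needs, 300.0, 1)
        assert sum(got) == pytest.approx(min(sum(needs), 300.0))


class TestMixingAdjustment:
    def test_arrival_of_sicker_movers_raises_pool(self):
        # 100 arrivals at HP 55 joining 100 residents at HP 49: +3 per capita
        got = mixing_adjustment(100.0, 100.0, 49.0, 55.0, "arrival")
        assert got == pytest.approx(3.0)

    def test_equal_health_is_neutral(self):
        assert mixing_adjustment(50.0, 200.0, 48.0, 48.0, "arrival") == 0.0
        assert mixing_adjustment(50.0, 200.0, 48.0, 48.0, "departure") == 0.0

    def test_departure_of_sicker_movers_lowers_origin(self):
        # healthier movers leave: the pool's per-capita problems rise
        got = mixing_adjustment(100.0, 1000.0, 50.0, 40.0, "departure")
        assert got == pytest.approx(100.0 / 900.0 * 10.0)

    def test_departure_capped_and_zero_pool(self):
        assert mixing_adjustment(10.0, 10.0, 50.0, 40.0, "departure") == 0.0
        assert mixing_adjustment(0.0, 0.0, 0.0, 0.0, "arrival") == 0.0

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            mixing_adjustment(1.0, 1.0, 1.0, 1.0, "sideways")


class TestEffectiveService:
    def test_no_damage_passthrough(self):
        q, c = effective_service(1.0, 4200.0, 0.0, 0.0,
                                 (lambda x: 0.0, lambda x: 0.0),
                                 (lambda x: 0.0, lambda x: 0.0))
        assert (q, c) == (1.0, 4200.0)

    def test_linear_damage_subtracts(self):
        q, _ = effective_service(0.75, 0.0, 1.0, 0.0,
                                 (lambda x: 0.1 * x, lambda x: 0.0),
                                 (lambda x: 0.0, lambda x: 0.0))
        assert q == pytest.approx(0.65)

    def test_damage_floors(self):
        q, c = effective_service(0.5, 100.0, 1.0, 0.0,
                                 (lambda x: 2.0, lambda x: 0.0),
                                 (lambda x: 500.0, lambda x: 0.0))
        assert (q, c) == (0.0, 0.0)


class TestConflictStep:
    def test_override_skips_draw(self):
        stream = RandomStream(0)
        out = conflict_step(0.9, 5.0, override=0.0, stream=stream, substream="origin_conflict")
        assert out.intensity == 0.0
        assert out.drawn_threshold is None

    def test_risk_clamped_to_unit_interval(self):
        out = conflict_step(2.0, 1.0, override=0.0,
                            stream=RandomStream(0), substream="origin_conflict")
        assert out.risk == 1.0

    def test_zero_risk_never_ignites(self):
        stream = RandomStream(0)
        for _ in range(20):
            out = conflict_step(0.0, 7.0, None, stream, "destination_conflict")
            assert out.intensity == 0.0

    def test_certain_risk_always_ignites(self):
        stream = RandomStream(0)
        for _ in range(20):
            out = conflict_step(1.5, 7.0, None, stream, "destination_conflict")
            assert out.intensity == 7.0
            assert 0.0 <= out.drawn_threshold <= 1.0


class TestMigrationStep:
    def _setup(self, endtime=5):
        scen = ScenarioSet.constant(endtime, od_nmhppc_x=0.9)
        fb = FunctionBank.zeroed()
        ctrl = ControllerSet({})
        origin = GroupState(pop_s=1000.0, hppc_s=40.0, ep_s=0.0)
        di = GroupState(pop_s=100.0, hppc_s=48.0, ep_s=0.0)
        dn = GroupState(pop_s=2000.0, hppc_s=48.0, ep_s=0.0)
        return origin, di, dn, scen, fb, ctrl

    def test_selection_ratio_scales_arrival_health(self):
        origin, di, dn, scen, fb, ctrl = self._setup()
        out = migration_step(origin, di, dn, 0.0, 0.0, scen, 0, fb, ctrl)
        assert out.od_imhppc_a == pytest.approx(36.0)  # 40 * 0.9

    def test_all_zero_drivers_give_no_movers(self):
        origin, di, dn, scen, fb, ctrl = self._setup()
        out = migration_step(origin, di, dn, 0.0, 0.0, scen, 0, fb, ctrl)
        assert out.od_nm_a == 0.0

    def test_movers_capped_at_origin_population(self):
        origin, di, dn, scen, fb, ctrl = self._setup()
        scen.series["od_nm_tx"][:] = 5000.0  # exogenous push beyond the population
        out = migration_step(origin, di, dn, 0.0, 0.0, scen, 0, fb, ctrl)
        assert out.od_nm_a == origin.pop_s

    def test_negative_sum_floored_at_zero(self):
        origin, di, dn, scen, fb, ctrl = self._setup()
        scen.series["od_nm_tx"][:] = -50.0
        out = migration_step(origin, di, dn, 0.0, 0.0, scen, 0, fb, ctrl)
        assert out.od_nm_a == 0.0


class TestShortagePolicyAlgebra:
    def test_barrier_beats_equal_quality_discount_under_shortage(self):
        """Under shortage, [b=0, q=0.75] hands immigrants a smaller capacity
        share than [b=0.25, q=1], and their health is worse throughout."""
        barrier_run = run(build_storyline("S3", barrier=0.25))     # q(1-b) = 0.75
        quality_run = run(build_storyline("S4", quality=0.75))     # q(1-b) = 0.75
        m_q = quality_run.series("di_tnhcfp_a")   # b=0: full need m
        n_q = quality_run.series("dn_tnhcfp_a")
        shortage = quality_run.series("d_tnhcfp_a") > quality_run.series("d_hcc_a")
        mask = shortage & (m_q > 0) & (n_q > 0)
        assert mask.any()
        # share algebra on the period values: 0.75m/(m+n) < 0.75m/(0.75m+n)
        lhs = 0.75 * m_q[mask] / (m_q[mask] + n_q[mask])
        rhs = 0.75 * m_q[mask] / (0.75 * m_q[mask] + n_q[mask])
        assert np.all(lhs < rhs)
        # in the full runs the quality-discount policy's immigrant HP pc
        # climbs sooner and peaks higher
        di_q = quality_run.series("di_hppc_s")
        di_b = barrier_run.series("di_hppc_s")
        assert di_q.max() > di_b.max()
        assert np.argmax(di_q) <= np.argmax(di_b)

    def test_barrier_monotonicity_under_ample_capacity(self):
        """With capacity never binding, a higher immigrant barrier weakly
        raises the immigrant health-problem stock at every period."""
        prev = None
        for b in (0.0, 0.25, 0.5):
            sl = build_storyline("policy", barrier=b, quality=1.0, hc_capacity=1e9)
            di = run(sl).series("di_hppc_s")
            if prev is not None:
                assert np.all(di >= prev - 1e-9)
            prev = di
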