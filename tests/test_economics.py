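"""Economic accrual, ICUR arithmetic, and frontier/dominance logic."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from masld_cea.cascade import CohortSlice
from masld_cea.economics import (EconResult, accrue, discount_factor,
                                 discount_weights, frontier, icur, nmb)
from masld_cea.markov import Trajectory, run_horizon
from masld_cea.params import ParameterSet, with_override


class TestDiscounting:
    @pytest.mark.parametrize("rate, t, expected", [
        (0.03, 0, 1.0),
        (0.0, 7, 1.0),
        (0.03, 1, 1 / 1.03),
        (0.03, 10, 1.03 ** -10),
    ])
    def test_closed_form(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_rate_and_fractional_cycle(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)
        with pytest.raises(ValueError):
            discount_factor(0.03, 1.5)

    def test_weights_cover_cycles_one_to_horizon(self):
        w = discount_weights(0.03, 10)
        assert len(w) == 10
        assert w[0] == pytest.approx(1 / 1.03)


def _unit_slice(params, **kw):
    defaults = dict(arm="x", fraction=1.0, diseased=True, regime="natural",
                    program=False, state0=params.initial_stage_distribution,
                    sex="boys", age=10)
    defaults.update(kw)
    return CohortSlice(**defaults)


class TestAccrue:
    def test_unit_utility_cohort_counts_person_years(self, params):
        # u == 1 in every stage, r = 0: QALYs are exactly count * years
        ps = params
        for stage in ("f0", "f1_f2", "f3", "f4"):
            ps = with_override(ps, f"utilities.{stage}", 1.0)
        ps = with_override(ps, "discount_rate", 0.0)
        ps = with_override(ps, "cohort_size", 100)
        sl = _unit_slice(ps)
        traj = run_horizon(sl, ps)
        res = accrue([(sl, traj)], 0.0, ps, "S4")
        assert res.total_qaly == pytest.approx(1000.0, abs=1e-9)
        assert res.total_cost == 0.0

    def test_two_cycle_hand_calculation_of_treatment_gain(self, params):
        # single diseased slice, horizon 2: incremental QALYs equal the
        # utility-weighted occupancy gap between regimes, chained by hand
        ps = with_override(params, "horizon_years", 2)
        ps = with_override(ps, "cohort_size", 1)
        u = ps.utilities.point_vector()
        d1, d2 = 1 / 1.03, 1.03 ** -2
        from masld_cea.markov import build_transition_matrix

        s0 = np.asarray(ps.initial_stage_distribution)
        results = {}
        for regime in ("natural", "intervention"):
            m = build_transition_matrix("boys", regime, 10, ps.transitions)
            s1 = s0 @ m
            s2 = s1 @ m
            results[regime] = (s1 @ u) * d1 + (s2 @ u) * d2
        sl_nat = _unit_slice(ps)
        sl_trt = _unit_slice(ps, regime="intervention")
        got_nat = accrue([(sl_nat, run_horizon(sl_nat, ps))], 0.0, ps).total_qaly
        got_trt = accrue([(sl_trt, run_horizon(sl_trt, ps))], 0.0, ps).total_qaly
        assert got_nat == pytest.approx(results["natural"], abs=1e-12)
        assert got_trt == pytest.approx(results["intervention"], abs=1e-12)
        assert got_trt - got_nat == pytest.approx(
            results["intervention"] - results["natural"], abs=1e-12)
        assert got_trt > got_nat

    def test_program_costs_discounted_over_duration(self, params):
        ps = with_override(params, "cohort_size", 1000)
        sl = _unit_slice(ps, program=True)
        traj = run_horizon(sl, ps)
        res = accrue([(sl, traj)], 5.0, ps)
        annuity = discount_weights(0.03, 10).sum()
        expected = 1000 * (5.0 + 32.2 * annuity)
        assert res.total_cost == pytest.approx(expected)

    def test_program_duration_knob_shortens_cost_stream(self, params):
        short = with_override(params, "program_duration_years", 1)
        sl = _unit_slice(short, program=True)
        res = accrue([(sl, run_horizon(sl, short))], 0.0, short)
        assert res.total_cost == pytest.approx(
            short.cohort_size * 32.2 / 1.03)

    def test_horizon_mismatch_rejected(self, params):
        sl = _unit_slice(params)
        bad = Trajectory(states=np.tile(sl.state0, (3, 1)))
        with pytest.raises(ValueError, match="horizon"):
            accrue([(sl, bad)], 0.0, params)

    def test_discount_monotonicity(self, params):
        sl = _unit_slice(params, program=True)
        totals = []
        for r in (0.0, 0.03, 0.05):
            ps = with_override(params, "discount_rate", r)
            res = accrue([(sl, run_horizon(sl, ps))], 1.0, ps)
            totals.append(res)
        assert totals[0].total_qaly >= totals[1].total_qaly >= totals[2].total_qaly
        assert totals[0].total_cost >= totals[1].total_cost >= totals[2].total_cost


class TestIcur:
    def test_reported_pairwise_ratios_follow_from_increments(self):
        # printed increments reproduce the printed ratios exactly
        s1 = EconResult("S1", 0.0, 0.0)
        s2 = EconResult("S2", 220_000.0, 42.6)
        r = icur(s2, s1)
        assert round(r.value, 1) == 5164.3
        s3 = EconResult("S3", s2.total_cost + 2_260_000.0, s2.total_qaly + 48.9)
        assert round(icur(s3, s2).value, 1) == 46216.8

    def test_equal_qalys_flagged_undefined_not_crash(self):
        a, b = EconResult("A", 10.0, 1.0), EconResult("B", 20.0, 1.0)
        r = icur(b, a)
        assert r.label == "undefined"
        assert math.isnan(r.value)

    def test_quadrant_flags(self):
        ref = EconResult("ref", 100.0, 10.0)
        assert icur(EconResult("a", 50.0, 12.0), ref).label == "dominant"
        assert icur(EconResult("b", 150.0, 8.0), ref).label == "dominated"
        assert icur(EconResult("c", 150.0, 12.0), ref).label == "icur"

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6),
           st.floats(-100, 100), st.floats(-100, 100))
    def test_antisymmetry_is_exact(self, ca, cb, qa, qb):
        a, b = EconResult("A", ca, qa), EconResult("B", cb, qb)
        ra, rb = icur(a, b), icur(b, a)
        if math.isnan(ra.value):
            assert math.isnan(rb.value)
        else:
            assert ra.value == rb.value  # (-x)/(-y) is exact in IEEE


class TestFrontier:
    def _mk(self, pts):
        return [EconResult(f"T{i}", c, q) for i, (c, q) in enumerate(pts)]

    def test_strict_dominance_picks_cheaper_of_equals(self):
        res = self._mk([(10.0, 2.0), (30.0, 2.0)])
        dec = frontier(res, wtp=100.0)
        assert dec.optimal == "T0"
        assert dec.strictly_dominated == {"T1"}

    def test_three_point_frontier_at_low_and_high_wtp(self):
        res = self._mk([(0.0, 0.0), (10.0, 2.0), (30.0, 3.0)])
        low = frontier(res, wtp=5.0)
        assert low.frontier_icurs["T1"] == pytest.approx(5.0)
        assert low.frontier_icurs["T2"] == pytest.approx(20.0)
        assert low.optimal == "T1"  # ICUR 5 <= wtp 5, next step is 20
        high = frontier(res, wtp=25.0)
        assert high.optimal == "T2"

    def test_extended_dominance_removed_from_frontier(self):
        # middle option has a higher incremental ratio than its successor
        res = self._mk([(0.0, 0.0), (10.0, 1.0), (12.0, 3.0)])
        dec = frontier(res, wtp=6.0)
        assert dec.extended_dominated == {"T1"}
        assert dec.frontier == ("T0", "T2")
        assert dec.optimal == "T2"  # 12/3 = 4 <= 6

    def test_optimal_never_dominated(self, params):
        res = self._mk([(0.0, 0.0), (5.0, 0.5), (10.0, 2.0), (30.0, 3.0)])
        for wtp in (1.0, 5.0, 10.0, 50.0):
            dec = frontier(res, wtp)
            assert dec.optimal not in dec.dominated

    @given(st.lists(st.tuples(st.floats(0, 1e6), st.floats(0, 1e3)),
                    min_size=2, max_size=6),
           st.floats(0.0, 1e5))
    def test_frontier_agrees_with_nmb_maximization(self, pts, wtp):
        res = self._mk(pts)
        dec = frontier(res, wtp)  # raises internally on disagreement
        best = max(nmb(r, wtp) for r in res)
        chosen = next(r for r in res if r.strategy_id == dec.optimal)
        assert nmb(chosen, wtp) == pytest.approx(best, rel=1e-9, abs=1e-6)
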