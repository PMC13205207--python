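"""Decision-tree screening cascade: arm arithmetic and conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from masld_cea.cascade import (STRATEGIES, CascadeResult, assign_management,
                               classify_second_stage, run_cascade)
from masld_cea.params import ConfigError, with_override


class TestClassifySecondStage:
    @pytest.mark.parametrize(
        "pi, se, sp, expected",
        [
            (0.3, 1.0, 1.0, (0.3, 0.0, 0.0, 0.7)),        # perfect test
            (0.3, 0.72, 0.98, (0.216, 0.084, 0.014, 0.686)),
            (0.0, 0.95, 0.92, (0.0, 0.0, 0.08, 0.92)),     # disease-free
        ],
    )
    def test_worked_examples(self, pi, se, sp, expected):
        got = classify_second_stage(pi, se, sp)
        assert got == pytest.approx(expected, abs=1e-12)

    @given(pi=st.floats(0, 1), se=st.floats(0, 1), sp=st.floats(0, 1))
    def test_partition_of_tested(self, pi, se, sp):
        tp, fn, fp, tn = classify_second_stage(pi, se, sp)
        assert min(tp, fn, fp, tn) >= 0
        assert tp + fn + fp + tn == pytest.approx(1.0, abs=1e-9)
        assert tp + fn == pytest.approx(pi, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_second_stage(1.2, 0.5, 0.5)


class TestRunCascade:
    def test_no_screening_has_zero_cost_and_untested_disease(self, params):
        cas = run_cascade(STRATEGIES["S4"], params, age=10)
        assert cas.tp == cas.fp == cas.tn == cas.fn == 0.0
        assert cas.one_off_cost_per_child == 0.0
        assert cas.whtr_neg_diseased == params.prevalence(10)
        assert cas.responder_fraction == 0.0

    def test_conditional_prevalence_chains_through_both_stages(self, params):
        # pi = 0.08 at stage 1 concentrates to 0.08/0.226 among positives
        ps = with_override(params, "prevalence_by_age.10", 0.08)
        cas = run_cascade(STRATEGIES["S2"], ps, age=10)
        pi_cond = 0.08 / 0.226
        tp_c, fn_c, fp_c, tn_c = classify_second_stage(pi_cond, 0.72, 0.98)
        assert pi_cond == pytest.approx(0.3540, abs=5e-5)
        assert cas.tp == pytest.approx(0.226 * tp_c)
        assert cas.fn == pytest.approx(0.226 * fn_c)
        assert cas.fp == pytest.approx(0.226 * fp_c)
        assert cas.tn == pytest.approx(0.226 * tn_c)
        assert cas.whtr_neg_diseased == 0.0  # stage-1 sensitivity 1.0

    def test_perfect_cascade_recovers_all_prevalence(self, params):
        ps = with_override(params, "tests.ultrasound.sensitivity", 1.0)
        ps = with_override(ps, "tests.ultrasound.specificity", 1.0)
        cas = run_cascade(STRATEGIES["S1"], ps, age=12)
        assert cas.fn == pytest.approx(0.0, abs=1e-15)
        assert cas.fp == pytest.approx(0.0, abs=1e-15)
        assert cas.tp == pytest.approx(ps.prevalence(12))

    def test_one_off_cost_charges_whtr_positives_for_stage_two(self, params):
        cas = run_cascade(STRATEGIES["S3"], params, age=8)
        expected = 2.9 + 0.226 * (87.0 + 22.5)
        assert cas.one_off_cost_per_child == pytest.approx(expected)

    def test_blood_panel_restricted_to_test_positives_option(self, params):
        ps = with_override(params, "blood_panel_all_whtr_positive", False)
        cas_all = run_cascade(STRATEGIES["S2"], params, age=8)
        cas_pos = run_cascade(STRATEGIES["S2"], ps, age=8)
        assert cas_pos.one_off_cost_per_child < cas_all.one_off_cost_per_child

    def test_incompatible_stage1_sensitivity_is_a_config_error(self, params):
        ps = with_override(params, "prevalence_by_age.10", 0.40)
        with pytest.raises(ConfigError, match="conditional prevalence"):
            run_cascade(STRATEGIES["S2"], ps, age=10)

    @pytest.mark.parametrize("sid", ["S1", "S2", "S3", "S4"])
    @pytest.mark.parametrize("age", [6, 10, 14])
    def test_arm_fractions_partition_cohort(self, params, sid, age):
        cas = run_cascade(STRATEGIES[sid], params, age)
        assert cas.arm_fractions().sum() == pytest.approx(1.0, abs=1e-12)
        assert cas.tp + cas.fn + cas.whtr_neg_diseased == pytest.approx(
            cas.prevalence, abs=1e-12)

    @given(se=st.floats(0.1, 1.0), rho=st.floats(0.0, 1.0),
           pi=st.floats(0.0, 0.2))
    def test_responders_monotone_in_se_response_and_prevalence(
            self, params, se, rho, pi):
        ps = with_override(params, "tests.fibroscan.sensitivity", se)
        ps = with_override(ps, "transitions.response_rate", rho)
        ps = with_override(ps, "prevalence_by_age.10", pi)
        cas = run_cascade(STRATEGIES["S2"], ps, age=10)
        lower = run_cascade(
            STRATEGIES["S2"],
            with_override(ps, "tests.fibroscan.sensitivity", se * 0.5), 10)
        assert cas.responder_fraction >= lower.responder_fraction - 1e-15

    @given(sp=st.floats(0.0, 1.0))
    def test_false_positives_decrease_with_specificity(self, params, sp):
        ps_lo = with_override(params, "tests.mri_pdff.specificity", sp)
        ps_hi = with_override(params, "tests.mri_pdff.specificity",
                              sp + (1 - sp) / 2)
        fp_lo = run_cascade(STRATEGIES["S3"], ps_lo, 10).fp
        fp_hi = run_cascade(STRATEGIES["S3"], ps_hi, 10).fp
        assert fp_hi <= fp_lo + 1e-15


class TestAssignManagement:
    def test_zero_response_rate_leaves_no_responder_slice(self, params):
        cas = run_cascade(STRATEGIES["S2"], params, age=10)
        slices = assign_management(cas, 0.0, params.initial_stage_distribution)
        assert "tp_responder" not in {s.arm for s in slices}
        assert all(s.regime != "intervention" for s in slices)

    def test_full_response_routes_all_tp_to_intervention(self, params):
        cas = run_cascade(STRATEGIES["S2"], params, age=10)
        slices = assign_management(cas, 1.0, params.initial_stage_distribution)
        by_arm = {s.arm: s for s in slices}
        assert by_arm["tp_responder"].fraction == pytest.approx(cas.tp)
        assert "tp_nonresponder" not in by_arm

    def test_responder_slice_is_tp_times_rho(self, params):
        cas = CascadeResult(strategy_id="S2", age=10, prevalence=0.35,
                            tp=0.25, fp=0.05, tn=0.30, fn=0.05,
                            whtr_neg_diseased=0.05, whtr_neg_healthy=0.30,
                            responder_fraction=0.10,
                            one_off_cost_per_child=10.0)
        slices = assign_management(cas, 0.4, params.initial_stage_distribution)
        by_arm = {s.arm: s for s in slices}
        assert by_arm["tp_responder"].fraction == pytest.approx(0.10)

    @pytest.mark.parametrize("sid", ["S1", "S2", "S3", "S4"])
    def test_slice_fractions_conserve_cohort(self, params, sid):
        for age in (6, 9, 14):
            cas = run_cascade(STRATEGIES[sid], params, age)
            slices = assign_management(cas, 0.4,
                                       params.initial_stage_distribution)
            assert sum(s.fraction for s in slices) == pytest.approx(1.0,
                                                                    abs=1e-12)

    def test_diseased_slices_seed_at_initial_distribution(self, params):
        cas = run_cascade(STRATEGIES["S1"], params, age=10)
        for s in assign_management(cas, 0.4, params.initial_stage_distribution):
            if s.diseased:
                assert s.state0 == params.initial_stage_distribution
            else:
                assert s.state0 == (1.0, 0.0, 0.0, 0.0, 0.0)
                assert s.regime is None

    def test_program_membership_is_second_stage_positives_only(self, params):
        cas = run_cascade(STRATEGIES["S2"], params, age=10)
        slices = assign_management(cas, 0.4, params.initial_stage_distribution)
        program_arms = {s.arm for s in slices if s.program}
        assert program_arms == {"tp_responder", "tp_nonresponder", "fp"}
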