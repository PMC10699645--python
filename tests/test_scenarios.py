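"""Stress/relief/treatment scenarios, subjects, and endocrine tests."""

import numpy as np
import pytest

from hpatoggle import (ConfigError, DomainError, crh_test,
                       critical_stress_duration, dex_crh_test, make_subject,
                       run_relief_scenario, run_stress_scenario,
                       run_treatment_scenario)


class TestStressScenarios:
    def test_brief_stress_recovers(self, nominal):
        _, outcome = run_stress_scenario(1.0, 2.0, 5.0, 3.0, 120.0, nominal)
        assert outcome == "euthymic"

    def test_prolonged_stress_locks_in_depression(self, nominal):
        traj, outcome = run_stress_scenario(1.0, 2.0, 5.0, 60.0, 160.0,
                                            nominal)
        assert outcome == "depressed"
        # the state persists long after stress has returned to baseline
        assert traj.iloc[-1]["u"] == 1.0
        assert traj.iloc[-1]["A"] > 1.5

    def test_outcome_monotone_in_duration(self, nominal):
        outcomes = [run_stress_scenario(1.0, 2.0, 0.0, d, d + 120.0, nominal,
                                        mode="reduced")[1]
                    for d in (2.0, 15.0, 40.0, 80.0)]
        flips = sum(a != b for a, b in zip(outcomes, outcomes[1:]))
        assert outcomes[0] == "euthymic"
        assert outcomes[-1] == "depressed"
        assert flips == 1

    def test_critical_duration_set_by_slow_turnover(self, nominal):
        """The weeks-scale onset time is set by the slow turnover rates:
        rescaling them all rescales the critical stress duration inversely,
        and slowing the adrenal turnover alone lengthens it."""
        base = critical_stress_duration(1.0, 2.0, nominal, tol=0.25)
        for fold in (0.5, 2.0):
            slow_scaled = nominal.replace(
                aA=nominal.aA * fold, bA=nominal.bA * fold,
                aP=nominal.aP * fold, bP=nominal.bP * fold,
                ah=nominal.ah * fold, bh=nominal.bh * fold)
            scaled = critical_stress_duration(1.0, 2.0, slow_scaled,
                                              tol=0.25, hi=300.0)
            assert scaled == pytest.approx(base / fold, rel=0.05)
        adrenal_slow = nominal.replace(aA=nominal.aA / 2, bA=nominal.bA / 2)
        adrenal_fast = nominal.replace(aA=nominal.aA * 2, bA=nominal.bA * 2)
        assert critical_stress_duration(1.0, 2.0, adrenal_slow, tol=0.25,
                                        hi=300.0) > base
        assert critical_stress_duration(1.0, 2.0, adrenal_fast,
                                        tol=0.25) < base


class TestReliefScenarios:
    def test_brief_relief_fails(self, nominal):
        _, outcome = run_relief_scenario(1.0, 0.5, 3.0, 120.0, nominal)
        assert outcome == "depressed"

    def test_prolonged_relief_recovers(self, nominal):
        _, outcome = run_relief_scenario(1.0, 0.5, 60.0, 160.0, nominal)
        assert outcome == "euthymic"

    def test_relief_above_lower_threshold_never_works(self, nominal):
        # u_relief = 0.8 > u2 = 0.75: the depressed point persists
        _, outcome = run_relief_scenario(1.0, 0.8, 120.0, 200.0, nominal)
        assert outcome == "depressed"


class TestTreatmentScenarios:
    def test_brief_treatment_fails(self, nominal):
        _, outcome = run_treatment_scenario(2.0, 5.0, 120.0, nominal)
        assert outcome == "depressed"

    def test_prolonged_treatment_recovers(self, nominal):
        _, outcome = run_treatment_scenario(2.0, 60.0, 160.0, nominal)
        assert outcome == "euthymic"

    def test_no_treatment_stays_depressed(self, nominal):
        _, outcome = run_treatment_scenario(1.0, 60.0, 160.0, nominal)
        assert outcome == "depressed"

    def test_scenarios_are_deterministic(self, nominal):
        t1, o1 = run_treatment_scenario(2.0, 30.0, 80.0, nominal)
        t2, o2 = run_treatment_scenario(2.0, 30.0, 80.0, nominal)
        assert o1 == o2
        assert np.array_equal(t1.to_numpy(), t2.to_numpy())


class TestSubjects:
    def test_control_sits_at_normalized_baseline(self, nominal):
        subject = make_subject("control", 1.0, nominal)
        assert subject.state.x3 == pytest.approx(1.0, abs=1e-9)
        assert subject.state.A == pytest.approx(1.0, abs=1e-9)
        assert subject.state.P == pytest.approx(1.0, abs=0.02)

    def test_mdd_glands_enlarged_adrenal_more_than_pituitary(self, nominal):
        control = make_subject("control", 1.0, nominal)
        mdd = make_subject("MDD", 1.0, nominal)
        a_ratio = mdd.state.A / control.state.A
        p_ratio = mdd.state.P / control.state.P
        assert a_ratio > p_ratio > 1.0
        assert mdd.state.x3 > nominal.T

    def test_mdd_subject_impossible_in_resilient_regime(self, nominal):
        with pytest.raises(DomainError):
            make_subject("MDD", 0.4, nominal)

    def test_unknown_label_rejected(self, nominal):
        with pytest.raises(ConfigError):
            make_subject("patient", 1.0, nominal)


class TestCrhTest:
    def test_zero_dose_is_flat(self, nominal):
        subject = make_subject("control", 1.0, nominal)
        result = crh_test(subject, 0.0, nominal, window=120.0)
        assert result.series["acth"].max() - result.series["acth"].min() \
            < 1e-6

    def test_negative_dose_rejected(self, nominal):
        subject = make_subject("control", 1.0, nominal)
        with pytest.raises(DomainError):
            crh_test(subject, -1.0, nominal)

    def test_mdd_response_is_blunted(self, nominal):
        control = make_subject("control", 1.0, nominal)
        mdd = make_subject("MDD", 1.0, nominal)
        peak_c = crh_test(control, 5.0, nominal).peak_acth
        peak_m = crh_test(mdd, 5.0, nominal).peak_acth
        assert peak_m < peak_c

    def test_weaker_pituitary_gr_reduces_blunting(self, nominal):
        def blunting(params):
            control = make_subject("control", 1.0, params)
            mdd = make_subject("MDD", 1.0, params)
            return (crh_test(control, 5.0, params).peak_acth
                    / crh_test(mdd, 5.0, params).peak_acth)

        weaker = nominal.replace(KGR=2 * nominal.KGR)
        assert blunting(weaker) < blunting(nominal)

    def test_square_pulse_mode_also_blunted(self, nominal):
        control = make_subject("control", 1.0, nominal)
        mdd = make_subject("MDD", 1.0, nominal)
        peak_c = crh_test(control, 5.0, nominal, pulse_mode="square").peak_acth
        peak_m = crh_test(mdd, 5.0, nominal, pulse_mode="square").peak_acth
        assert peak_m < peak_c


class TestDexCrhTest:
    def test_mdd_response_is_elevated(self, nominal):
        control = make_subject("control", 1.0, nominal)
        mdd = make_subject("MDD", 1.0, nominal)
        dex = 3.0 * nominal.KGR
        peak_c = dex_crh_test(control, dex, 5.0, nominal).peak_acth
        peak_m = dex_crh_test(mdd, dex, 5.0, nominal).peak_acth
        assert peak_m > peak_c

    def test_dex_suppresses_pre_crh_acth(self, nominal):
        dex = 10.0 * nominal.KGR
        for label in ("control", "MDD"):
            subject = make_subject(label, 1.0, nominal)
            result = dex_crh_test(subject, dex, 5.0, nominal)
            assert result.baseline_acth < 0.1  # far below baseline 1

    def test_peak_ratio_approaches_pituitary_mass_ratio(self, nominal):
        """Under near-total GR suppression the ACTH readout is proportional
        to pituitary secretion capacity."""
        control = make_subject("control", 1.0, nominal)
        mdd = make_subject("MDD", 1.0, nominal)
        dex = 10.0 * nominal.KGR
        ratio = (dex_crh_test(mdd, dex, 5.0, nominal).peak_acth
                 / dex_crh_test(control, dex, 5.0, nominal).peak_acth)
        p_ratio = mdd.state.P / control.state.P
        assert ratio == pytest.approx(p_ratio, rel=0.1)

    def test_directions_robust_across_dose_sweep(self, nominal, rng):
        """Blunted CRH and elevated DEX/CRH signatures across doses/KGR."""
        for _ in range(4):
            params = nominal.replace(KGR=rng.uniform(4.0, 8.0))
            dose = rng.uniform(2.0, 10.0)
            dex = rng.uniform(2.0, 5.0) * params.KGR
            control = make_subject("control", 1.0, params)
            mdd = make_subject("MDD", 1.0, params)
            assert crh_test(mdd, dose, params).peak_acth < \
                crh_test(control, dose, params).peak_acth
            assert dex_crh_test(mdd, dex, dose, params).peak_acth > \
                dex_crh_test(control, dex, dose, params).peak_acth
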