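"""Placement reconciliation, CVR equations, CO2 correction, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pccvr
from pccvr import (DataError, UndefinedCVRError, classify_response,
                   correct_for_petco2, cvr_hypercapnic, cvr_hypoxic_peto2,
                   cvr_hypoxic_spo2, fit_placement_model,
                   meaningful_change_threshold,
                   reconcile_vertebral_placements, steady_state_cbf)
from pccvr.cvrcore import PlacementModel, backtoback_pairs


class TestPlacementModel:
    def test_exact_linear_relation(self):
        p1 = np.array([50.0, 60.0, 70.0, 90.0])
        model = fit_placement_model(p1, 1.05 * p1, "L_VA")
        assert model.slope == pytest.approx(1.05)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_residual_sd_recovered_from_noise(self):
        rng = np.random.default_rng(17)
        p1 = rng.uniform(50, 120, 10)
        p2 = 1.02 * p1 + rng.normal(0.0, 5.0, 10)
        model = fit_placement_model(p1, p2, "L_VA")
        assert model.residual_sd == pytest.approx(5.0, rel=0.5)

    def test_too_few_points(self):
        with pytest.raises(DataError, match=">= 3"):
            fit_placement_model([1.0, 2.0], [1.0, 2.0], "L_VA")

    def test_constant_predictor(self):
        with pytest.raises(DataError, match="constant"):
            fit_placement_model([60.0] * 5, [58.0, 59, 60, 61, 62], "L_VA")


class TestReconciliationRule:
    model = PlacementModel(vessel="L_VA", slope=1.05, intercept=0.0,
                           residual_sd=5.0, n=20)

    def test_large_excess_triggers_substitution(self):
        # p1=60 predicts 63; p2=90 exceeds by 27 > 1.96*5 = 9.8
        assert reconcile_vertebral_placements(self.model, [60.0], [90.0])

    def test_on_prediction_keeps_placement_one(self):
        assert not reconcile_vertebral_placements(self.model, [60.0], [63.0])

    def test_rule_is_one_sided(self):
        # placement 2 *below* prediction never triggers, however far
        assert not reconcile_vertebral_placements(self.model, [60.0], [10.0])

    def test_any_timepoint_triggers(self):
        assert reconcile_vertebral_placements(
            self.model, [60.0, 80.0, 70.0], [63.0, 84.0, 95.0])

    def test_zero_residual_sd_needs_floor(self):
        degenerate = PlacementModel(vessel="L_VA", slope=1.0, intercept=0.0,
                                    residual_sd=0.0, n=5)
        with pytest.raises(DataError, match="floor"):
            reconcile_vertebral_placements(degenerate, [60.0], [70.0],
                                           residual_sd_floor=0.0)
        # with the default floor the rule is well-defined again
        assert reconcile_vertebral_placements(degenerate, [60.0], [70.0])


def session_frame(rows):
    cols = ["acq_id", "subject", "session", "phase", "placement", "start_s",
            "duration_s", "spo2_start", "hr_start", "flow_L_ICA",
            "flow_R_ICA", "flow_L_VA", "flow_R_VA"]
    return pd.DataFrame(rows, columns=cols)


def physio_frame(acq_ids, phase):
    return pd.DataFrame({
        "acq_id": acq_ids, "subject": 1, "session": 1, "phase": phase,
        "placement": 1, "petco2": 41.0, "peto2": 112.0, "ve": 9.0,
        "spo2": 98.0, "hr": 67.0})


class TestSteadyStateCbf:
    def make_inputs(self, p1_bl=(780.0, 778.0)):
        rows = []
        for i, total in enumerate(p1_bl):
            rows.append([f"a{i}", 1, 1, "BL", 1, 100.0 + 30 * i, 30.0, 98.0,
                         67.0, total * 0.38, total * 0.38, total * 0.12,
                         total * 0.12])
        rows.append(["p2", 1, 1, "BL", 2, 70.0, 30.0, 98.0, 67.0,
                     779.0 * 0.38, 779.0 * 0.38, 120.0, 121.0])
        acq = session_frame(rows)
        phys = physio_frame([r[0] for r in rows if r[4] == 1], "BL")
        return acq, phys

    def test_mean_of_two_acquisitions(self):
        acq, phys = self.make_inputs()
        out = steady_state_cbf(acq, phys, 1, 1, mass_g=1000.0)
        assert out.cbf["BL"] == pytest.approx(779.0)
        assert out.ncbf["BL"] == pytest.approx(77.9)

    def test_single_acquisition_used_directly(self):
        acq, phys = self.make_inputs(p1_bl=(780.0,))
        out = steady_state_cbf(acq, phys, 1, 1, mass_g=1000.0)
        assert out.cbf["BL"] == pytest.approx(780.0)

    def test_substitution_swaps_vertebral_only(self):
        acq, phys = self.make_inputs()
        out = steady_state_cbf(acq, phys, 1, 1, mass_g=1000.0,
                               substitutions={"L_VA": True})
        flows = out.vessel_flows["BL"]
        assert flows["L_VA"] == pytest.approx(120.0)   # placement-2 value
        assert flows["R_VA"] == pytest.approx(0.12 * 779.0)
        assert flows["L_ICA"] == pytest.approx(0.38 * 779.0)

    def test_ica_substitution_rejected(self):
        acq, phys = self.make_inputs()
        with pytest.raises(DataError, match="vertebral"):
            steady_state_cbf(acq, phys, 1, 1, 1000.0,
                             substitutions={"L_ICA": True})

    def test_missing_phase_absent_not_error(self):
        acq, phys = self.make_inputs()
        out = steady_state_cbf(acq, phys, 1, 1, 1000.0)
        assert not out.has_phase("HC")


class TestCvrEquations:
    def test_hypercapnic_group_mean_arithmetic(self):
        # 63 -> 77 mL/100 g/min over +5 mmHg: 100 * (14/63) / 5
        assert cvr_hypercapnic(63.0, 77.0, 41.0, 46.0) == \
            pytest.approx(4.4444, abs=1e-4)

    def test_hypercapnic_no_change_zero(self):
        assert cvr_hypercapnic(63.0, 63.0, 41.0, 46.0) == 0.0

    def test_hypercapnic_zero_delta_undefined(self):
        with pytest.raises(UndefinedCVRError):
            cvr_hypercapnic(63.0, 77.0, 41.0, 41.0)

    def test_hypoxic_peto2_group_mean_arithmetic(self):
        # 63 -> 67 while P_ET_O2 falls 112.3 -> 61.6
        assert cvr_hypoxic_peto2(63.0, 67.0, 112.3, 61.6) == \
            pytest.approx(0.12523, abs=1e-4)

    def test_hypoxic_peto2_paradoxical_negative(self):
        assert cvr_hypoxic_peto2(63.0, 60.0, 112.3, 61.6) == \
            pytest.approx(-0.09392, abs=1e-4)

    def test_hypoxic_spo2_group_mean_arithmetic(self):
        assert cvr_hypoxic_spo2(63.0, 67.0, 98.0, 90.0) == \
            pytest.approx(0.79365, abs=1e-4)

    def test_hypoxic_no_change_zero(self):
        assert cvr_hypoxic_peto2(63.0, 63.0, 112.3, 61.6) == 0.0
        assert cvr_hypoxic_spo2(63.0, 63.0, 98.0, 90.0) == 0.0

    def test_hypoxic_zero_delta_undefined(self):
        with pytest.raises(UndefinedCVRError):
            cvr_hypoxic_peto2(63.0, 67.0, 112.3, 112.3)
        with pytest.raises(UndefinedCVRError):
            cvr_hypoxic_spo2(63.0, 67.0, 98.0, 98.0)

    @given(delta=st.floats(0.1, 20.0), drop=st.floats(1.0, 60.0))
    @settings(max_examples=50, deadline=None)
    def test_sign_convention_and_antisymmetry(self, delta, drop):
        bl = 63.0
        up = cvr_hypoxic_peto2(bl, bl + delta, 112.3, 112.3 - drop)
        down = cvr_hypoxic_peto2(bl, bl - delta, 112.3, 112.3 - drop)
        assert up > 0
        assert down == pytest.approx(-up, rel=1e-9)


class TestCo2Correction:
    def test_worked_example(self):
        # Delta 3, baseline 63, CVR_HC 4.33 %/mmHg, P_ET_CO2 0.4 lower:
        # corrected = 3 - 63 * 0.0433 * (-0.4) = 4.09
        assert correct_for_petco2(3.0, 63.0, 4.33, -0.4) == \
            pytest.approx(4.0912, abs=1e-4)

    def test_identity_at_zero_delta_petco2(self):
        assert correct_for_petco2(3.0, 63.0, 4.33, 0.0) == 3.0

    def test_positive_perturbation_reduces_delta(self):
        assert correct_for_petco2(3.0, 63.0, 4.0, 1.0) == \
            pytest.approx(0.48, abs=1e-9)

    def test_correction_decorrelates_but_is_nonsignificant(self):
        # cohort with strong deliberate coupling: correction removes the
        # association with the concurrent P_ET_CO2 change
        config = pccvr.CohortConfig(n_subjects=20, n_sessions=3, seed=0,
                                    hx_petco2_perturb_sd=2.0,
                                    schedule=pccvr.Schedule.compact())
        study = pccvr.generate_cohort(config)
        result = pccvr.analyze_study(study)
        df = result.cvr_results.dropna(
            subset=["delta_petco2_hx", "delta_ncbf_hx",
                    "delta_ncbf_hx_corrected"])
        r_u, p_u = pccvr.pearson_r(df["delta_petco2_hx"],
                                   df["delta_ncbf_hx"])
        r_c, p_c = pccvr.pearson_r(df["delta_petco2_hx"],
                                   df["delta_ncbf_hx_corrected"])
        assert r_u > 0.3 and p_u < 0.01
        assert abs(r_c) < abs(r_u) / 3
        assert p_c > 0.05


class TestThresholdAndClassification:
    def test_median_absolute_difference(self):
        assert meaningful_change_threshold([1.0, -2.0, 3.0]) == 2.0

    def test_identical_pairs_zero(self):
        assert meaningful_change_threshold([0.0, 0.0]) == 0.0

    def test_no_pairs_errors(self):
        with pytest.raises(DataError):
            meaningful_change_threshold([])

    @pytest.mark.parametrize("delta, expected", [
        (3.0, "increase"), (-1.5, "minimal"), (-2.5, "decrease"),
        (1.99, "minimal"), (2.0, "increase")])
    def test_classification(self, delta, expected):
        assert classify_response(delta, 2.0) == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(DataError):
            classify_response(1.0, 0.0)


class TestPipelineRecovery:
    def test_zero_noise_recovery_exact(self, zero_noise_study,
                                       fixed_threshold_options):
        result = pccvr.analyze_study(zero_noise_study,
                                     options=fixed_threshold_options)
        df = result.cvr_results.set_index(["subject", "session"])
        for subj in zero_noise_study.truth:
            for sess in subj.sessions:
                row = df.loc[(subj.subject, sess.session)]
                assert row["cvr_hc"] == pytest.approx(sess.cvr_hc, abs=1e-9)
                assert row["cvr_hx_peto2_corrected"] == \
                    pytest.approx(sess.cvr_hx, abs=1e-9)
                assert row["ncbf_bl"] == pytest.approx(subj.baseline_ncbf,
                                                       abs=1e-9)

    def test_default_noise_cvr_hc_error_at_measurement_floor(self):
        # pipeline error must match the irreducible floor implied by the
        # back-to-back measurement noise, computed by a direct-formula
        # oracle under identical conditions
        config = pccvr.CohortConfig(n_subjects=34, n_sessions=3, seed=23,
                                    schedule=pccvr.Schedule.compact())
        study = pccvr.generate_cohort(config)
        result = pccvr.analyze_study(study)
        df = result.cvr_results.set_index(["subject", "session"])
        errors = []
        for subj in study.truth:
            for sess in subj.sessions:
                errors.append(abs(df.loc[(subj.subject, sess.session),
                                         "cvr_hc"] - sess.cvr_hc))
        assert len(errors) >= 100
        mae = np.mean(errors)

        rng = np.random.default_rng(99)
        n = 100000
        c = config
        bl = rng.normal(c.baseline_ncbf_mean, c.baseline_ncbf_sd, n)
        delta = rng.normal(c.hc_petco2_delta, c.hc_petco2_achieved_sd, n)
        cvr = rng.normal(c.cvr_hc_mean,
                         np.hypot(c.cvr_hc_sd_subject, c.cvr_hc_sd_session),
                         n)
        hc = bl * (1 + cvr * delta / 100.0)
        noise = c.ncbf_noise_sd / np.sqrt(2)  # two acquisitions averaged
        bl_m = bl + rng.normal(0, noise, n)
        hc_m = hc + rng.normal(0, noise, n)
        oracle_mae = np.mean(np.abs(100 * (hc_m - bl_m) / (bl_m * delta)
                                    - cvr))
        assert mae == pytest.approx(oracle_mae, rel=0.15)
        assert mae < 0.6

    def test_substitution_never_changes_ica_flows(self):
        config = pccvr.CohortConfig(n_subjects=12, n_sessions=2, seed=31,
                                    va_attenuation_prob=0.5,
                                    va_attenuation_range=(0.70, 0.85),
                                    schedule=pccvr.Schedule.compact())
        study = pccvr.generate_cohort(config)
        result = pccvr.analyze_study(study)
        flagged = [s for s in result.session_cbf
                   if any(s.substituted.values())]
        assert flagged, "attenuated cohort should trigger substitutions"
        acq = study.acquisitions
        for scbf in flagged:
            for phase, flows in scbf.vessel_flows.items():
                p1 = acq[(acq.subject == scbf.subject)
                         & (acq.session == scbf.session)
                         & (acq.phase == phase) & (acq.placement == 1)]
                for vessel in ("L_ICA", "R_ICA"):
                    assert flows[vessel] == pytest.approx(
                        p1[f"flow_{vessel}"].mean())

    def test_attenuated_sessions_flagged(self):
        # strong attenuation of one vessel is detected by the 1.96-sigma rule
        config = pccvr.CohortConfig(n_subjects=20, n_sessions=2, seed=2,
                                    va_attenuation_prob=0.12,
                                    va_attenuation_range=(0.70, 0.75),
                                    schedule=pccvr.Schedule.compact())
        study = pccvr.generate_cohort(config)
        result = pccvr.analyze_study(study)
        truth_flags, found_flags = [], []
        truth_map = {(s.subject, sess.session): sess
                     for s in study.truth for sess in s.sessions}
        for scbf in result.session_cbf:
            sess = truth_map[(scbf.subject, scbf.session)]
            for vessel in ("L_VA", "R_VA"):
                truth_flags.append(sess.va_attenuation[vessel] < 1.0)
                found_flags.append(scbf.substituted[vessel])
        truth_flags = np.array(truth_flags)
        found_flags = np.array(found_flags)
        # most strongly attenuated vessels are caught
        assert found_flags[truth_flags].mean() > 0.7

    def test_backtoback_pairs_counted_per_phase(self, small_study):
        mass = {t.subject: t.brain_volume_mL * 1.06
                for t in small_study.truth}
        pairs = backtoback_pairs(small_study.acquisitions, mass)
        # 8 sessions x (1 BL pair + 1 HX pair + 1 HC pair)
        assert len(pairs) == 24
        assert set(pairs["phase"]) == {"BL", "HX", "HC"}
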