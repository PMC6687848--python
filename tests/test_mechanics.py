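"""Ramp-trial reduction: corrections, averaging, stiffness and outcomes."""

import numpy as np
import pytest

from tendonkit import mechanics as mech
from tendonkit import synthetic as syn

from conftest import (CSA_DIST, CSA_FULL, CSA_PROX, MOMENT_ARM, REST_LENGTH,
                      STIFFNESS, STRAIN80, TFMAX_N)


def _trial(moment, angle=70.0, emg=0.0, n=None):
    moment = np.atleast_1d(np.asarray(moment, dtype=float))
    n = n or moment.size
    moment = np.resize(moment, n)
    return mech.RampTrial(np.arange(n) * 0.01, moment, np.resize(angle, n),
                          np.resize(emg, n), np.zeros(n))


class TestGravityCorrect:
    def test_zero_passive_is_identity(self):
        trial = _trial(np.linspace(0, 50, 100))
        passive = _trial(np.zeros(100), angle=np.linspace(55, 85, 100))
        assert np.allclose(mech.gravity_correct(trial, passive), trial.dyn_moment_Nm)

    def test_sinusoidal_gravity_removed(self):
        """A*sin(angle) gravity sampled by the passive sweep leaves <1 % of A."""
        amp = 8.0
        ang_p = np.linspace(55, 85, 400)
        passive = mech.RampTrial(np.arange(400) * 0.01,
                                 amp * np.sin(np.radians(ang_p)), ang_p,
                                 np.zeros(400), np.zeros(400))
        ang_t = np.linspace(58, 82, 200)
        trial = mech.RampTrial(np.arange(200) * 0.01,
                               amp * np.sin(np.radians(ang_t)), ang_t,
                               np.zeros(200), np.zeros(200))
        resid = mech.gravity_correct(trial, passive)
        assert np.abs(resid).max() < 0.01 * amp

    def test_constant_angle_constant_offset(self):
        ang_p = np.linspace(55, 85, 100)
        passive = mech.RampTrial(np.arange(100) * 0.01,
                                 3.0 + 0.1 * ang_p, ang_p,
                                 np.zeros(100), np.zeros(100))
        trial = _trial(np.linspace(0, 100, 50), angle=70.0)
        corr = trial.dyn_moment_Nm - mech.gravity_correct(trial, passive)
        assert np.allclose(corr, corr[0])

    def test_out_of_range_angle_warns(self):
        passive = _trial(np.zeros(100), angle=np.linspace(60, 80, 100))
        trial = _trial(np.ones(10), angle=90.0)
        with pytest.warns(UserWarning):
            mech.gravity_correct(trial, passive)


class TestEMGMomentModel:
    def test_exact_line_recovered(self):
        emg = np.linspace(0.05, 0.9, 50)
        trials = [_trial(30.0 * emg + 2.0, emg=emg)]
        model = mech.fit_emg_moment(trials)
        assert model.slope_Nm_per_emg == pytest.approx(30.0)
        assert model.intercept_Nm == pytest.approx(2.0)
        assert model.r2 == pytest.approx(1.0)

    def test_noisy_estimates_within_sampling_error(self):
        """OLS over 100 seeds: estimates within 3 SE of the true line."""
        emg = np.linspace(0.05, 0.9, 80)
        sigma = 1.5
        sxx = np.sum((emg - emg.mean()) ** 2)
        se_slope = sigma / np.sqrt(sxx)
        bad = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mom = 30.0 * emg + 2.0 + rng.normal(0, sigma, emg.size)
            model = mech.fit_emg_moment([_trial(mom, emg=emg)])
            if abs(model.slope_Nm_per_emg - 30.0) > 3 * se_slope:
                bad += 1
        assert bad <= 3  # ~0.3 % expected outside 3 SE; allow a small margin

    def test_constant_emg_rejected(self):
        with pytest.raises(ValueError):
            mech.fit_emg_moment([_trial(np.ones(10), emg=0.5)])


class TestAntagonistCorrect:
    def test_zero_emg_zero_intercept_identity(self):
        model = mech.EMGMomentModel(30.0, 0.0, 1.0)
        net = np.linspace(0, 200, 50)
        assert np.allclose(mech.antagonist_correct(net, np.zeros(50), model), net)

    def test_negative_prediction_clamped(self):
        model = mech.EMGMomentModel(30.0, -5.0, 1.0)
        out = mech.antagonist_correct(np.zeros(3), np.array([0.0, 0.1, 0.5]), model)
        assert np.allclose(out, [0.0, 0.0, 10.0])

    def test_generator_antagonist_recovered(self, clean_ramp_set):
        """Corrected moment equals the true extensor moment within 0.5 %."""
        rs = clean_ramp_set
        model = mech.fit_emg_moment(rs.flexion_trials)
        trial = rs.trials[0]
        net = mech.gravity_correct(trial, rs.passive)
        corrected = mech.antagonist_correct(net, trial.antagonist_emg, model)
        true_force = TFMAX_N * trial.time_s / trial.time_s[-1]
        true_moment = true_force * MOMENT_ARM / 1000.0
        scale = true_moment.max()
        assert np.abs(corrected - true_moment).max() < 5e-3 * scale


class TestMomentArmScaling:
    def test_identity_profile(self):
        assert mech.moment_arm_at_angle(54.1, 10.0, 70.0) == 54.1

    def test_doubling_profile(self):
        profile = (np.array([0.0, 90.0]), np.array([1.0, 3.0]))
        got = mech.moment_arm_at_angle(10.0, 0.0, 45.0, profile)
        assert got == pytest.approx(10.0 * 2.0)  # linear interp: 1 -> 2 at 45

    def test_piecewise_profile_matches_hand_interp(self):
        profile = (np.array([0.0, 30.0, 60.0]), np.array([1.0, 1.2, 0.9]))
        got = mech.moment_arm_at_angle(50.0, 30.0, 45.0, profile)
        assert got == pytest.approx(50.0 * 1.05 / 1.2)

    def test_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            mech.moment_arm_at_angle(50.0, 10.0, 95.0, (np.array([0.0, 90.0]),
                                                        np.array([1.0, 1.0])))


class TestTendonForce:
    def test_table_scale_force(self):
        """238 N*m over a 54.1 mm arm gives ~4399 N."""
        f = mech.tendon_force(np.array([238.0]), 54.1)
        assert f[0] == pytest.approx(4399.0, rel=2e-3)

    def test_zero_moment_zero_force(self):
        assert mech.tendon_force(np.zeros(3), 54.1).sum() == 0.0

    def test_doubling_arm_halves_force(self):
        m = np.array([100.0])
        assert mech.tendon_force(m, 108.2)[0] == pytest.approx(
            0.5 * mech.tendon_force(m, 54.1)[0])

    def test_nonpositive_arm_rejected(self):
        with pytest.raises(ValueError):
            mech.tendon_force(np.array([1.0]), 0.0)


class TestAveraging:
    def _law_trial(self, peak, toe=1.5, noise=0.0, seed=0, n=400):
        force = np.linspace(0, peak, n)
        elong = syn.elongation_law(force, TFMAX_N, STIFFNESS, toe)
        if noise:
            elong = elong + np.random.default_rng(seed).normal(0, noise, n)
        return force, elong

    def test_identical_trials_average_to_one(self):
        trials = [self._law_trial(TFMAX_N)] * 5
        curve = mech.average_force_elongation(trials, TFMAX_N)
        single = mech.average_force_elongation(trials[:1], TFMAX_N)
        assert curve.n_trials_averaged == 5
        assert np.allclose(curve.elongation_mm, single.elongation_mm)

    def test_noise_free_law_reproduced_on_linear_segment(self):
        curve = mech.average_force_elongation([self._law_trial(TFMAX_N, n=20000)],
                                              TFMAX_N, n_levels=100)
        # dense sampling makes interpolation error negligible on the law
        expected = syn.elongation_law(curve.force_N, TFMAX_N, STIFFNESS, 1.5)
        assert np.abs(curve.elongation_mm - expected).max() < 1e-6

    def test_short_trial_excluded(self):
        trials = [self._law_trial(TFMAX_N)] * 4 + [self._law_trial(0.75 * TFMAX_N)]
        with pytest.warns(UserWarning):
            curve = mech.average_force_elongation(trials, TFMAX_N)
        assert curve.n_trials_averaged == 4

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError):
            mech.average_force_elongation([self._law_trial(0.7 * TFMAX_N)], TFMAX_N)

    def test_monotone_inputs_give_monotone_curve(self):
        trials = [self._law_trial(TFMAX_N, seed=s, noise=0.0) for s in range(3)]
        curve = mech.average_force_elongation(trials, TFMAX_N)
        assert np.all(np.diff(curve.elongation_mm) >= 0)


class TestStiffness:
    def test_exact_linear_segment(self):
        force = np.linspace(0, TFMAX_N, 5000)
        elong = syn.elongation_law(force, TFMAX_N, STIFFNESS, 1.5)
        curve = mech.average_force_elongation([(force, elong)], TFMAX_N)
        assert mech.stiffness(curve) == pytest.approx(STIFFNESS, abs=1e-6)

    def test_doubled_elongation_halves_slope(self):
        force = np.linspace(0, TFMAX_N, 2000)
        elong = syn.elongation_law(force, TFMAX_N, STIFFNESS, 1.5)
        c1 = mech.average_force_elongation([(force, elong)], TFMAX_N)
        c2 = mech.average_force_elongation([(force, 2 * elong)], TFMAX_N)
        assert mech.stiffness(c2) == pytest.approx(0.5 * mech.stiffness(c1))

    def test_band_restriction(self):
        """Quadratic toe below 50 % does not contaminate the band slope."""
        force = np.linspace(0, TFMAX_N, 5000)
        elong = syn.elongation_law(force, TFMAX_N, STIFFNESS, 2.0)
        curve = mech.average_force_elongation([(force, elong)], TFMAX_N)
        assert mech.stiffness(curve) == pytest.approx(STIFFNESS, rel=1e-9)


class TestDerivedOutcomes:
    @pytest.fixture()
    def curve(self, toe_exponent):
        force = np.linspace(0, TFMAX_N, 20000)
        elong = syn.elongation_law(force, TFMAX_N, STIFFNESS, toe_exponent)
        return mech.average_force_elongation([(force, elong)], TFMAX_N, n_levels=200)

    def test_strain80_from_table_scale_elongation(self, curve):
        out = mech.derived_outcomes(curve, STIFFNESS, REST_LENGTH,
                                    CSA_PROX, CSA_DIST, CSA_FULL)
        assert curve.elongation_at(0.8 * TFMAX_N) == pytest.approx(3.4914, abs=1e-3)
        assert out.strain80_pct == pytest.approx(STRAIN80, abs=1e-3)

    def test_stress_is_force_over_area(self, curve):
        out = mech.derived_outcomes(curve, STIFFNESS, REST_LENGTH,
                                    CSA_PROX, CSA_DIST, CSA_FULL)
        assert out.stress_proximal_MPa == pytest.approx(TFMAX_N / CSA_PROX)
        assert out.stress_proximal_MPa == pytest.approx(37.28, abs=0.01)

    def test_extrapolated_strain_closed_form(self, curve):
        out = mech.derived_outcomes(curve, STIFFNESS, REST_LENGTH,
                                    CSA_PROX, CSA_DIST, CSA_FULL)
        expected = out.strain80_pct + 100.0 * (0.2 * TFMAX_N / STIFFNESS) / REST_LENGTH
        assert out.strain_max_extrapolated_pct == pytest.approx(expected, abs=1e-12)
        assert out.strain_max_extrapolated_pct == pytest.approx(7.84, abs=0.01)
        assert out.strain_max_extrapolated_pct >= out.strain80_pct

    def test_modulus_consistent_with_stiffness(self, curve):
        """E = k L0 / CSA when stress-strain derives from the same curve."""
        out = mech.derived_outcomes(curve, STIFFNESS, REST_LENGTH,
                                    CSA_PROX, CSA_DIST, CSA_FULL)
        k_band = mech.stiffness(curve)
        assert out.elastic_modulus_MPa == pytest.approx(
            k_band * REST_LENGTH / CSA_FULL, rel=1e-9)

    def test_normalized_stiffness_units(self, curve):
        out = mech.derived_outcomes(curve, STIFFNESS, REST_LENGTH,
                                    CSA_PROX, CSA_DIST, CSA_FULL)
        assert out.normalized_stiffness_kN_per_strain == pytest.approx(
            STIFFNESS * REST_LENGTH / 1000.0)

    def test_nonpositive_inputs_rejected(self, curve):
        with pytest.raises(ValueError):
            mech.derived_outcomes(curve, -1.0, REST_LENGTH, CSA_PROX, CSA_DIST, CSA_FULL)


class TestEndToEndRecovery:
    def test_noise_free_recovery(self, clean_ramp_set):
        rs = clean_ramp_set
        out = mech.analyze_trials(rs.trials, rs.passive, rs.flexion_trials,
                                  MOMENT_ARM, REST_LENGTH, CSA_PROX, CSA_DIST, CSA_FULL)
        assert out.tfmax_N == pytest.approx(rs.truth["tfmax_N"], rel=1e-3)
        assert out.stiffness_N_per_mm == pytest.approx(rs.truth["stiffness_N_per_mm"],
                                                       rel=1e-3)
        assert out.strain80_pct == pytest.approx(rs.truth["strain80_pct"], abs=1e-2)

    def test_noisy_stiffness_within_five_percent(self, toe_exponent):
        noise = 0.02 * TFMAX_N / STIFFNESS  # elongation equivalent of 2 % force noise
        errs = []
        for seed in range(100):
            rs = syn.gen_ramp_trials(syn.RampSpec(toe_exponent=toe_exponent,
                                                  noise_sd=noise, seed=seed))
            out = mech.analyze_trials(rs.trials, rs.passive, rs.flexion_trials,
                                      MOMENT_ARM, REST_LENGTH,
                                      CSA_PROX, CSA_DIST, CSA_FULL)
            errs.append(abs(out.stiffness_N_per_mm - STIFFNESS) / STIFFNESS)
        assert max(errs) < 0.05
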