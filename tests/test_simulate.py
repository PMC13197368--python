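"""Calibration, the generative model, and parameter recovery."""

import numpy as np
import pytest

from dualprobe import scoring, simulate
from dualprobe.psychometrics import build_item_matrix, kr20
from dualprobe.simulate import (
    CalibrationError,
    SimulationConfig,
    calibrate_from_descriptives,
    disattenuate_correlation,
    recovery_experiment,
    simulate_cohort,
    simulate_latents,
    simulate_outcome_arrays,
)


# --- calibration ----------------------------------------------------------


def test_calibration_hand_computation():
    """Defaults: error var = 0.48*0.52/(0.9326*240); latent SD ~ 0.1256."""
    expected = np.sqrt(0.13**2 - 0.48 * 0.52 / (0.9326 * 240))
    assert calibrate_from_descriptives() == pytest.approx(expected, abs=1e-12)
    assert calibrate_from_descriptives() == pytest.approx(0.1256, abs=5e-4)


def test_calibration_limits():
    # with no measurement error, the latent SD is the observed SD
    assert calibrate_from_descriptives(n_trials=10**9) == pytest.approx(0.13, abs=1e-4)
    # observed variance exactly at the binomial floor -> zero latent SD
    floor = np.sqrt(0.48 * 0.52 / (0.9326 * 240))
    assert calibrate_from_descriptives(observed_sd=floor) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(CalibrationError):
        calibrate_from_descriptives(observed_sd=0.02)
    with pytest.raises(CalibrationError):
        calibrate_from_descriptives(observed_mean=1.5)


def test_disattenuation():
    assert disattenuate_correlation(0.20, 1.0) == pytest.approx(0.20)
    assert disattenuate_correlation(0.20, 0.93) == pytest.approx(0.20 / np.sqrt(0.93))
    with pytest.raises(CalibrationError):
        disattenuate_correlation(0.9, 0.5)


# --- generative model -----------------------------------------------------


def test_null_bias_cohort_mean_index_half():
    """sigma_theta = 0, mu = 0.5, delta = 1: indices are Binomial(240, .5)/240."""
    cfg = SimulationConfig(
        n_participants=40, mu_theta=0.5, sigma_theta=0.0, mu_delta=1.0, sigma_delta=0.0, seed=3
    )
    cohort = simulate_cohort(cfg)
    results = [scoring.score_session(s) for s in cohort.sessions]
    assert all(r.identification_rate == 1.0 for r in results)
    assert all(r.retained for r in results)
    idx = np.array([r.ab_index for r in results])
    assert idx.mean() == pytest.approx(0.5, abs=0.02)  # se ~ 0.005


def test_round_trip_through_scoring(small_cohort):
    """Simulated logs satisfy all scoring-module validations and consistency."""
    for s in small_cohort.sessions:
        res = scoring.score_session(s)
        assert res.n_trials == 240
        assert scoring.score_stai_t(s.stai_t_items) == int(
            small_cohort.truth.set_index("participant_id").loc[s.participant_id, "trait"]
        )
        base = scoring.score_stai_s6(s.stai_s6_baseline)
        assert 0 <= base <= 100


def test_cohort_matches_calibrated_descriptives(calibrated_config):
    """Cohort moments land near the targets the calibration encodes."""
    cohort = simulate_cohort(calibrated_config.model_copy(update={"n_participants": 400}))
    results = [scoring.score_session(s) for s in cohort.sessions]
    retained = [r for r in results if r.retained]
    idx = np.array([r.ab_index for r in retained])
    rates = np.array([r.identification_rate for r in retained])
    assert idx.mean() == pytest.approx(0.48, abs=0.02)
    assert idx.std(ddof=1) == pytest.approx(0.13, abs=0.02)
    assert rates.mean() == pytest.approx(0.9326, abs=0.01)


def test_index_unbiased_for_latent_theta():
    """E[I | theta] = theta: mean estimation error vanishes over a large cohort."""
    cfg = SimulationConfig(n_participants=2000, sigma_theta=0.1256, seed=17)
    rng = np.random.default_rng(5)
    theta, delta, _ = simulate_latents(cfg, rng)
    neg, ident = simulate_outcome_arrays(cfg, rng, theta, delta)
    index = neg.sum(axis=1) / ident.sum(axis=1)
    assert np.mean(index - theta) == pytest.approx(0.0, abs=0.003)
    assert np.corrcoef(index, theta)[0, 1] > 0.9


def test_observed_index_sd_matches_calibration_identity():
    """Cohort SD of I converges to sqrt(sigma_theta^2 + binomial error)."""
    sig = calibrate_from_descriptives()
    cfg = SimulationConfig(n_participants=5000, sigma_theta=sig, seed=23)
    rng = np.random.default_rng(11)
    theta, delta, _ = simulate_latents(cfg, rng)
    neg, ident = simulate_outcome_arrays(cfg, rng, theta, delta)
    index = neg.sum(axis=1) / ident.sum(axis=1)
    assert index.std(ddof=1) == pytest.approx(0.13, abs=0.006)
    assert index.mean() == pytest.approx(0.48, abs=0.01)


def test_attenuation_identity_at_large_n():
    """corr(I, T) ~ rho_latent * sqrt(reliability) with binomial attenuation."""
    sig = calibrate_from_descriptives()
    cfg = SimulationConfig(n_participants=5000, sigma_theta=sig, rho_latent=0.207, seed=29)
    rng = np.random.default_rng(13)
    theta, delta, trait = simulate_latents(cfg, rng)
    neg, ident = simulate_outcome_arrays(cfg, rng, theta, delta)
    index = neg.sum(axis=1) / ident.sum(axis=1)
    reliability = sig**2 / 0.13**2
    expected = cfg.rho_latent * np.sqrt(reliability)
    assert np.corrcoef(index, trait)[0, 1] == pytest.approx(expected, abs=0.035)


def test_latent_truncation_and_trait_scale(calibrated_config):
    rng = np.random.default_rng(1)
    theta, delta, trait = simulate_latents(
        calibrated_config.model_copy(update={"n_participants": 1000}), rng
    )
    assert np.all((theta > 0) & (theta < 1))
    assert np.all((delta > 0) & (delta <= 1))
    assert np.all((trait >= 20) & (trait <= 80))
    assert np.array_equal(trait, np.rint(trait))


def test_recovery_experiment(calibrated_config):
    cfg = calibrated_config.model_copy(update={"n_participants": 60})
    report = recovery_experiment(cfg, n_replicates=2, seed=101)
    assert len(report) == 2
    assert (report["corr_index_theta"] > 0.85).all()
    assert report["mean_bias"].abs().max() < 0.02
    assert (report["kr20"] > 0.85).all()


def test_more_trials_raise_reliability(calibrated_config):
    """Doubling the probe count halves the error variance, raising KR-20."""
    base = calibrated_config.model_copy(update={"n_participants": 120, "seed": 31})
    double = base.model_copy(update={"probes_per_video": 20})
    rng1, rng2 = np.random.default_rng(41), np.random.default_rng(41)
    th1, d1, _ = simulate_latents(base, rng1)
    neg1, id1 = simulate_outcome_arrays(base, rng1, th1, d1)
    th2, d2, _ = simulate_latents(double, rng2)
    neg2, id2 = simulate_outcome_arrays(double, rng2, th2, d2)

    def kr(neg, ident):
        data = neg.astype(float)
        data[ident == 0] = np.nan
        return kr20(data)

    assert kr(neg2, id2) > kr(neg1, id1)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(mu_theta=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(rho_latent=2.0)
    with pytest.raises(ValueError):
        SimulationConfig(trait_bounds=(10, 90))
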