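"""Robust CAS estimation: initialization, optimization, equivariances."""

import numpy as np
import pytest

from cardiocas import (
    CASParameters,
    CAS_PARAM_NAMES,
    ParameterBounds,
    ProtocolTiming,
    RRiRecording,
    evaluate_model,
    fit_cas,
    huber_loss,
    initialize_parameters,
    inject_artifacts,
    simulate_rri_trajectory,
)


def test_initialization_locates_drop_onset(noiseless_recording, protocol):
    start = initialize_parameters(noiseless_recording, protocol)
    assert start.tau == pytest.approx(6.89, abs=0.5)
    assert start.alpha == pytest.approx(884.77, abs=10)


def test_initialization_flat_series_warns():
    rec = RRiRecording.from_intervals(np.full(800, 900.0))
    with pytest.warns(UserWarning, match="degenerate drop"):
        start = initialize_parameters(rec)
    assert start.alpha == pytest.approx(900.0)
    assert start.beta == pytest.approx(10.0)


def test_initialization_within_bounds_across_seeds(ref_params_noisy, protocol):
    bounds = ParameterBounds.for_protocol(protocol)
    for s in range(100):
        rec = simulate_rri_trajectory(ref_params_noisy, protocol, seed=s)
        start = initialize_parameters(rec, protocol, bounds)
        assert bounds.contains(start.as_array())


def test_noiseless_round_trip_recovers_all_parameters(noiseless_recording, ref_params):
    fit = fit_cas(noiseless_recording, seed=0)
    assert fit.converged
    est, tru = fit.estimate.as_array(), ref_params.as_array()
    assert np.all(np.abs(est - tru) / np.abs(tru) < 1e-3)


def test_reported_loss_matches_independent_recomputation(noisy_recording):
    fit = fit_cas(noisy_recording, seed=2)
    r = noisy_recording.kept_intervals - evaluate_model(
        noisy_recording.kept_times, fit.estimate.as_array()
    )
    assert fit.loss == pytest.approx(huber_loss(r, fit.huber_threshold), rel=1e-8)


def test_translation_equivariance(ref_params, protocol):
    rec = simulate_rri_trajectory(ref_params, protocol, seed=0)
    shift = 3.0
    shifted = RRiRecording(rec.beat_times + shift, rec.intervals.copy())
    bounds = ParameterBounds(tau=(0.0, protocol.total_duration + shift))
    base = fit_cas(rec, seed=0).estimate.as_array()
    moved = fit_cas(shifted, bounds=bounds, seed=0).estimate.as_array()
    assert moved[5] - base[5] == pytest.approx(shift, abs=0.01)
    others = [0, 1, 2, 3, 4, 6]
    assert np.allclose(moved[others], base[others], rtol=1e-3)


def test_scale_equivariance(ref_params, protocol):
    rec = simulate_rri_trajectory(ref_params, protocol, seed=0)
    s = 1.2
    scaled = RRiRecording(rec.beat_times.copy(), rec.intervals * s)
    base = fit_cas(rec, seed=0).estimate.as_array()
    mod = fit_cas(scaled, seed=0).estimate.as_array()
    assert mod[0] == pytest.approx(base[0] * s, rel=1e-3)  # alpha
    assert mod[1] == pytest.approx(base[1] * s, rel=1e-3)  # beta
    assert np.allclose(mod[2:], base[2:], rtol=1e-2, atol=1e-3)


def test_matches_coarse_grid_plus_polish_oracle(noiseless_recording, ref_params, protocol):
    """Independent brute-force route: coarse grid over the nonlinear
    parameters, then a derivative-free polish of the best grid point."""
    from itertools import product

    from scipy.optimize import minimize

    t, y = noiseless_recording.kept_times, noiseless_recording.kept_intervals

    def sse(theta):
        r = y - evaluate_model(t, theta)
        return float(r @ r)

    start = initialize_parameters(noiseless_recording, protocol)
    best, best_val = None, np.inf
    for lam, phi, tau, delta in product(
        [1.0, 3.0, 6.0], [1.0, 3.0, 6.0], np.arange(5.0, 9.1, 0.5), [1.0, 2.0, 3.0]
    ):
        theta = np.array([start.alpha, start.beta, 0.9, lam, phi, tau, delta])
        v = sse(theta)
        if v < best_val:
            best, best_val = theta, v
    polish = minimize(sse, best, method="Nelder-Mead",
                      options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    oracle = polish.x
    qn = fit_cas(noiseless_recording, seed=0).estimate.as_array()
    assert np.all(np.abs(qn - oracle) / np.maximum(np.abs(oracle), 1e-6) < 0.01)


def test_mean_alpha_recovery_under_noise(ref_params_noisy, protocol):
    ests = []
    for s in range(1, 7):
        rec = simulate_rri_trajectory(ref_params_noisy, protocol, seed=s)
        ests.append(fit_cas(rec, seed=s).estimate.alpha)
    assert np.mean(ests) == pytest.approx(ref_params_noisy.alpha, rel=0.01)


def test_huber_beats_least_squares_in_aggregate(ref_params_noisy, protocol):
    """Paired across 20 seeds with 5% uncorrected ectopic spikes, the
    Huber fit's across-seed RMSE is strictly smaller than plain least
    squares' for every parameter."""
    tru = ref_params_noisy.as_array()
    H, Q = [], []
    for s in range(1, 21):
        rec = simulate_rri_trajectory(ref_params_noisy, protocol, seed=s)
        corrupted, _ = inject_artifacts(rec, 0.05, (0.4, 0.6), seed=1000 + s)
        H.append(fit_cas(corrupted, seed=s).estimate.as_array())
        Q.append(fit_cas(corrupted, seed=s, loss="squared").estimate.as_array())
    relH = (np.array(H) - tru) / tru
    relQ = (np.array(Q) - tru) / tru
    rmseH = np.sqrt((relH**2).mean(0))
    rmseQ = np.sqrt((relQ**2).mean(0))
    assert np.all(rmseH < rmseQ)


def test_unknown_loss_rejected(noisy_recording):
    with pytest.raises(ValueError):
        fit_cas(noisy_recording, loss="cauchy")


def test_fit_is_deterministic_given_seed(noisy_recording):
    a = fit_cas(noisy_recording, seed=4).estimate.as_array()
    b = fit_cas(noisy_recording, seed=4).estimate.as_array()
    assert np.array_equal(a, b)


def test_sigma_estimated_from_residual_scale(ref_params_noisy, protocol):
    rec = simulate_rri_trajectory(ref_params_noisy, protocol, seed=9)
    fit = fit_cas(rec, seed=9)
    assert fit.estimate.sigma == pytest.approx(30.0, rel=0.1)
    assert fit.n_beats_used == rec.n_kept
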