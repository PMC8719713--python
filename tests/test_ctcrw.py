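import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from oracles import brute_force_ctcrw_loglik
from whimtrack import ctcrw
from whimtrack.geodesy import aeq_inverse, great_circle_km
from whimtrack.io import Fix, Track

UTC = "UTC"


def _track_from_planar(t_h, xy, lat0=45.0, lon0=-60.0, lc="LC3", animal="a"):
    lats, lons = aeq_inverse(xy[:, 0], xy[:, 1], lat0, lon0)
    base = pd.Timestamp("2020-01-01", tz=UTC)
    fixes = [Fix(animal, base + pd.Timedelta(hours=float(h)), float(la), float(lo), lc)
             for h, la, lo in zip(t_h, lats, lons)]
    return Track(animal, fixes)


@pytest.mark.parametrize("beta,sigma", [(0.5, 5.0), (2.0, 1.0), (0.05, 20.0)])
def test_kalman_likelihood_equals_brute_force_mvn(beta, sigma):
    """Filter likelihood equals the joint-Gaussian density on small instances."""
    rng = np.random.default_rng(3)
    for n in (2, 5, 12):
        t_h = np.sort(rng.uniform(0, 72, n))
        t_h[0] = 0.0
        obs = rng.normal(0, 8, (n, 2))
        err = rng.uniform(0.1, 0.7, n)
        kl = ctcrw.kalman_loglik(t_h, obs, err, beta, sigma)
        bl = brute_force_ctcrw_loglik(t_h, obs, err, beta, sigma,
                                      ctcrw.transition_matrices)
        assert abs(kl - bl) / abs(bl) < 1e-6


def test_simulation_is_seeded_and_velocity_decorrelates():
    params = ctcrw.CTCRWParams(beta_per_h=0.8, sigma=4.0)
    t1, xy1 = ctcrw.simulate_ctcrw(params, duration_h=2000, dt_h=0.5, seed=9)
    t2, xy2 = ctcrw.simulate_ctcrw(params, duration_h=2000, dt_h=0.5, seed=9)
    assert np.array_equal(xy1, xy2)
    # autocorrelation of interval-averaged velocities: closed form for the
    # integrated OU is exp(-beta*m*dt) * (1-e^-bd)(e^bd-1) / (2(bd-1+e^-bd))
    v = np.diff(xy1[:, 0]) / 0.5
    beta, dt = 0.8, 0.5
    bd = beta * dt
    shape = (1 - np.exp(-bd)) * (np.exp(bd) - 1) / (2 * (bd - 1 + np.exp(-bd)))
    for lag_steps in (1, 2, 4):
        rho = np.corrcoef(v[:-lag_steps], v[lag_steps:])[0, 1]
        expected = np.exp(-beta * lag_steps * dt) * shape
        assert rho == pytest.approx(expected, abs=0.08)


def test_sigma_zero_limit_is_straight_uniform_motion():
    params = ctcrw.CTCRWParams(beta_per_h=1e-9, sigma=1e-12)
    t, xy = ctcrw.simulate_ctcrw(params, duration_h=10, dt_h=1.0, seed=0,
                                 start_v=(3.0, -1.0))
    vx = np.diff(xy[:, 0])
    assert np.allclose(vx, 3.0, atol=1e-5)
    assert np.allclose(np.diff(xy[:, 1]), -1.0, atol=1e-5)


def test_fit_recovers_parameters_within_two_se():
    beta, sigma = 0.5, 5.0
    t, xy = ctcrw.simulate_ctcrw(ctcrw.CTCRWParams(beta, sigma),
                                 duration_h=0.5 * 499, dt_h=0.5, seed=42,
                                 start_v=(3.0, 1.0))
    rng = np.random.default_rng(1)
    noisy = xy + rng.normal(0, 0.1, xy.shape)
    track = _track_from_planar(t, noisy)
    fit = ctcrw.fit_ctcrw(track)
    assert fit.converged
    assert abs(np.log(fit.params.beta_per_h) - np.log(beta)) < 2 * fit.se_log_beta
    assert abs(np.log(fit.params.sigma) - np.log(sigma)) < 2 * fit.se_log_sigma
    assert fit.log_likelihood >= -1e12


def test_fit_improves_on_init_and_needs_enough_fixes():
    t, xy = ctcrw.simulate_ctcrw(ctcrw.CTCRWParams(1.0, 3.0), 100, 1.0, seed=5)
    track = _track_from_planar(t, xy)
    init = ctcrw.CTCRWParams(beta_per_h=0.01, sigma=50.0)
    fit = ctcrw.fit_ctcrw(track, init=init)
    t_h, obs, err, _ = ctcrw._prepare_obs(track, init.obs_error_m_by_class)
    ll_init = ctcrw.kalman_loglik(t_h, obs, err, init.beta_per_h, init.sigma)
    assert fit.log_likelihood >= ll_init
    with pytest.raises(ValueError):
        ctcrw.fit_ctcrw(_track_from_planar(t[:5], xy[:5]))


def test_degenerate_stationary_track_flags_not_crashes():
    xy = np.zeros((20, 2))
    track = _track_from_planar(np.arange(20.0), xy)
    fit = ctcrw.fit_ctcrw(track)
    assert fit.degenerate or fit.params.sigma < 0.05


def test_smoother_passes_through_noise_free_dense_observations():
    params = ctcrw.CTCRWParams(beta_per_h=0.5, sigma=5.0,
                               obs_error_m_by_class={"LC3": 0.0})
    t, xy = ctcrw.simulate_ctcrw(ctcrw.CTCRWParams(0.5, 5.0), 24, 0.25, seed=2,
                                 start_v=(5.0, 0.0))
    track = _track_from_planar(t, xy)
    path = ctcrw.predict_path(track, params, dt_minutes=15.0)
    # every observation instant is on the grid; smoothed point must match
    t_h, obs, err, center = ctcrw._prepare_obs(track, params.obs_error_m_by_class)
    for k in range(0, len(t_h), 7):
        i = int(np.argmin(np.abs((path.instants - track.times[k]).total_seconds())))
        d = great_circle_km(path.lats[i], path.lons[i],
                            track.lats[k], track.lons[k])
        assert d < 1e-3


def test_two_fix_high_beta_limit_is_straight_segment():
    """As velocity correlation vanishes, the smoothed path approaches the chord."""
    track = make_track([(45.0, -60.0), (46.0, -58.0)], step_h=5.0)
    params = ctcrw.CTCRWParams(beta_per_h=40.0, sigma=2.0,
                               obs_error_m_by_class={"LC3": 1.0})
    path = ctcrw.predict_path(track, params, dt_minutes=15.0)
    from whimtrack.stats import path_length_km
    chord = great_circle_km(45.0, -60.0, 46.0, -58.0)
    assert path_length_km(path) == pytest.approx(chord, rel=0.02)


def test_uncertainty_smaller_at_observations_than_in_gaps():
    base = pd.Timestamp("2020-01-01", tz=UTC)
    # two dense clusters separated by a 48 h gap
    hours = list(np.arange(0, 5, 1.0)) + list(np.arange(53, 58, 1.0))
    fixes = [Fix("a", base + pd.Timedelta(hours=h), 45.0 + 0.01 * h, -60.0, "LC3")
             for h in hours]
    track = Track("a", fixes)
    params = ctcrw.CTCRWParams(beta_per_h=0.5, sigma=3.0)
    path = ctcrw.predict_path(track, params, dt_minutes=30.0)
    sd = path.position_sd_km
    t_rel = (path.instants - path.instants[0]).total_seconds() / 3600.0
    sd_obs = sd[np.argmin(np.abs(t_rel - 4.0))]
    sd_gap = sd[np.argmin(np.abs(t_rel - 29.0))]   # middle of the gap
    assert sd_obs < sd_gap
    with pytest.raises(ValueError):
        ctcrw.predict_path(track, params, dt_minutes=0.0)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ctcrw.CTCRWParams(beta_per_h=0.0, sigma=1.0)
    with pytest.raises(ValueError):
        ctcrw.CTCRWParams(beta_per_h=1.0, sigma=-1.0)
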