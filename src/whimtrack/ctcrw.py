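"""Continuous-time correlated random walk (CTCRW) fitting and interpolation.

The movement model is the integrated Ornstein–Uhlenbeck process: per planar
axis the velocity v follows ``dv = -beta * v dt + sigma * dW`` and position
integrates v.  Observations are the position plus Gaussian measurement error
whose SD is fixed by the ARGOS location class.  This is the classical
state-space model used to fill duty-cycle gaps in satellite tracks: the
Kalman filter gives the exact likelihood at irregular observation times, and
the fixed-interval (RTS) smoother predicts positions with uncertainty on a
regular grid.

Working frame
-------------
Each track segment is projected with an azimuthal-equidistant projection
centered on its midpoint fix, fitted and smoothed in planar km, and the
prediction grid is inverse-projected before any geodesic measurement.

Parameters
----------
``beta_per_h``  velocity autocorrelation decay rate (1/h): the velocity
    decorrelates as exp(-beta * lag).  Large beta → near straight-line
    ballistic interpolation between fixes.
``sigma``      velocity stochasticity scale (km/h per sqrt(h)); the
    stationary velocity SD is sigma / sqrt(2 * beta).
``obs_error_m_by_class``  per-location-class measurement SD in meters
    (defaults LC3=100, LC2=250, LC1=700); fixed, not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .geodesy import aeq_forward, aeq_inverse

DEFAULT_OBS_ERROR_M = {"LC3": 100.0, "LC2": 250.0, "LC1": 700.0,
                       "LC0": 1500.0, "LCA": 3000.0, "LCB": 5000.0, "LCZ": 10000.0}


@dataclass(frozen=True)
class CTCRWParams:
    beta_per_h: float
    sigma: float
    obs_error_m_by_class: dict = field(default_factory=lambda: dict(DEFAULT_OBS_ERROR_M))

    def __post_init__(self):
        if self.beta_per_h <= 0 or self.sigma <= 0:
            raise ValueError("beta and sigma must be strictly positive")
        if any(v < 0 for v in self.obs_error_m_by_class.values()):
            raise ValueError("observation error SDs must be non-negative")


@dataclass
class InterpolatedPath:
    """Smoothed positions on a regular time grid with per-instant uncertainty."""

    animal_id: str
    instants: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    position_sd_km: np.ndarray


@dataclass
class CTCRWFit:
    params: CTCRWParams
    log_likelihood: float
    se_log_beta: float
    se_log_sigma: float
    converged: bool
    degenerate: bool = False

    def __iter__(self):  # allows `params, ll = fit_ctcrw(...)`
        return iter((self.params, self.log_likelihood))


def transition_matrices(beta: float, sigma: float, dt_h: np.ndarray):
    """Exact IOU transition (T) and process-noise (Q) blocks per interval.

    State per axis is (position, velocity); returned arrays have shape
    (n, 2, 2).  These are the standard closed-form discretizations of the
    integrated OU process at irregular steps.
    """
    dt = np.asarray(dt_h, dtype=float)
    e1 = np.exp(-beta * dt)
    e2 = np.exp(-2.0 * beta * dt)
    phi = (1.0 - e1) / beta
    T = np.zeros(dt.shape + (2, 2))
    T[..., 0, 0] = 1.0
    T[..., 0, 1] = phi
    T[..., 1, 1] = e1
    s2 = sigma ** 2
    Q = np.zeros_like(T)
    Q[..., 0, 0] = s2 / beta ** 2 * (dt - 2.0 * phi + (1.0 - e2) / (2.0 * beta))
    Q[..., 0, 1] = Q[..., 1, 0] = s2 * (1.0 - e1) ** 2 / (2.0 * beta ** 2)
    Q[..., 1, 1] = s2 * (1.0 - e2) / (2.0 * beta)
    return T, Q


def _prepare_obs(track, obs_error_m):
    """Project a track to the planar frame; return times (h), xy (km), err (km)."""
    times = track.times
    t_h = (times - times[0]).total_seconds().to_numpy() / 3600.0
    mid = len(track.fixes) // 2
    lat0, lon0 = track.fixes[mid].lat, track.fixes[mid].lon
    x, y = aeq_forward(track.lats, track.lons, lat0, lon0)
    err_km = np.array([obs_error_m.get(f.location_class, 1500.0) / 1000.0
                       for f in track.fixes])
    return t_h, np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]), err_km, (lat0, lon0)


def _initial_state(obs_xy, err_km, beta, sigma):
    """Prior at the first observation time: position at the first fix with its
    measurement variance, velocity at the stationary distribution."""
    m0 = np.array([obs_xy[0, 0], obs_xy[0, 1], 0.0, 0.0])
    vvar = sigma ** 2 / (2.0 * beta)
    pvar = max(err_km[0] ** 2, 1e-6)
    P0 = np.diag([pvar, pvar, vvar, vvar])
    return m0, P0


def _expand(T2, Q2):
    """2x2 per-axis blocks -> 4x4 (x, y, vx, vy) with independent axes."""
    n = T2.shape[0]
    T = np.zeros((n, 4, 4))
    Q = np.zeros((n, 4, 4))
    for a, b in ((0, 2), (1, 3)):
        T[:, a, a] = T2[:, 0, 0]
        T[:, a, b] = T2[:, 0, 1]
        T[:, b, b] = T2[:, 1, 1]
        Q[:, a, a] = Q2[:, 0, 0]
        Q[:, a, b] = Q[:, b, a] = Q2[:, 0, 1]
        Q[:, b, b] = Q2[:, 1, 1]
    return T, Q


_H = np.zeros((2, 4))
_H[0, 0] = _H[1, 1] = 1.0


def kalman_loglik(t_h, obs_xy, err_km, beta, sigma) -> float:
    """Exact Gaussian log-likelihood of the observations under the CTCRW."""
    T2, Q2 = transition_matrices(beta, sigma, np.diff(t_h))
    T, Q = _expand(T2, Q2)
    m, P = _initial_state(obs_xy, err_km, beta, sigma)
    ll = 0.0
    for k in range(len(t_h)):
        if k > 0:
            m = T[k - 1] @ m
            P = T[k - 1] @ P @ T[k - 1].T + Q[k - 1]
        r2 = max(err_km[k] ** 2, 1e-12)
        S = _H @ P @ _H.T + r2 * np.eye(2)
        innov = obs_xy[k] - _H @ m
        Sinv = np.linalg.inv(S)
        sign, logdet = np.linalg.slogdet(S)
        ll += -0.5 * (2.0 * np.log(2.0 * np.pi) + logdet + innov @ Sinv @ innov)
        K = P @ _H.T @ Sinv
        m = m + K @ innov
        P = P - K @ S @ K.T
        P = 0.5 * (P + P.T)
    return float(ll)


#: Documented fixed starting point for the optimizer (log-space).
DEFAULT_INIT = CTCRWParams(beta_per_h=1.0, sigma=10.0)
_LOG_BOUNDS = ((np.log(1e-3), np.log(50.0)), (np.log(1e-3), np.log(500.0)))


def fit_ctcrw(track, init: CTCRWParams | None = None, bounds=None,
              min_fixes: int = 8) -> CTCRWFit:
    """Maximum-likelihood beta, sigma for one track via the Kalman filter.

    Optimization runs on log-transformed parameters (positivity) from a fixed
    documented initial point, so the fit is deterministic.  Standard errors of
    the log-parameters come from the numerical Hessian at the optimum.
    """
    if len(track.fixes) < min_fixes:
        raise ValueError(f"need at least {min_fixes} fixes, got {len(track.fixes)}")
    init = init or DEFAULT_INIT
    bounds = bounds or _LOG_BOUNDS
    t_h, obs_xy, err_km, _ = _prepare_obs(track, init.obs_error_m_by_class)
    if t_h[-1] <= 0:
        raise ValueError("track has zero time span")

    def nll(theta):
        b, s = np.exp(theta)
        val = -kalman_loglik(t_h, obs_xy, err_km, b, s)
        return val if np.isfinite(val) else 1e12

    theta0 = np.log([init.beta_per_h, init.sigma])
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    beta_hat, sigma_hat = np.exp(res.x)
    se_lb, se_ls = _hessian_se(nll, res.x)
    at_bound = any(abs(res.x[i] - bounds[i][j]) < 1e-6
                   for i in range(2) for j in range(2))
    params = replace(init, beta_per_h=float(beta_hat), sigma=float(sigma_hat))
    return CTCRWFit(params=params, log_likelihood=float(-res.fun),
                    se_log_beta=se_lb, se_log_sigma=se_ls,
                    converged=bool(res.success), degenerate=at_bound)


def _hessian_se(f, x, h: float = 1e-4):
    """SEs from the inverse numerical Hessian (central differences)."""
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h
            ej = np.eye(n)[j] * h
            H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                 - f(x - ei + ej) + f(x - ei - ej)) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if (d <= 0).any():
            return np.inf, np.inf
        return float(np.sqrt(d[0])), float(np.sqrt(d[1]))
    except np.linalg.LinAlgError:
        return np.inf, np.inf


def predict_path(track, params: CTCRWParams, dt_minutes: float = 15.0) -> InterpolatedPath:
    """Fixed-interval smoother on a regular grid spanning the track.

    Forward Kalman filter over the union of grid and observation instants,
    then the Rauch–Tung–Striebel backward pass; grid rows are returned with
    position SD (km, RMS of the two planar axes).  With zero observation
    noise and an observation exactly on a grid instant the smoothed position
    equals that observation.
    """
    if dt_minutes <= 0:
        raise ValueError("dt must be positive")
    t_h, obs_xy, err_km, center = _prepare_obs(track, params.obs_error_m_by_class)
    dt_h = dt_minutes / 60.0
    n_steps = int(np.floor((t_h[-1] - t_h[0]) / dt_h + 1e-9))
    grid = t_h[0] + dt_h * np.arange(n_steps + 1)
    # merge grid and observation times; grid point coincident with an
    # observation reuses that instant
    all_t = np.unique(np.concatenate([grid, t_h]))
    obs_idx = np.searchsorted(all_t, t_h)
    is_obs = np.zeros(all_t.size, dtype=bool)
    is_obs[obs_idx] = True
    obs_at = {int(i): k for k, i in enumerate(obs_idx)}

    beta, sigma = params.beta_per_h, params.sigma
    T2, Q2 = transition_matrices(beta, sigma, np.diff(all_t))
    T, Q = _expand(T2, Q2)
    n = all_t.size
    m_pred = np.zeros((n, 4))
    P_pred = np.zeros((n, 4, 4))
    m_filt = np.zeros((n, 4))
    P_filt = np.zeros((n, 4, 4))
    m, P = _initial_state(obs_xy, err_km, beta, sigma)
    for k in range(n):
        if k > 0:
            m = T[k - 1] @ m
            P = T[k - 1] @ P @ T[k - 1].T + Q[k - 1]
        m_pred[k], P_pred[k] = m, P
        if is_obs[k]:
            j = obs_at[k]
            r2 = max(err_km[j] ** 2, 1e-12)
            S = _H @ P @ _H.T + r2 * np.eye(2)
            K = P @ _H.T @ np.linalg.inv(S)
            m = m + K @ (obs_xy[j] - _H @ m)
            P = P - K @ S @ K.T
            P = 0.5 * (P + P.T)
        m_filt[k], P_filt[k] = m, P

    m_sm = m_filt.copy()
    P_sm = P_filt.copy()
    for k in range(n - 2, -1, -1):
        G = P_filt[k] @ T[k].T @ np.linalg.inv(P_pred[k + 1])
        m_sm[k] = m_filt[k] + G @ (m_sm[k + 1] - m_pred[k + 1])
        P_sm[k] = P_filt[k] + G @ (P_sm[k + 1] - P_pred[k + 1]) @ G.T
        P_sm[k] = 0.5 * (P_sm[k] + P_sm[k].T)

    gi = np.searchsorted(all_t, grid)
    xy = m_sm[gi][:, :2]
    sd = np.sqrt(0.5 * (P_sm[gi][:, 0, 0] + P_sm[gi][:, 1, 1]).clip(min=0.0))
    lats, lons = aeq_inverse(xy[:, 0], xy[:, 1], *center)
    t0 = track.times[0]
    instants = t0 + pd.to_timedelta((grid - t_h[0]) * 3600.0, unit="s")
    return InterpolatedPath(animal_id=track.animal_id, instants=pd.DatetimeIndex(instants),
                            lats=np.atleast_1d(lats), lons=np.atleast_1d(lons),
                            position_sd_km=sd)


def smoother_variances(track, params: CTCRWParams, dt_minutes: float = 15.0):
    """(filter SD, smoother SD) on the prediction grid — diagnostic helper."""
    # kept minimal: recompute via predict_path internals for tests
    path = predict_path(track, params, dt_minutes)
    return path.position_sd_km


def simulate_ctcrw(params: CTCRWParams, duration_h: float, dt_h: float, seed: int,
                   start_xy=(0.0, 0.0), start_v=(0.0, 0.0)):
    """Sample the IOU process exactly at the discretization points.

    Returns (times_h, xy) with xy of shape (n, 2) in planar km.  The same
    seed reproduces the same sample path bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_h / dt_h)) + 1
    t = dt_h * np.arange(n)
    T2, Q2 = transition_matrices(params.beta_per_h, params.sigma,
                                 np.full(n - 1, dt_h))
    # all steps equal: factor one noise covariance
    Q = Q2[0]
    w, V = np.linalg.eigh(Q)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    Tm = T2[0]
    state = np.array([[start_xy[0], start_v[0]], [start_xy[1], start_v[1]]])  # per-axis (x, v)
    out = np.zeros((n, 2))
    out[0] = state[:, 0]
    for k in range(1, n):
        noise = (L @ rng.standard_normal((2, 2))).T  # independent per axis
        state = state @ Tm.T + noise
        out[k] = state[:, 0]
    return t, out
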