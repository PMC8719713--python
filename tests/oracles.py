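"""Independent oracles used by the tests.

These deliberately avoid the implementation paths they check: Vincenty's
ellipsoidal distance (vs the package's spherical haversine), a brute-force
joint-Gaussian likelihood for the correlated-random-walk state-space model
(vs the Kalman recursion), and brute-force single-linkage clustering.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import multivariate_normal

# WGS84
_A = 6378137.0
_F = 1 / 298.257223563
_B = _A * (1 - _F)


def vincenty_km(lat1, lon1, lat2, lon2, tol=1e-12, max_iter=200):
    """Vincenty inverse solution on the WGS84 ellipsoid, km."""
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    U1 = math.atan((1 - _F) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - _F) * math.tan(math.radians(lat2)))
    L = math.radians(lon2 - lon1)
    lam = L
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.sqrt((cosU2 * sin_lam) ** 2
                              + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha ** 2
        cos_2sm = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha else 0.0
        C = _F / 16 * cos2_alpha * (4 + _F * (4 - 3 * cos2_alpha))
        lam_new = L + (1 - C) * _F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm ** 2)))
        if abs(lam_new - lam) < tol:
            lam = lam_new
            break
        lam = lam_new
    u2 = cos2_alpha * (_A ** 2 - _B ** 2) / _B ** 2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    d_sigma = B * sin_sigma * (cos_2sm + B / 4 * (
        cos_sigma * (-1 + 2 * cos_2sm ** 2)
        - B / 6 * cos_2sm * (-3 + 4 * sin_sigma ** 2) * (-3 + 4 * cos_2sm ** 2)))
    return _B * A * (sigma - d_sigma) / 1000.0


def brute_force_ctcrw_loglik(t_h, obs_xy, err_km, beta, sigma,
                             transition_matrices) -> float:
    """Joint multivariate-normal log-density of the observations.

    Builds the full covariance of the per-axis (position, velocity) states
    at the observation times by composing exact transition blocks, then
    evaluates the Gaussian density of the observed positions directly.
    Matches the package's prior convention: position at the first fix with
    its measurement variance, velocity at the stationary distribution.
    """
    t_h = np.asarray(t_h, dtype=float)
    obs_xy = np.asarray(obs_xy, dtype=float)
    n = len(t_h)
    T2, Q2 = transition_matrices(beta, sigma, np.diff(t_h))
    vvar = sigma ** 2 / (2.0 * beta)
    pvar = max(err_km[0] ** 2, 1e-6)
    H = np.array([[1.0, 0.0]])
    ll = 0.0
    for ax in range(2):
        means = [np.array([obs_xy[0, ax], 0.0])]
        P = [np.diag([pvar, vvar])]
        for k in range(1, n):
            means.append(T2[k - 1] @ means[-1])
            P.append(T2[k - 1] @ P[-1] @ T2[k - 1].T + Q2[k - 1])
        C = np.zeros((n, n, 2, 2))
        for j in range(n):
            C[j, j] = P[j]
            Ai = np.eye(2)
            for i in range(j + 1, n):
                Ai = T2[i - 1] @ Ai
                C[i, j] = Ai @ P[j]
                C[j, i] = C[i, j].T
        mu = np.array([(H @ means[k])[0] for k in range(n)])
        S = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                S[i, j] = (H @ C[i, j] @ H.T)[0, 0]
            S[i, i] += max(err_km[i] ** 2, 1e-12)
        ll += multivariate_normal.logpdf(obs_xy[:, ax], mean=mu, cov=S,
                                         allow_singular=True)
    return float(ll)


def brute_force_single_linkage(dist_matrix: np.ndarray, cut: float) -> list[set]:
    """Single-linkage clusters by transitive closure of the cut graph."""
    n = dist_matrix.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dist_matrix[i, j] <= cut:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: min(s))
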