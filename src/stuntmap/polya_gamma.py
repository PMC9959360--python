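"""Exact Pólya-Gamma PG(1, psi) sampling for logistic data augmentation.

If omega ~ PG(1, psi), a Bernoulli-logit likelihood becomes conditionally
Gaussian in the linear predictor, which is what turns the spatial
logistic model into a tractable Gibbs sampler.  Draws use Devroye's
alternating-series rejection sampler for the Jacobi J*(1, z) distribution
(PG(1, psi) = J*(1, psi/2)/4), which is exact and has acceptance
probability > 0.99 uniformly in psi.

The inner loop is scalar and compiled with numba; one call draws a whole
vector.  Determinism is per-call via an explicit integer seed feeding
numba's internal RNG.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_T = 0.64  # series switch point; Devroye's recommended value
_PI2_8 = np.pi**2 / 8.0


@njit(cache=True)
def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / np.sqrt(2.0)))


@njit(cache=True)
def _pigauss_cdf(t: float, z: float) -> float:
    """CDF at t of an inverse-Gaussian(mu=1/z, lambda=1); Levy limit at z=0."""
    if t <= 0.0:
        return 0.0
    rt = np.sqrt(t)
    if z <= 0.0:
        return 2.0 * _norm_cdf(-1.0 / rt)
    a = (t * z - 1.0) / rt
    b = -(t * z + 1.0) / rt
    # exp(2z) * Phi(b) can underflow/overflow in pieces; combine in logs
    val = _norm_cdf(a)
    if b > -37.0:
        val += np.exp(2.0 * z + np.log(_norm_cdf(b)))
    return val


@njit(cache=True)
def _rtigauss(z: float, t: float) -> float:
    """Inverse-Gaussian(mu=1/z, 1) truncated to (0, t]."""
    if z <= 0.0 or 1.0 / z > t:
        # mu > t: sample via truncated inverse-chi-square proposal
        while True:
            while True:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
                if e1 * e1 <= 2.0 * e2 / t:
                    break
            x = t / ((1.0 + t * e1) ** 2)
            if np.random.random() <= np.exp(-0.5 * z * z * x):
                return x
    mu = 1.0 / z
    while True:
        y = np.random.standard_normal() ** 2
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * np.sqrt(4.0 * mu * y + (mu * y) ** 2)
        if np.random.random() > mu / (mu + x):
            x = mu * mu / x
        if x <= t:
            return x


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    nph = n + 0.5
    if x <= _T:
        return np.pi * nph * (2.0 / (np.pi * x)) ** 1.5 * np.exp(-2.0 * nph * nph / x)
    return np.pi * nph * np.exp(-0.5 * nph * nph * np.pi * np.pi * x)


@njit(cache=True)
def _jacobi_draw(z: float) -> float:
    """One draw of J*(1, z), z >= 0 (Devroye)."""
    k = _PI2_8 + 0.5 * z * z
    p = (np.pi / (2.0 * k)) * np.exp(-k * _T)
    q = 2.0 * np.exp(-z) * _pigauss_cdf(_T, z)
    ratio = p / (p + q)
    while True:
        if np.random.random() < ratio:
            x = _T + np.random.exponential(1.0) / k
        else:
            x = _rtigauss(z, _T)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return x


@njit(cache=True)
def _pg_vector(psi: np.ndarray, seed: int) -> np.ndarray:
    np.random.seed(seed)
    out = np.empty(psi.shape[0])
    for i in range(psi.shape[0]):
        z = 0.5 * abs(psi[i])
        out[i] = 0.25 * _jacobi_draw(z)
    return out


def pg_draw(psi, seed: int) -> np.ndarray:
    """Vector of PG(1, psi_i) draws; `seed` must be a non-negative int < 2^32."""
    psi = np.ascontiguousarray(np.asarray(psi, dtype=float).ravel())
    return _pg_vector(psi, int(seed) % (2**32))


def pg_mean(psi) -> np.ndarray:
    """E[PG(1, psi)] = tanh(psi/2) / (2 psi), with the psi -> 0 limit 1/4."""
    psi = np.asarray(psi, dtype=float)
    out = np.full(psi.shape, 0.25)
    nz = np.abs(psi) > 1e-8
    out[nz] = np.tanh(psi[nz] / 2.0) / (2.0 * psi[nz])
    return out
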