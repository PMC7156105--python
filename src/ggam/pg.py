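"""Polya-Gamma random variates for logistic data augmentation.

A random variable omega ~ PG(b, z) has Laplace transform
E[exp(-omega t)] = cosh^b(z/2) / cosh^b(sqrt(z^2/2 + t) / sqrt(2)) and the
key identity used in binomial-logit Gibbs sampling:

    (e^eta)^y / (1 + e^eta)^n
      = 2^-n e^(kappa eta) E_omega[exp(-omega eta^2 / 2)],  kappa = y - n/2,

with omega ~ PG(n, 0).  Conditional on the data, omega | eta ~ PG(n, eta),
which makes the latent-liability layer Gaussian given omega.

PG(1, z) is drawn exactly by the alternating-series rejection sampler of
Devroye (tilted Jacobi distribution); PG(n, z) for integer n is the sum of
n independent PG(1, z) draws.  The kernels are numba-jitted; determinism is
obtained by seeding numba's thread-local legacy RNG per call.

Closed-form moments used by the test suite:
    E[PG(b, z)] = b / (2 z) * tanh(z / 2)     (b / 4 at z = 0).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["pg_mean", "sample_pg"]

_TRUNC = 0.64  # series crossover point t of the Devroye sampler


def pg_mean(b, z):
    """E[PG(b, z)] = b tanh(z/2) / (2 z), with the z -> 0 limit b/4."""
    b = np.asarray(b, dtype=float)
    z = np.asarray(z, dtype=float)
    out = np.where(
        np.abs(z) < 1e-8,
        b / 4.0 * (1.0 - z * z / 24.0),
        b / (2.0 * np.where(z == 0, 1.0, z)) * np.tanh(z / 2.0),
    )
    return out


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


@njit(cache=True)
def _pigauss(x, z):
    """CDF at x of InverseGaussian(mu=1/z, lambda=1); valid for z >= 0."""
    if x <= 0.0:
        return 0.0
    root = 1.0 / math.sqrt(x)
    a = _norm_cdf(root * (x * z - 1.0))
    ez = 2.0 * z
    # guard the exp for large z; the second term is then negligible anyway
    if ez > 600.0:
        return a
    b = math.exp(ez) * _norm_cdf(-root * (x * z + 1.0))
    return a + b


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of the alternating series for the Jacobi density."""
    npl = n + 0.5
    if x <= _TRUNC:
        return math.pi * npl * math.pow(2.0 / (math.pi * x), 1.5) * math.exp(
            -2.0 * npl * npl / x
        )
    return math.pi * npl * math.exp(-npl * npl * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _rtigauss(z, t):
    """Draw from InverseGaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    mu = 1.0 / z if z > 1e-12 else 1e12
    if mu > t:
        # small-z regime: one-sided rejection via truncated inverse-chi^2
        while True:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        while True:
            y = np.random.normal(0.0, 1.0)
            y = y * y
            x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(4.0 * mu * y + (mu * y) ** 2)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
            if x <= t:
                return x


@njit(cache=True)
def _pg1(z):
    """One exact PG(1, z) draw (Devroye alternating-series rejection)."""
    z = abs(z) * 0.5
    t = _TRUNC
    k = math.pi * math.pi / 8.0 + z * z / 2.0
    log_p_exp = math.log(math.pi / (2.0 * k)) - k * t
    p = math.exp(log_p_exp)
    q = 2.0 * math.exp(-z) * _pigauss(t, z)
    while True:
        if np.random.random() < p / (p + q):
            x = t + np.random.exponential(1.0) / k
        else:
            x = _rtigauss(z, t)
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
            return 0.25 * x


@njit(cache=True)
def _sample_pg_seeded(b, z, seed):
    np.random.seed(seed)
    out = np.empty(b.shape[0])
    for i in range(b.shape[0]):
        total = 0.0
        for _ in range(b[i]):
            total += _pg1(z[i])
        out[i] = total
    return out


def sample_pg(b, z, seed: int) -> np.ndarray:
    """Vectorised PG(b_i, z_i) draws for integer shapes b_i >= 0.

    ``seed`` seeds the jitted kernel's RNG, so a call is a pure function of
    its arguments.
    """
    b = np.ascontiguousarray(np.asarray(b, dtype=np.int64))
    z = np.ascontiguousarray(np.asarray(z, dtype=np.float64))
    if b.shape != z.shape:
        raise ValueError("b and z must have matching shapes")
    if (b < 0).any():
        raise ValueError("PG shape parameters must be nonnegative integers")
    if not np.all(np.isfinite(z)):
        raise ValueError("PG tilt parameters must be finite")
    return _sample_pg_seeded(b, z, np.int64(seed) % np.int64(2**32 - 1))
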