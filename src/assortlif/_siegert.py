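"""Numba core for the Siegert first-passage transfer function.

The stationary rate of an LIF neuron driven by Gaussian white current with
mean mu and variance sigma^2 is

    r = 1 / ( tau_ref + tau*sqrt(pi) * int_a^b exp(x^2)*(1+erf(x)) dx ),

with a=(V_reset-mu)/sigma, b=(theta-mu)/sigma.  The integrand equals
erfcx(-x), the scaled complementary error function, which is evaluated
without overflow: exp(x^2)*erfc(x) for moderate arguments, an asymptotic
series beyond, and the reflection erfcx(-x) = 2*exp(x^2) - erfcx(x) for
positive x.  The integral uses composite Gauss-Legendre panels sized to
the local steepness of exp(x^2), plus an analytic asymptotic tail for the
deep sub-threshold region x < -6.  For b > 8 the integral exceeds e^64 and
the rate is indistinguishable from zero in double precision.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT_PI = 1.7724538509055159
_B_CAP = 8.0
_ASYM_EDGE = 6.0

# 8-point Gauss-Legendre nodes/weights on [-1, 1]
_GL_X = np.array(
    [
        -0.9602898564975363,
        -0.7966664774136267,
        -0.525532409916329,
        -0.1834346424956498,
        0.1834346424956498,
        0.525532409916329,
        0.7966664774136267,
        0.9602898564975363,
    ]
)
_GL_W = np.array(
    [
        0.1012285362903763,
        0.2223810344533745,
        0.3137066458778873,
        0.3626837833783620,
        0.3626837833783620,
        0.3137066458778873,
        0.2223810344533745,
        0.1012285362903763,
    ]
)


@njit(cache=True, inline="always")
def _erfcx_pos(t: float) -> float:
    """erfcx(t) for t >= 0."""
    if t < _ASYM_EDGE:
        return math.exp(t * t) * math.erfc(t)
    inv2t2 = 1.0 / (2.0 * t * t)
    term = 1.0
    ssum = 1.0
    for n in range(1, 11):
        term *= -(2.0 * n - 1.0) * inv2t2
        ssum += term
    return ssum / (t * SQRT_PI)


@njit(cache=True, inline="always")
def _integrand(x: float) -> float:
    """erfcx(-x) = exp(x^2)*(1+erf(x))."""
    if x <= 0.0:
        return _erfcx_pos(-x)
    return 2.0 * math.exp(x * x) - _erfcx_pos(x)


@njit(cache=True, inline="always")
def _tail_antideriv(t: float) -> float:
    """Antiderivative of erfcx(t) for large t (asymptotic, t >= 6)."""
    # F(t) = (ln t + sum_{n>=1} (-1)^(n+1) (2n-1)!! / (2^n * 2n) * t^(-2n)) / sqrt(pi)
    inv_t2 = 1.0 / (t * t)
    acc = math.log(t)
    dfact = 1.0  # (2n-1)!!
    pw = 1.0  # (inv_t2 / 2)^n
    sgn = 1.0
    for n in range(1, 9):
        dfact *= 2.0 * n - 1.0
        pw *= 0.5 * inv_t2
        acc += sgn * dfact * pw / (2.0 * n)
        sgn = -sgn
    return acc / SQRT_PI


@njit(cache=True)
def siegert_integral(a: float, b: float) -> float:
    """int_a^b erfcx(-x) dx for a <= b <= _B_CAP."""
    total = 0.0
    lo = a
    if lo < -_ASYM_EDGE:
        hi_tail = min(b, -_ASYM_EDGE)
        # substitute t = -x: int erfcx(t) dt over [-hi_tail, -lo]
        total += _tail_antideriv(-lo) - _tail_antideriv(-hi_tail)
        lo = hi_tail
        if lo >= b:
            return total
    x = lo
    while x < b:
        if x < -2.0:
            w = 1.0
        elif x < 2.0:
            w = 0.5
        else:
            w = min(0.5, 2.0 / x)
        xr = min(x + w, b)
        half = 0.5 * (xr - x)
        mid = 0.5 * (xr + x)
        acc = 0.0
        for i in range(8):
            acc += _GL_W[i] * _integrand(mid + half * _GL_X[i])
        total += acc * half
        x = xr
    return total


@njit(cache=True, inline="always")
def siegert_rate_kernel(
    mu: float, sigma: float, tau: float, tau_ref: float, theta: float, v_reset: float
) -> float:
    """Stationary LIF rate in spikes/ms; sigma=0 falls back to the
    noiseless closed form."""
    if sigma <= 0.0:
        if mu <= theta:
            return 0.0
        return 1.0 / (tau_ref + tau * math.log((mu - v_reset) / (mu - theta)))
    b = (theta - mu) / sigma
    if b > _B_CAP:
        return 0.0  # rate below ~1e-26 spikes/ms
    a = (v_reset - mu) / sigma
    return 1.0 / (tau_ref + tau * SQRT_PI * siegert_integral(a, b))


@njit(cache=True)
def phi_coupled(
    counts,  # (K, K) joint degree matrix N_kk'
    rates,  # (K,) population rates in spikes/ms
    s: float,
    tau: float,
    tau_ref: float,
    theta: float,
    v_reset: float,
    J: float,
):
    """Coupled transfer function: out[k] = phi_k(rates, s) in spikes/ms.

    mu_k = J*tau*(nu_thr*s + sum_k' N_kk' r_k'), sigma_k^2 = J*mu_k.
    """
    K = rates.shape[0]
    out = np.empty(K)
    nu_thr = theta / (J * tau)
    for i in range(K):
        acc = 0.0
        for j in range(K):
            acc += counts[i, j] * rates[j]
        mu = J * tau * (nu_thr * s + acc)
        if mu <= 0.0:
            out[i] = 0.0
            continue
        sig = math.sqrt(J * mu)
        out[i] = siegert_rate_kernel(mu, sig, tau, tau_ref, theta, v_reset)
    return out


@njit(cache=True)
def scalar_mean_iteration(
    deg, pmf, s, tau, tau_ref, theta, v_reset, J, r0, tol, max_iter
):
    """Picard iteration for the one-dimensional mean-rate equation
    r = sum_k P(k) phi(J*tau*(nu_thr*s + k*r)); rates in spikes/ms."""
    nu_thr = theta / (J * tau)
    r = r0
    it = 0
    for it in range(max_iter):
        acc = 0.0
        for i in range(deg.shape[0]):
            mu = J * tau * (nu_thr * s + deg[i] * r)
            if mu <= 0.0:
                continue
            sig = math.sqrt(J * mu)
            acc += pmf[i] * siegert_rate_kernel(mu, sig, tau, tau_ref, theta, v_reset)
        if abs(acc - r) < tol:
            return acc, True, it
        r = acc
    return r, False, it
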