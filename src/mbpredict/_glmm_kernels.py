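"""Numba kernels for marginal likelihoods of count GLMMs.

Each family provides the per-observation log-likelihood l(η) and its
first two derivatives with respect to the mean-model linear predictor
η (μ = e^η).  Random intercepts b_g ~ N(0, σ²) are integrated out by a
Laplace approximation: per group,

    log ∫ e^{h(b)} db ≈ h(b̂) − ½ log(σ² H),   H = −h''(b̂),

where h(b) = Σ_{i∈g} l(η_i + b) − b²/(2σ²) (the additive normalizing
constants of the Gaussian prior and the Laplace integral cancel).  The
inner mode b̂ is found by damped Newton.  As σ² → 0 the expression
converges smoothly to the fixed-effects likelihood, which is how the
σ² = 0 boundary is handled.

Family codes: 0 = NB, 1 = zero-truncated NB, 2 = Bernoulli, 3 = ZINB
(zero-model linear predictor g per sample; random intercept in the mean
model only).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NB = 0
TRUNC_NB = 1
BERNOULLI = 2
ZINB = 3

_ETA_CLIP = 60.0


@njit(cache=True)
def _contrib(family, z, eta, theta, g):
    """(l, dl/dη, d²l/dη²) for one observation."""
    if eta > _ETA_CLIP:
        eta = _ETA_CLIP
    elif eta < -_ETA_CLIP:
        eta = -_ETA_CLIP
    if family == BERNOULLI:
        if eta > 0.0:
            p = 1.0 / (1.0 + math.exp(-eta))
            l = z * eta - (eta + math.log1p(math.exp(-eta)))
        else:
            e = math.exp(eta)
            p = e / (1.0 + e)
            l = z * eta - math.log1p(e)
        return l, z - p, -p * (1.0 - p)

    mu = math.exp(eta)
    tpm = theta + mu
    lnb = (
        math.lgamma(z + theta)
        - math.lgamma(theta)
        - math.lgamma(z + 1.0)
        + theta * (math.log(theta) - math.log(tpm))
        + z * (eta - math.log(tpm))
    )
    l1 = z - (z + theta) * mu / tpm
    l2 = -(z + theta) * theta * mu / (tpm * tpm)

    if family == NB:
        return lnb, l1, l2

    lp0 = theta * (math.log(theta) - math.log(tpm))  # log P(Z=0)
    p0 = math.exp(lp0)
    a = -theta * mu / tpm  # d log p0 / dη
    da = -theta * theta * mu / (tpm * tpm)

    if family == TRUNC_NB:
        om = 1.0 - p0
        if om < 1e-12:
            om = 1e-12
        l = lnb - math.log(om)
        corr1 = p0 * a / om
        corr2 = (p0 * (a * a + da) * om + (p0 * a) * (p0 * a)) / (om * om)
        return l, l1 + corr1, l2 + corr2

    # ZINB: φ from the zero-model predictor g
    if g > 0.0:
        phi = 1.0 / (1.0 + math.exp(-g))
        log1mphi = -(g + math.log1p(math.exp(-g)))
    else:
        e = math.exp(g)
        phi = e / (1.0 + e)
        log1mphi = -math.log1p(e)
    if z > 0:
        return log1mphi + lnb, l1, l2
    D = phi + (1.0 - phi) * p0
    if D < 1e-300:
        D = 1e-300
    u = (1.0 - phi) * p0 * a
    l = math.log(D)
    l1z = u / D
    l2z = ((1.0 - phi) * (p0 * a * a + p0 * da) * D - u * u) / (D * D)
    return l, l1z, l2z


@njit(cache=True)
def _sums(family, z, eta, gz, theta, b, i0, i1):
    s0 = 0.0
    s1 = 0.0
    s2 = 0.0
    for i in range(i0, i1):
        l, l1, l2 = _contrib(family, z[i], eta[i] + b, theta, gz[i])
        s0 += l
        s1 += l1
        s2 += l2
    return s0, s1, s2


@njit(cache=True)
def _loglik_only(family, z, eta, gz, theta, b, i0, i1):
    s0 = 0.0
    for i in range(i0, i1):
        l, _, _ = _contrib(family, z[i], eta[i] + b, theta, gz[i])
        s0 += l
    return s0


@njit(cache=True)
def _group_laplace(family, z, eta, gz, theta, sigma2, i0, i1):
    """Laplace-approximate marginal log-likelihood of one group."""
    b = 0.0
    h = _loglik_only(family, z, eta, gz, theta, b, i0, i1)
    s2 = 0.0
    for _ in range(60):
        s0, s1, s2 = _sums(family, z, eta, gz, theta, b, i0, i1)
        h = s0 - b * b / (2.0 * sigma2)
        h1 = s1 - b / sigma2
        h2 = s2 - 1.0 / sigma2
        if h2 > -1e-12:
            h2 = -1e-6
        step = -h1 / h2
        if abs(step) < 1e-11 * (1.0 + abs(b)):
            break
        # damped update: keep h non-decreasing
        new_b = b + step
        new_h = _loglik_only(family, z, eta, gz, theta, new_b, i0, i1) - new_b * new_b / (2.0 * sigma2)
        n_half = 0
        while new_h < h - 1e-12 and n_half < 15:
            step *= 0.5
            new_b = b + step
            new_h = _loglik_only(family, z, eta, gz, theta, new_b, i0, i1) - new_b * new_b / (2.0 * sigma2)
            n_half += 1
        if new_h < h - 1e-12:
            break
        b = new_b
        h = new_h
    s0, s1, s2 = _sums(family, z, eta, gz, theta, b, i0, i1)
    h = s0 - b * b / (2.0 * sigma2)
    H = 1.0 / sigma2 - s2
    if H < 1e-12:
        H = 1e-12
    return h - 0.5 * math.log(sigma2 * H)


@njit(cache=True)
def marginal_nll(family, z, eta, gz, theta, sigma2, group_start, use_random):
    """Negative (Laplace-approximate) marginal log-likelihood.

    Samples must be ordered so that group g occupies the slice
    group_start[g]:group_start[g+1] when ``use_random``.
    """
    if not use_random:
        total = _loglik_only(family, z, eta, gz, theta, 0.0, 0, len(z))
        return -total
    total = 0.0
    for g in range(len(group_start) - 1):
        total += _group_laplace(family, z, eta, gz, theta, sigma2, group_start[g], group_start[g + 1])
    return -total


@njit(cache=True)
def conditional_modes(family, z, eta, gz, theta, sigma2, group_start):
    """Conditional modes b̂_g of the random intercepts at given parameters."""
    n_groups = len(group_start) - 1
    modes = np.zeros(n_groups)
    for g in range(n_groups):
        i0, i1 = group_start[g], group_start[g + 1]
        b = 0.0
        for _ in range(60):
            s0, s1, s2 = _sums(family, z, eta, gz, theta, b, i0, i1)
            h2 = s2 - 1.0 / sigma2
            if h2 > -1e-12:
                h2 = -1e-6
            step = -(s1 - b / sigma2) / h2
            if abs(step) < 1e-11 * (1.0 + abs(b)):
                break
            b += step
        modes[g] = b
    return modes


@njit(cache=True)
def _digamma(x):
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    return r + math.log(x) - 0.5 * inv - inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0))


@njit(cache=True)
def _derivs(family, z, eta, theta, g):
    """Full derivative bundle for one observation.

    Returns (l, l_η, l_ηη, l_ηηη, l_θ, l_ηθ, l_ηηθ, l_g, l_ηg, l_ηηg);
    entries that do not apply to the family are zero.
    """
    if eta > _ETA_CLIP:
        eta = _ETA_CLIP
    elif eta < -_ETA_CLIP:
        eta = -_ETA_CLIP
    if family == BERNOULLI:
        if eta > 0.0:
            p = 1.0 / (1.0 + math.exp(-eta))
            l = z * eta - (eta + math.log1p(math.exp(-eta)))
        else:
            e = math.exp(eta)
            p = e / (1.0 + e)
            l = z * eta - math.log1p(e)
        pq = p * (1.0 - p)
        return l, z - p, -pq, -pq * (1.0 - 2.0 * p), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0

    mu = math.exp(eta)
    T = theta + mu
    lnb = (
        math.lgamma(z + theta)
        - math.lgamma(theta)
        - math.lgamma(z + 1.0)
        + theta * (math.log(theta) - math.log(T))
        + z * (eta - math.log(T))
    )
    l1 = z - (z + theta) * mu / T
    l2 = -(z + theta) * theta * mu / (T * T)
    l3 = -(z + theta) * theta * mu * (T - 2.0 * mu) / (T * T * T)
    lt = (_digamma(z + theta) - _digamma(theta) + math.log(theta) - math.log(T)
          + 1.0 - theta / T - z / T)
    l1t = mu * (z - mu) / (T * T)
    l2t = -mu * ((z + 2.0 * theta) * T - 2.0 * theta * (z + theta)) / (T * T * T)

    if family == NB:
        return lnb, l1, l2, l3, lt, l1t, l2t, 0.0, 0.0, 0.0

    # shared zero-probability machinery
    lp0 = theta * (math.log(theta) - math.log(T))
    p0 = math.exp(lp0)
    a = -theta * mu / T                      # d log p0 / dη
    a_e = -theta * theta * mu / (T * T)      # ∂a/∂η
    a_ee = -theta * theta * mu * (T - 2.0 * mu) / (T * T * T)  # ∂²a/∂η²
    at = math.log(theta) - math.log(T) + 1.0 - theta / T       # ∂ log p0/∂θ
    a_t = -mu * mu / (T * T)                 # ∂a/∂θ
    a_et = -2.0 * theta * mu * mu / (T * T * T)  # ∂a_e/∂θ

    if family == TRUNC_NB:
        om = 1.0 - p0
        if om < 1e-12:
            om = 1e-12
        r = p0 / om
        c = -math.log(om)
        r_e = r * a * (1.0 + r)
        r_t = r * at * (1.0 + r)
        c_e = r * a
        c_ee = r * a * a * (1.0 + r) + r * a_e
        c_eee = (r_e * (a * a * (1.0 + r) + a_e)
                 + r * (2.0 * a * a_e * (1.0 + r) + a * a * r_e + a_ee))
        c_t = r * at
        c_et = r_t * a + r * a_t
        c_eet = (r_t * a * a * (1.0 + r) + 2.0 * r * a * a_t * (1.0 + r)
                 + r * a * a * r_t + r_t * a_e + r * a_et)
        return (lnb + c, l1 + c_e, l2 + c_ee, l3 + c_eee,
                lt + c_t, l1t + c_et, l2t + c_eet, 0.0, 0.0, 0.0)

    # ZINB
    if g > 0.0:
        phi = 1.0 / (1.0 + math.exp(-g))
        log1mphi = -(g + math.log1p(math.exp(-g)))
    else:
        e = math.exp(g)
        phi = e / (1.0 + e)
        log1mphi = -math.log1p(e)
    if z > 0:
        return (log1mphi + lnb, l1, l2, l3, lt, l1t, l2t, -phi, 0.0, 0.0)
    F = (1.0 - phi) * p0
    D = phi + F
    if D < 1e-300:
        D = 1e-300
    F1 = F * a
    F2 = F * (a * a + a_e)
    F3 = F * (a * a * a + 3.0 * a * a_e + a_ee)
    Ft = F * at
    F1t = F * (at * a + a_t)
    F2t = F * (at * (a * a + a_e) + 2.0 * a * a_t + a_et)
    phig = phi * (1.0 - phi)
    Dg = phig * (1.0 - p0)
    Fg = -phig * p0
    F1g = -phig * p0 * a
    F2g = -phig * p0 * (a * a + a_e)
    l = math.log(D)
    q1 = F1 / D
    q2 = F2 / D - q1 * q1
    q3 = F3 / D - 3.0 * F1 * F2 / (D * D) + 2.0 * q1 * q1 * q1
    lt_z = Ft / D
    l1t_z = F1t / D - F1 * Ft / (D * D)
    l2t_z = (F2t / D - F2 * Ft / (D * D) - 2.0 * F1 * F1t / (D * D)
             + 2.0 * F1 * F1 * Ft / (D * D * D))
    lg = Dg / D
    l1g = F1g / D - F1 * Dg / (D * D)
    l2g = (F2g / D - F2 * Dg / (D * D) - 2.0 * F1 * F1g / (D * D)
           + 2.0 * F1 * F1 * Dg / (D * D * D))
    return l, q1, q2, q3, lt_z, l1t_z, l2t_z, lg, l1g, l2g


@njit(cache=True)
def nll_and_grad(family, z, X, offset, Z0, beta, gamma, theta, sigma2,
                 group_start, use_random, has_theta, b_cache):
    """Negative marginal log-likelihood and its exact gradient.

    Gradient order: β (p), γ (q, ZINB only), log θ (if the family has a
    dispersion), log σ² (if ``use_random``).  The Laplace gradient is
    exact: the envelope term at the inner mode plus the implicit
    derivative of the −½ log(σ²H) correction through the mode.
    ``b_cache`` carries per-group modes across evaluations (warm
    starts); it is updated in place.
    """
    n, p = X.shape
    q = Z0.shape[1]
    n_par = p + q + (1 if has_theta else 0) + (1 if use_random else 0)
    grad = np.zeros(n_par)
    eta = np.empty(n)
    gz = np.empty(n)
    for i in range(n):
        s = offset[i]
        for j in range(p):
            s += X[i, j] * beta[j]
        eta[i] = s
        s2 = 0.0
        for j in range(q):
            s2 += Z0[i, j] * gamma[j]
        gz[i] = s2

    if not use_random:
        total = 0.0
        st = 0.0
        for i in range(n):
            l, l1, _, _, lt, _, _, lg, _, _ = _derivs(family, z[i], eta[i], theta, gz[i])
            total += l
            for j in range(p):
                grad[j] += l1 * X[i, j]
            for j in range(q):
                grad[p + j] += lg * Z0[i, j]
            st += lt
        if has_theta:
            grad[p + q] = theta * st
        return -total, -grad

    total = 0.0
    it = p + q  # index of log-theta entry
    iv = n_par - 1  # index of log-sigma2 entry
    for gidx in range(len(group_start) - 1):
        i0, i1 = group_start[gidx], group_start[gidx + 1]
        # damped Newton for the mode, warm-started from the cache
        b = b_cache[gidx]
        h = -1e300
        for _ in range(80):
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            for i in range(i0, i1):
                l, l1, l2, _, _, _, _, _, _, _ = _derivs(family, z[i], eta[i] + b, theta, gz[i])
                s0 += l
                s1 += l1
                s2 += l2
            h = s0 - b * b / (2.0 * sigma2)
            h1 = s1 - b / sigma2
            h2 = s2 - 1.0 / sigma2
            if h2 > -1e-12:
                h2 = -1e-6
            step = -h1 / h2
            if abs(step) < 1e-11 * (1.0 + abs(b)):
                break
            new_b = b + step
            new_h = _loglik_only(family, z, eta, gz, theta, new_b, i0, i1) - new_b * new_b / (2.0 * sigma2)
            n_half = 0
            while new_h < h - 1e-12 and n_half < 20:
                step *= 0.5
                new_b = b + step
                new_h = _loglik_only(family, z, eta, gz, theta, new_b, i0, i1) - new_b * new_b / (2.0 * sigma2)
                n_half += 1
            if new_h < h - 1e-12:
                break
            b = new_b
            h = new_h
        b_cache[gidx] = b

        # accumulate the derivative bundle at the mode
        S0 = 0.0
        S2 = 0.0
        S3 = 0.0
        St = 0.0
        S1t = 0.0
        S2t = 0.0
        S1x = np.zeros(p)
        S2x = np.zeros(p)
        S3x = np.zeros(p)
        SGg = np.zeros(q)
        S1g = np.zeros(q)
        S2g = np.zeros(q)
        for i in range(i0, i1):
            l, l1, l2, l3, lt, l1t, l2t, lg, l1g, l2g = _derivs(family, z[i], eta[i] + b, theta, gz[i])
            S0 += l
            S2 += l2
            S3 += l3
            St += lt
            S1t += l1t
            S2t += l2t
            for j in range(p):
                xij = X[i, j]
                S1x[j] += l1 * xij
                S2x[j] += l2 * xij
                S3x[j] += l3 * xij
            for j in range(q):
                zij = Z0[i, j]
                SGg[j] += lg * zij
                S1g[j] += l1g * zij
                S2g[j] += l2g * zij
        H = 1.0 / sigma2 - S2
        if H < 1e-12:
            H = 1e-12
        total += S0 - b * b / (2.0 * sigma2) - 0.5 * math.log(sigma2 * H)
        for j in range(p):
            bdot = S2x[j] / H
            dH = -S3x[j] - S3 * bdot
            grad[j] += S1x[j] - 0.5 * dH / H
        for j in range(q):
            bdot = S1g[j] / H
            dH = -S2g[j] - S3 * bdot
            grad[p + j] += SGg[j] - 0.5 * dH / H
        if has_theta:
            bdot = theta * S1t / H
            dH = -theta * S2t - S3 * bdot
            grad[it] += theta * St - 0.5 * dH / H
        bdot = (b / sigma2) / H
        dH = -1.0 / sigma2 - S3 * bdot
        grad[iv] += b * b / (2.0 * sigma2) - 0.5 - 0.5 * dH / H
    return -total, -grad
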