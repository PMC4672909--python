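"""Fused numerical kernels for the Monte-Carlo response likelihood.

These replicate the vectorized numpy path in :mod:`fitting`
sample-for-sample, but fuse the whole generative pass (sensory sampling,
segregated/fused posterior means, causal posterior, bin assignment) into
one loop, removing the temporaries that dominate the numpy version's
cost.  Within one kernel call the measurement SD is constant, so each
prior is first *projected* against that SD: every mixture component k
reduces to four constants (posterior-mean coefficients a_k, b_k and
log-evidence coefficients c0_k, c1_k), leaving the single-component hot
path free of transcendentals.  The numpy implementation remains the
reference; a unit test asserts agreement.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)
_SQRT_2PI = math.sqrt(2.0 * math.pi)
_EMPTY = np.zeros(1)


def pack_prior(prior) -> tuple:
    """PriorSpec -> (kind flag, weights, means, sds, flat halfwidth)."""
    if prior.is_flat:
        return 0, _EMPTY + 1.0, _EMPTY, _EMPTY + 1.0, float(prior.support_halfwidth)
    w, m, t = prior.components()
    return (
        1,
        np.ascontiguousarray(w, float),
        np.ascontiguousarray(m, float),
        np.ascontiguousarray(t, float),
        0.0,
    )


def project_prior(pack: tuple, sigma: float) -> tuple:
    """Fold a packed prior and a fixed measurement SD into kernel constants.

    Returns ``(kind, inv_sigma, halfwidth, logc, m, a, b, c0, c1)`` where,
    for mixture component k with predictive variance pv = sigma^2 + t_k^2:
    posterior mean = a_k x + b_k, component log evidence =
    c0_k - c1_k (x - m_k)^2.  For the flat prior only the truncation
    geometry is needed.
    """
    kind, w, m, t, h = pack
    if kind == 0:
        return (0, 1.0 / sigma, h, -math.log(2.0 * h), _EMPTY, _EMPTY, _EMPTY, _EMPTY, _EMPTY)
    var = sigma * sigma
    tv = t * t
    pv = var + tv
    a = tv / pv
    b = m * var / pv
    c0 = np.log(w) - 0.5 * np.log(pv) - _LOG_SQRT_2PI
    c1 = 0.5 / pv
    return (1, 0.0, 0.0, 0.0, m, a, b, c0, c1)


@njit(cache=True, inline="always")
def _erf_fast(x):
    """erf to |error| < 1.5e-7 (Abramowitz & Stegun 7.1.26); libm erf is
    several times slower and the likelihood is insensitive at this scale."""
    s = 1.0 if x >= 0.0 else -1.0
    ax = x if x >= 0.0 else -x
    t = 1.0 / (1.0 + 0.3275911 * ax)
    y = 1.0 - (
        ((((1.061405429 * t - 1.453152027) * t) + 1.421413741) * t - 0.284496736) * t
        + 0.254829592
    ) * t * math.exp(-ax * ax)
    return s * y


@njit(cache=True, inline="always")
def _post1(x, kind, inv_sigma, h, logc, m, a, b, c0, c1):
    """Posterior mean and log evidence for one measurement (scalar)."""
    if kind == 0:
        alpha = (-h - x) * inv_sigma
        beta = (h - x) * inv_sigma
        if alpha < -7.0 and beta > 7.0:
            # truncation negligible: posterior is the raw likelihood
            return x, logc
        z = 0.5 * (_erf_fast(beta / _SQRT2) - _erf_fast(alpha / _SQRT2))
        if z < 1e-300:
            z = 1e-300
        phi_a = math.exp(-0.5 * alpha * alpha) / _SQRT_2PI
        phi_b = math.exp(-0.5 * beta * beta) / _SQRT_2PI
        mean = x + (phi_a - phi_b) / (z * inv_sigma)
        return mean, math.log(z) + logc
    K = m.shape[0]
    if K == 1:
        d = x - m[0]
        return a[0] * x + b[0], c0[0] - c1[0] * d * d
    best = -1.0e308
    for k in range(K):
        d = x - m[k]
        lev = c0[k] - c1[k] * d * d
        if lev > best:
            best = lev
    s = 0.0
    ms = 0.0
    for k in range(K):
        d = x - m[k]
        e = math.exp(c0[k] - c1[k] * d * d - best)
        s += e
        ms += e * (a[k] * x + b[k])
    return ms / s, best + math.log(s)


@njit(cache=True, inline="always")
def _bin90(r):
    """0.1-degree quantization, then the 1-degree bin on [-45, 45]."""
    rq = round(r * 10.0) / 10.0
    idx = int(math.floor(rq + 45.0))
    if idx < 0:
        idx = 0
    elif idx > 89:
        idx = 89
    return idx


@njit(cache=True)
def bisensory_bin_weights(
    muA,
    sdA,
    muV,
    sdV,
    zA,
    zV,
    p_common,
    sigma_A,
    sigma_V,
    kV,
    iV,
    hV,
    lV,
    mV,
    aV,
    bV,
    c0V,
    c1V,
    kA,
    iA,
    hA,
    lA,
    mA,
    aA,
    bA,
    c0A,
    c1A,
    k1,
    i1,
    h1,
    l1,
    m1,
    a1,
    b1,
    c01,
    c11,
    counts,
):
    """Accumulate xi-marginalized joint-bin weights for all bisensory conditions."""
    C = muA.shape[0]
    n = zA.shape[0]
    precA = 1.0 / (sigma_A * sigma_A)
    precV = 1.0 / (sigma_V * sigma_V)
    prec = precA + precV
    pair_var = sigma_A * sigma_A + sigma_V * sigma_V
    lpair_const = -0.5 * math.log(pair_var) - _LOG_SQRT_2PI
    inv_2pair = 0.5 / pair_var
    if p_common >= 1.0:
        lp0 = 1.0e308
    elif p_common <= 0.0:
        lp0 = -1.0e308
    else:
        lp0 = math.log(p_common) - math.log1p(-p_common)
    for c in range(C):
        base = c * 8100
        mA_c = muA[c]
        mV_c = muV[c]
        sV_c = sdV[c]
        for i in range(n):
            xA = mA_c + sdA * zA[i]
            xV = mV_c + sV_c * zV[i]
            segA, levA = _post1(xA, kA, iA, hA, lA, mA, aA, bA, c0A, c1A)
            segV, levV = _post1(xV, kV, iV, hV, lV, mV, aV, bV, c0V, c1V)
            xbar = (xA * precA + xV * precV) / prec
            fus, lev1 = _post1(xbar, k1, i1, h1, l1, m1, a1, b1, c01, c11)
            d = xA - xV
            logit = lp0 + lpair_const - d * d * inv_2pair + lev1 - levA - levV
            if logit > 700.0:
                p1 = 1.0
            elif logit < -700.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + math.exp(-logit))
            bF = _bin90(fus)
            counts[base + _bin90(segA) * 90 + _bin90(segV)] += 1.0 - p1
            counts[base + bF * 91] += p1


@njit(cache=True)
def unisensory_bin_counts(mu, sd, z, kind, inv_sigma, h, logc, m, a, b, c0, c1, counts):
    """Accumulate 1-D bin counts for a batch of unisensory conditions."""
    C = mu.shape[0]
    n = z.shape[0]
    for c in range(C):
        base = c * 90
        mu_c = mu[c]
        sd_c = sd[c]
        for i in range(n):
            x = mu_c + sd_c * z[i]
            r, _ = _post1(x, kind, inv_sigma, h, logc, m, a, b, c0, c1)
            counts[base + _bin90(r)] += 1.0
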