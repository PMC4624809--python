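"""Numba kernels: Wiener first-passage-time density and trial log-likelihood.

The density of the first passage of a drift diffusion (drift v, boundary
separation a, relative start w = z/a, diffusion scale s = 1) through the
lower boundary factorises into a drift-dependent exponential and a
drift-free infinite series with two equivalent representations — one that
converges quickly for small normalized time and one for large. Following
the usual dual-series scheme, the representation needing fewer terms for
the requested truncation error is chosen per evaluation.

Between-trial drift variability (normal with sd ``sv``) is integrated out
in closed form; between-trial non-decision-time variability (uniform of
width ``st``) is handled by midpoint quadrature.
"""

import math

import numpy as np
from numba import njit

SQRT_2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def wfpt_series(tt, w, err):
    """Drift-free part of the lower-boundary density at normalized time tt.

    tt = t / a^2; returns f0 such that the density is
    f0 * exp(-v*a*w - v^2*t/2) / a^2. Truncation error below *err*.
    """
    if tt <= 0.0:
        return 0.0
    # number of terms needed by each representation
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    if 2.0 * SQRT_2PI * math.sqrt(tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * SQRT_2PI * math.sqrt(tt) * err))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -int(math.floor((K - 1) / 2.0))
        hi = int(math.ceil((K - 1) / 2.0))
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-wk * wk / (2.0 * tt))
        p /= SQRT_2PI * tt * math.sqrt(tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(
                k * math.pi * w
            )
        p *= math.pi
    return p


@njit(cache=True)
def wfpt_density_lower(t_dec, v, a, w, sv, err):
    """Lower-boundary first-passage density at decision time t_dec.

    With sv > 0 the normal between-trial drift distribution is integrated
    out analytically.
    """
    if t_dec <= 0.0 or a <= 0.0:
        return 0.0
    tt = t_dec / (a * a)
    f0 = wfpt_series(tt, w, err)
    if f0 <= 0.0:
        return 0.0
    if sv > 0.0:
        s2t = sv * sv * t_dec
        expo = (a * w * sv * a * w * sv - 2.0 * a * w * v - v * v * t_dec) / (
            2.0 * (1.0 + s2t)
        )
        return f0 * math.exp(expo) / (a * a * math.sqrt(1.0 + s2t))
    return f0 * math.exp(-v * a * w - v * v * t_dec / 2.0) / (a * a)


@njit(cache=True)
def wfpt_density(t_dec, v, a, w, upper, sv, err):
    """First-passage density at the chosen boundary (upper via reflection)."""
    if upper:
        return wfpt_density_lower(t_dec, -v, a, 1.0 - w, sv, err)
    return wfpt_density_lower(t_dec, v, a, w, sv, err)


@njit(cache=True)
def trial_loglik(rt, upper, v, a, t_nd, sv, st, n_quad, err):
    """Log density of one trial's (rt, boundary) under the full DDM.

    Non-decision-time variability integrates a uniform of width st by
    midpoint quadrature with n_quad nodes. Returns -inf when the density
    is zero (e.g. rt <= t_nd with st = 0).
    """
    w = 0.5  # start point fixed midway (no response bias)
    if st <= 1e-12:
        d = wfpt_density(rt - t_nd, v, a, w, upper, sv, err)
    else:
        d = 0.0
        h = st / n_quad
        t0 = t_nd - st / 2.0
        for q in range(n_quad):
            tq = t0 + (q + 0.5) * h
            d += wfpt_density(rt - tq, v, a, w, upper, sv, err)
        d /= n_quad
    if d <= 0.0:
        return -np.inf
    return math.log(d)


@njit(cache=True)
def block_loglik(rts, uppers, i0, i1, v, a, t_nd, sv, st, n_quad, err):
    """Summed log-likelihood of the trial slice [i0, i1)."""
    total = 0.0
    for i in range(i0, i1):
        ll = trial_loglik(rts[i], uppers[i] == 1, v, a, t_nd, sv, st, n_quad, err)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total
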