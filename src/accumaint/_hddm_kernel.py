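"""Numba kernel running one MCMC chain of the hierarchical DDM.

Sampling scheme: adaptive Metropolis-within-Gibbs. Subject-level drift
rates (normal hierarchy), log boundary separations and log non-decision
times (log-normal hierarchies) move by random-walk Metropolis steps whose
scales adapt toward a 44% acceptance rate during burn-in and are frozen
afterwards. Group means and variances are conjugate normal /
inverse-gamma Gibbs draws. The group-level between-trial variabilities
sv (drift) and st (non-decision time) move by reflective random walks on
[0, inf) under half-normal priors.
"""

import math

import numpy as np
from numba import njit

from ._wfpt import block_loglik

# weakly-informative hyperpriors
MU_PRIOR_VAR = 100.0   # N(0, 10^2) on group means (raw or log scale)
VAR_PRIOR_A = 1.0      # inverse-gamma shape on group variances
VAR_PRIOR_B = 0.01     # inverse-gamma rate
SV_PRIOR_SD = 2.0      # half-normal sd on sv
ST_PRIOR_SD = 0.25     # half-normal sd on st


@njit(cache=True)
def _cell_ll(rts, uppers, start, end, j, l, vmap, amap, v, la, lt, sv, st, nq, err):
    return block_loglik(
        rts, uppers, start[j, l], end[j, l],
        v[j, vmap[l]], math.exp(la[j, amap[l]]), math.exp(lt[j]),
        sv, st, nq, err,
    )


@njit(cache=True)
def run_chain(
    rts, uppers, start, end, vmap, amap, n_lv, n_la,
    v0, la0, lt0, sv0, st0,
    n_burn, n_keep, thin, seed, nq, err,
):
    np.random.seed(seed)
    J = start.shape[0]
    L = 4

    v = v0.copy()
    la = la0.copy()
    lt = lt0.copy()
    sv = sv0
    st = st0
    mu_v = np.zeros(n_lv)
    sd_v = np.zeros(n_lv)
    for k in range(n_lv):
        mu_v[k] = v[:, k].mean()
        sd_v[k] = max(v[:, k].std() + 1e-3, 0.05)
    mu_la = np.zeros(n_la)
    sd_la = np.zeros(n_la)
    for k in range(n_la):
        mu_la[k] = la[:, k].mean()
        sd_la[k] = max(la[:, k].std() + 1e-3, 0.05)
    mu_lt = lt.mean()
    sd_lt = max(lt.std() + 1e-3, 0.05)

    # log-likelihood cache per subject x level
    ll = np.zeros((J, L))
    for j in range(J):
        for l in range(L):
            ll[j, l] = _cell_ll(rts, uppers, start, end, j, l, vmap, amap,
                                v, la, lt, sv, st, nq, err)

    # proposal scales and acceptance counters
    sc_v = np.full((J, n_lv), 0.25)
    sc_la = np.full((J, n_la), 0.10)
    sc_lt = np.full(J, 0.05)
    sc_sv = 0.15
    sc_st = 0.03
    ac_v = np.zeros((J, n_lv))
    ac_la = np.zeros((J, n_la))
    ac_lt = np.zeros(J)
    ac_sv = 0.0
    ac_st = 0.0
    ADAPT_WIN = 50

    n_group = 2 * n_lv + 2 * n_la + 4
    n_params = n_group + J * n_lv + J * n_la + J
    chains = np.zeros((n_keep, n_params))
    deviance = np.zeros(n_keep)

    n_iter = n_burn + n_keep * thin
    kept = 0
    new_ll = np.zeros(L)

    for it in range(n_iter):
        # --- subject drift rates ---
        for j in range(J):
            for k in range(n_lv):
                prop = v[j, k] + sc_v[j, k] * np.random.standard_normal()
                logr = (
                    -0.5 * ((prop - mu_v[k]) ** 2 - (v[j, k] - mu_v[k]) ** 2)
                    / (sd_v[k] * sd_v[k])
                )
                old = v[j, k]
                v[j, k] = prop
                ok = True
                for l in range(L):
                    if vmap[l] == k:
                        nl = _cell_ll(rts, uppers, start, end, j, l, vmap, amap,
                                      v, la, lt, sv, st, nq, err)
                        new_ll[l] = nl
                        if nl == -np.inf:
                            ok = False
                            break
                        logr += nl - ll[j, l]
                if ok and math.log(np.random.random()) < logr:
                    for l in range(L):
                        if vmap[l] == k:
                            ll[j, l] = new_ll[l]
                    ac_v[j, k] += 1.0
                else:
                    v[j, k] = old

        # --- subject log boundary separations ---
        for j in range(J):
            for k in range(n_la):
                prop = la[j, k] + sc_la[j, k] * np.random.standard_normal()
                logr = (
                    -0.5 * ((prop - mu_la[k]) ** 2 - (la[j, k] - mu_la[k]) ** 2)
                    / (sd_la[k] * sd_la[k])
                )
                old = la[j, k]
                la[j, k] = prop
                ok = True
                for l in range(L):
                    if amap[l] == k:
                        nl = _cell_ll(rts, uppers, start, end, j, l, vmap, amap,
                                      v, la, lt, sv, st, nq, err)
                        new_ll[l] = nl
                        if nl == -np.inf:
                            ok = False
                            break
                        logr += nl - ll[j, l]
                if ok and math.log(np.random.random()) < logr:
                    for l in range(L):
                        if amap[l] == k:
                            ll[j, l] = new_ll[l]
                    ac_la[j, k] += 1.0
                else:
                    la[j, k] = old

        # --- subject log non-decision times ---
        for j in range(J):
            prop = lt[j] + sc_lt[j] * np.random.standard_normal()
            logr = -0.5 * ((prop - mu_lt) ** 2 - (lt[j] - mu_lt) ** 2) / (sd_lt * sd_lt)
            old = lt[j]
            lt[j] = prop
            ok = True
            for l in range(L):
                nl = _cell_ll(rts, uppers, start, end, j, l, vmap, amap,
                              v, la, lt, sv, st, nq, err)
                new_ll[l] = nl
                if nl == -np.inf:
                    ok = False
                    break
                logr += nl - ll[j, l]
            if ok and math.log(np.random.random()) < logr:
                for l in range(L):
                    ll[j, l] = new_ll[l]
                ac_lt[j] += 1.0
            else:
                lt[j] = old

        # --- group-level sv then st (reflective walk, half-normal prior);
        # five sub-updates each, since these global moves dominate the
        # autocorrelation of the chain ---
        for rep in range(10):
            which = rep % 2
            if which == 0:
                prop = abs(sv + sc_sv * np.random.standard_normal())
                logr = -0.5 * (prop * prop - sv * sv) / (SV_PRIOR_SD * SV_PRIOR_SD)
                sv_new, st_new = prop, st
            else:
                prop = abs(st + sc_st * np.random.standard_normal())
                logr = -0.5 * (prop * prop - st * st) / (ST_PRIOR_SD * ST_PRIOR_SD)
                sv_new, st_new = sv, prop
            total_new = 0.0
            ok = True
            tmp = np.zeros((J, L))
            for j in range(J):
                if not ok:
                    break
                for l in range(L):
                    nl = _cell_ll(rts, uppers, start, end, j, l, vmap, amap,
                                  v, la, lt, sv_new, st_new, nq, err)
                    tmp[j, l] = nl
                    if nl == -np.inf:
                        ok = False
                        break
                    total_new += nl
            if ok:
                logr += total_new - ll.sum()
                if math.log(np.random.random()) < logr:
                    ll = tmp
                    if which == 0:
                        sv = sv_new
                        ac_sv += 1.0
                    else:
                        st = st_new
                        ac_st += 1.0

        # --- conjugate group updates ---
        for k in range(n_lv):
            prec = J / (sd_v[k] * sd_v[k]) + 1.0 / MU_PRIOR_VAR
            mean = (v[:, k].sum() / (sd_v[k] * sd_v[k])) / prec
            mu_v[k] = mean + np.random.standard_normal() / math.sqrt(prec)
            s = 0.0
            for j in range(J):
                s += (v[j, k] - mu_v[k]) ** 2
            g = np.random.gamma(VAR_PRIOR_A + J / 2.0)
            sd_v[k] = math.sqrt((VAR_PRIOR_B + s / 2.0) / g)
        for k in range(n_la):
            prec = J / (sd_la[k] * sd_la[k]) + 1.0 / MU_PRIOR_VAR
            mean = (la[:, k].sum() / (sd_la[k] * sd_la[k])) / prec
            mu_la[k] = mean + np.random.standard_normal() / math.sqrt(prec)
            s = 0.0
            for j in range(J):
                s += (la[j, k] - mu_la[k]) ** 2
            g = np.random.gamma(VAR_PRIOR_A + J / 2.0)
            sd_la[k] = math.sqrt((VAR_PRIOR_B + s / 2.0) / g)
        prec = J / (sd_lt * sd_lt) + 1.0 / MU_PRIOR_VAR
        mean = (lt.sum() / (sd_lt * sd_lt)) / prec
        mu_lt = mean + np.random.standard_normal() / math.sqrt(prec)
        s = 0.0
        for j in range(J):
            s += (lt[j] - mu_lt) ** 2
        g = np.random.gamma(VAR_PRIOR_A + J / 2.0)
        sd_lt = math.sqrt((VAR_PRIOR_B + s / 2.0) / g)

        # --- adapt proposal scales during burn-in ---
        if it < n_burn and (it + 1) % ADAPT_WIN == 0:
            for j in range(J):
                for k in range(n_lv):
                    sc_v[j, k] *= math.exp(0.66 * (ac_v[j, k] / ADAPT_WIN - 0.44))
                    ac_v[j, k] = 0.0
                for k in range(n_la):
                    sc_la[j, k] *= math.exp(0.66 * (ac_la[j, k] / ADAPT_WIN - 0.44))
                    ac_la[j, k] = 0.0
                sc_lt[j] *= math.exp(0.66 * (ac_lt[j] / ADAPT_WIN - 0.44))
                ac_lt[j] = 0.0
            sc_sv *= math.exp(0.66 * (ac_sv / (5 * ADAPT_WIN) - 0.44))
            sc_st *= math.exp(0.66 * (ac_st / (5 * ADAPT_WIN) - 0.44))
            ac_sv = 0.0
            ac_st = 0.0

        # --- record ---
        if it >= n_burn and (it - n_burn) % thin == 0:
            p = 0
            for k in range(n_lv):
                chains[kept, p] = mu_v[k]
                p += 1
            for k in range(n_lv):
                chains[kept, p] = sd_v[k]
                p += 1
            for k in range(n_la):
                chains[kept, p] = mu_la[k]
                p += 1
            for k in range(n_la):
                chains[kept, p] = sd_la[k]
                p += 1
            chains[kept, p] = mu_lt
            p += 1
            chains[kept, p] = sd_lt
            p += 1
            chains[kept, p] = sv
            p += 1
            chains[kept, p] = st
            p += 1
            for j in range(J):
                for k in range(n_lv):
                    chains[kept, p] = v[j, k]
                    p += 1
            for j in range(J):
                for k in range(n_la):
                    chains[kept, p] = la[j, k]
                    p += 1
            for j in range(J):
                chains[kept, p] = lt[j]
                p += 1
            deviance[kept] = -2.0 * ll.sum()
            kept += 1

    return chains, deviance
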