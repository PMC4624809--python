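"""Numba kernels for the hierarchical behavior samplers.

Both models factor over coherence levels. Positive parameters move by
log-scale random walks (with the log-normal proposal Jacobian), the
group accuracy mean by a logit-scale walk; subject-level accuracy
parameters are conjugate beta draws. Proposal scales adapt toward 44%
acceptance during burn-in only.
"""

import math

import numpy as np
from numba import njit

U_LO = 0.01  # uniform hyperprior support, shared by all positive hypers
U_HI = 30.0
ADAPT_WIN = 50


@njit(cache=True)
def _gamma_logpdf(x, shape, rate):
    if x <= 0.0 or shape <= 0.0 or rate <= 0.0:
        return -np.inf
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x


@njit(cache=True)
def _beta_logpdf(x, a, b):
    if x <= 0.0 or x >= 1.0 or a <= 0.0 or b <= 0.0:
        return -np.inf
    return (
        math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        + (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x)
    )


@njit(cache=True)
def _cell_gamma_loglik(n, sx, slx, mu, sig2):
    """Gamma likelihood of one subject x level RT cell from sufficient stats."""
    if mu <= 0.0 or sig2 <= 0.0:
        return -np.inf
    shape = mu * mu / sig2
    rate = mu / sig2
    return n * (shape * math.log(rate) - math.lgamma(shape)) + (shape - 1.0) * slx - rate * sx


@njit(cache=True)
def run_rt_chain(n, sx, slx, n_burn, n_keep, thin, seed):
    """One chain of the hierarchical gamma response-time model.

    Data are per (level, subject) sufficient statistics of the trial RTs:
    counts n, sums sx and log-sums slx. Per level c the model has group
    mean/sd (M, S) of the subject means, group mean/sd (V, W) of the
    subject variances — all with uniform(0.01, 30) hyperpriors — and
    subject-level means mu and variances sig2 with gamma priors derived
    from the group mean/sd via the shape = mean^2/sd^2, rate = mean/sd^2
    transform. Trial likelihood: rt ~ Gamma(mu^2/sig2, mu/sig2).

    Returns samples packed as [M(4), S(4), V(4), W(4), mu(4*J), sig2(4*J)].
    """
    np.random.seed(seed)
    C, J = n.shape
    M = np.zeros(C)
    S = np.zeros(C)
    V = np.zeros(C)
    W = np.zeros(C)
    mu = np.zeros((C, J))
    sig2 = np.zeros((C, J))
    for c in range(C):
        for j in range(J):
            m = sx[c, j] / max(n[c, j], 1.0)
            mu[c, j] = max(m, 0.05)
            sig2[c, j] = max(0.25 * m * m, 1e-3)
        M[c] = mu[c].mean()
        S[c] = max(mu[c].std(), 0.02)
        V[c] = sig2[c].mean()
        W[c] = max(sig2[c].std(), 0.002)

    sc_hyper = np.full((C, 4), 0.2)
    ac_hyper = np.zeros((C, 4))
    sc_mu = np.full((C, J), 0.05)
    ac_mu = np.zeros((C, J))
    sc_s2 = np.full((C, J), 0.2)
    ac_s2 = np.zeros((C, J))

    n_params = 4 * C + 2 * C * J
    out = np.zeros((n_keep, n_params))
    kept = 0
    n_iter = n_burn + n_keep * thin
    for it in range(n_iter):
        for c in range(C):
            # hyper M, S: prior of mu[c, :]
            for h in range(2):
                old = M[c] if h == 0 else S[c]
                prop = old * math.exp(sc_hyper[c, h] * np.random.standard_normal())
                if U_LO <= prop <= U_HI:
                    Mn = prop if h == 0 else M[c]
                    Sn = S[c] if h == 0 else prop
                    logr = math.log(prop / old)  # proposal Jacobian
                    sh_o = M[c] * M[c] / (S[c] * S[c])
                    ra_o = M[c] / (S[c] * S[c])
                    sh_n = Mn * Mn / (Sn * Sn)
                    ra_n = Mn / (Sn * Sn)
                    for j in range(J):
                        logr += _gamma_logpdf(mu[c, j], sh_n, ra_n) - _gamma_logpdf(
                            mu[c, j], sh_o, ra_o
                        )
                    if math.log(np.random.random()) < logr:
                        if h == 0:
                            M[c] = prop
                        else:
                            S[c] = prop
                        ac_hyper[c, h] += 1.0
            # hyper V, W: prior of sig2[c, :]
            for h in range(2):
                old = V[c] if h == 0 else W[c]
                prop = old * math.exp(sc_hyper[c, 2 + h] * np.random.standard_normal())
                if U_LO <= prop <= U_HI:
                    Vn = prop if h == 0 else V[c]
                    Wn = W[c] if h == 0 else prop
                    logr = math.log(prop / old)
                    sh_o = V[c] * V[c] / (W[c] * W[c])
                    ra_o = V[c] / (W[c] * W[c])
                    sh_n = Vn * Vn / (Wn * Wn)
                    ra_n = Vn / (Wn * Wn)
                    for j in range(J):
                        logr += _gamma_logpdf(sig2[c, j], sh_n, ra_n) - _gamma_logpdf(
                            sig2[c, j], sh_o, ra_o
                        )
                    if math.log(np.random.random()) < logr:
                        if h == 0:
                            V[c] = prop
                        else:
                            W[c] = prop
                        ac_hyper[c, 2 + h] += 1.0
            # subject means and variances
            sh_m = M[c] * M[c] / (S[c] * S[c])
            ra_m = M[c] / (S[c] * S[c])
            sh_v = V[c] * V[c] / (W[c] * W[c])
            ra_v = V[c] / (W[c] * W[c])
            for j in range(J):
                old = mu[c, j]
                prop = old * math.exp(sc_mu[c, j] * np.random.standard_normal())
                logr = math.log(prop / old)
                logr += _gamma_logpdf(prop, sh_m, ra_m) - _gamma_logpdf(old, sh_m, ra_m)
                logr += _cell_gamma_loglik(n[c, j], sx[c, j], slx[c, j], prop, sig2[c, j]) - \
                    _cell_gamma_loglik(n[c, j], sx[c, j], slx[c, j], old, sig2[c, j])
                if math.log(np.random.random()) < logr:
                    mu[c, j] = prop
                    ac_mu[c, j] += 1.0
                old = sig2[c, j]
                prop = old * math.exp(sc_s2[c, j] * np.random.standard_normal())
                logr = math.log(prop / old)
                logr += _gamma_logpdf(prop, sh_v, ra_v) - _gamma_logpdf(old, sh_v, ra_v)
                logr += _cell_gamma_loglik(n[c, j], sx[c, j], slx[c, j], mu[c, j], prop) - \
                    _cell_gamma_loglik(n[c, j], sx[c, j], slx[c, j], mu[c, j], old)
                if math.log(np.random.random()) < logr:
                    sig2[c, j] = prop
                    ac_s2[c, j] += 1.0

        if it < n_burn and (it + 1) % ADAPT_WIN == 0:
            for c in range(C):
                for h in range(4):
                    sc_hyper[c, h] *= math.exp(0.66 * (ac_hyper[c, h] / ADAPT_WIN - 0.44))
                    ac_hyper[c, h] = 0.0
                for j in range(J):
                    sc_mu[c, j] *= math.exp(0.66 * (ac_mu[c, j] / ADAPT_WIN - 0.44))
                    ac_mu[c, j] = 0.0
                    sc_s2[c, j] *= math.exp(0.66 * (ac_s2[c, j] / ADAPT_WIN - 0.44))
                    ac_s2[c, j] = 0.0

        if it >= n_burn and (it - n_burn) % thin == 0:
            p = 0
            for arr in (M, S, V, W):
                for c in range(C):
                    out[kept, p] = arr[c]
                    p += 1
            for c in range(C):
                for j in range(J):
                    out[kept, p] = mu[c, j]
                    p += 1
            for c in range(C):
                for j in range(J):
                    out[kept, p] = sig2[c, j]
                    p += 1
            kept += 1
    return out


@njit(cache=True)
def _betabinom_loglik(z, N, a, b):
    """Binomial likelihood with the subject rate integrated out of its beta."""
    if a <= 0.0 or b <= 0.0:
        return -np.inf
    return (
        math.lgamma(a + z) + math.lgamma(b + N - z) - math.lgamma(a + b + N)
        + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
    )


@njit(cache=True)
def run_accuracy_chain(z, N, n_burn, n_keep, thin, seed):
    """One chain of the hierarchical beta-binomial accuracy model.

    Data: correct counts z and trial counts N per (level, subject). Per
    level the subject accuracies theta are beta-distributed around a
    group mean m (flat Beta(1,1) prior) with variance var; var has a
    gamma prior whose mean Vm and sd Vs carry uniform(0.01, 30)
    hyperpriors. The beta is moment-parameterized: kappa = m(1-m)/var - 1,
    alpha = m*kappa, beta = (1-m)*kappa (requires var < m(1-m)).

    Group-level moves use the collapsed (beta-binomial) likelihood with
    the subject rates integrated out — this removes the funnel between
    the group variance and the subject rates. The variance is sampled as
    the fraction phi = var / (m(1-m)) of its admissible range, so the
    beta concentration kappa = (1-phi)/phi is decoupled from the mean
    and the sampler does not crawl along the var < m(1-m) boundary when
    accuracies are near ceiling. Thetas are then drawn from their exact
    conditional Beta(alpha + z, beta + N - z) for reporting.

    Returns samples packed as [m(4), var(4), Vm(4), Vs(4), theta(4*J)].
    """
    np.random.seed(seed)
    C, J = z.shape
    m = np.zeros(C)
    phi = np.zeros(C)
    Vm = np.full(C, 0.01)
    Vs = np.full(C, 0.02)
    theta = np.zeros((C, J))
    for c in range(C):
        for j in range(J):
            theta[c, j] = (z[c, j] + 1.0) / (N[c, j] + 2.0)
        m[c] = theta[c].mean()
        v0 = min(max(theta[c].var(), 1e-4), 0.5 * m[c] * (1 - m[c]))
        phi[c] = v0 / (m[c] * (1 - m[c]))

    sc_m = np.full(C, 0.3)
    ac_m = np.zeros(C)
    sc_var = np.full(C, 0.3)
    ac_var = np.zeros(C)
    sc_h = np.full((C, 2), 0.3)
    ac_h = np.zeros((C, 2))

    n_params = 4 * C + C * J
    out = np.zeros((n_keep, n_params))
    kept = 0
    n_iter = n_burn + n_keep * thin
    for it in range(n_iter):
        for c in range(C):
            kappa = (1.0 - phi[c]) / phi[c]
            alpha = m[c] * kappa
            beta = (1 - m[c]) * kappa
            var_c = phi[c] * m[c] * (1 - m[c])
            sh = Vm[c] * Vm[c] / (Vs[c] * Vs[c])
            ra = Vm[c] / (Vs[c] * Vs[c])
            # group mean: logit walk, flat prior on (0,1), collapsed
            # likelihood; var = phi*m(1-m) moves with m, so the ratio
            # carries the gamma prior of var and its d var/d phi Jacobian
            # (m(1-m)) on top of the logit-proposal Jacobian
            lo = math.log(m[c] / (1 - m[c]))
            lp = lo + sc_m[c] * np.random.standard_normal()
            mp = 1.0 / (1.0 + math.exp(-lp))
            vn = phi[c] * mp * (1 - mp)
            if vn >= 1e-9:
                logr = 2.0 * (math.log(mp * (1 - mp)) - math.log(m[c] * (1 - m[c])))
                logr += _gamma_logpdf(vn, sh, ra) - _gamma_logpdf(var_c, sh, ra)
                an = mp * kappa
                bn = (1 - mp) * kappa
                for j in range(J):
                    logr += _betabinom_loglik(z[c, j], N[c, j], an, bn) - _betabinom_loglik(
                        z[c, j], N[c, j], alpha, beta
                    )
                if math.log(np.random.random()) < logr:
                    m[c] = mp
                    alpha, beta = an, bn
                    var_c = vn
                    ac_m[c] += 1.0
            # variance fraction: logit walk on phi, gamma prior on var
            lo = math.log(phi[c] / (1 - phi[c]))
            lp = lo + sc_var[c] * np.random.standard_normal()
            pp = 1.0 / (1.0 + math.exp(-lp))
            vn = pp * m[c] * (1 - m[c])
            if vn >= 1e-9:
                logr = math.log(pp * (1 - pp)) - math.log(phi[c] * (1 - phi[c]))
                logr += _gamma_logpdf(vn, sh, ra) - _gamma_logpdf(var_c, sh, ra)
                kn = (1.0 - pp) / pp
                an = m[c] * kn
                bn = (1 - m[c]) * kn
                for j in range(J):
                    logr += _betabinom_loglik(z[c, j], N[c, j], an, bn) - _betabinom_loglik(
                        z[c, j], N[c, j], alpha, beta
                    )
                if math.log(np.random.random()) < logr:
                    phi[c] = pp
                    alpha, beta, kappa = an, bn, kn
                    var_c = vn
                    ac_var[c] += 1.0
            # subject rates from their exact conditional (reporting only)
            for j in range(J):
                theta[c, j] = np.random.beta(alpha + z[c, j], beta + N[c, j] - z[c, j])
            # hypers of the variance gamma
            for h in range(2):
                old = Vm[c] if h == 0 else Vs[c]
                prop = old * math.exp(sc_h[c, h] * np.random.standard_normal())
                if U_LO <= prop <= U_HI:
                    Vmn = prop if h == 0 else Vm[c]
                    Vsn = Vs[c] if h == 0 else prop
                    logr = math.log(prop / old)
                    logr += _gamma_logpdf(var_c, Vmn * Vmn / (Vsn * Vsn), Vmn / (Vsn * Vsn))
                    logr -= _gamma_logpdf(var_c, Vm[c] * Vm[c] / (Vs[c] * Vs[c]), Vm[c] / (Vs[c] * Vs[c]))
                    if math.log(np.random.random()) < logr:
                        if h == 0:
                            Vm[c] = prop
                        else:
                            Vs[c] = prop
                        ac_h[c, h] += 1.0

        if it < n_burn and (it + 1) % ADAPT_WIN == 0:
            for c in range(C):
                sc_m[c] *= math.exp(0.66 * (ac_m[c] / ADAPT_WIN - 0.44))
                ac_m[c] = 0.0
                sc_var[c] *= math.exp(0.66 * (ac_var[c] / ADAPT_WIN - 0.44))
                ac_var[c] = 0.0
                for h in range(2):
                    sc_h[c, h] *= math.exp(0.66 * (ac_h[c, h] / ADAPT_WIN - 0.44))
                    ac_h[c, h] = 0.0

        if it >= n_burn and (it - n_burn) % thin == 0:
            p = 0
            for c in range(C):
                out[kept, p] = m[c]
                p += 1
            for c in range(C):
                out[kept, p] = phi[c] * m[c] * (1 - m[c])  # var on its natural scale
                p += 1
            for c in range(C):
                out[kept, p] = Vm[c]
                p += 1
            for c in range(C):
                out[kept, p] = Vs[c]
                p += 1
            for c in range(C):
                for j in range(J):
                    out[kept, p] = theta[c, j]
                    p += 1
            kept += 1
    return out
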