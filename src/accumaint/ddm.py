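"""Hierarchical drift-diffusion estimation from reaction-time trials.

The drift diffusion model treats a two-choice decision as noisy evidence
accumulating from a start point z between two boundaries 0 and a; the
drift rate v measures evidence quality, and a non-decision time t adds
encoding and motor latency to the first-passage time. Here z is fixed at
a/2 (no response bias), the diffusion scale at s = 1, and the likelihood
is the Wiener first-passage-time density with between-trial variability
in drift (sv, integrated analytically) and non-decision time (st,
midpoint quadrature).

Four model variants differ in which parameters track difficulty
(coherence level): the full model lets both drift and boundary vary by
level; the difficulty-blind variant fixes both; the remaining two free
only the drift or only the boundary. Variants are compared with the
deviance information criterion; posterior predictive simulation checks
that fitted parameters reproduce the observed RT distributions.

Fitting applies only to the reaction-time condition: with a cued delay,
responses are decoupled from boundary crossings, so delayed-response
trials are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _wfpt
from ._hddm_kernel import run_chain
from .design import ExperimentDesign
from .posterior import PosteriorChains
from .synthetic_data import GenParamsDDM, simulate_ddm_dataset

__all__ = [
    "DDMModelSpec",
    "DDMPosterior",
    "DICResult",
    "MCMCConfig",
    "wfpt_density",
    "ddm_loglik",
    "fit_hddm",
    "dic",
    "posterior_predictive",
]

LEVELS = (1, 2, 3, 4)


@dataclass(frozen=True)
class DDMModelSpec:
    """Which DDM parameters vary with coherence level.

    name is one of "m1" (drift and boundary vary), "m2" (neither; the
    difficulty-blind model), "m3" (drift only), "m4" (boundary only).
    Non-decision time and the group-level variabilities sv and st are
    always estimated; the start point is fixed at a/2.
    """

    name: str = "m1"

    def __post_init__(self):
        if self.name not in ("m1", "m2", "m3", "m4"):
            raise ValueError("model must be one of m1, m2, m3, m4")

    @property
    def drift_by_level(self) -> bool:
        return self.name in ("m1", "m3")

    @property
    def boundary_by_level(self) -> bool:
        return self.name in ("m1", "m4")

    @property
    def vmap(self) -> np.ndarray:
        """coherence level (0-based) -> drift parameter index"""
        return np.arange(4) if self.drift_by_level else np.zeros(4, dtype=int)

    @property
    def amap(self) -> np.ndarray:
        return np.arange(4) if self.boundary_by_level else np.zeros(4, dtype=int)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler budget. Defaults: 3 chains, 5000 kept after 2000 burn-in."""

    n_chains: int = 3
    n_samples: int = 5000
    n_burn: int = 2000
    thin: int = 1
    st_quad_points: int = 3
    precision: float = 1e-7

    def __post_init__(self):
        if self.n_chains < 1 or self.n_samples < 1 or self.thin < 1:
            raise ValueError("invalid MCMC budget")


def wfpt_density(t_dec, v, a, z_rel=0.5, precision=1e-7, boundary="lower", sv=0.0):
    """Wiener first-passage density at one boundary at decision time t_dec.

    The series truncation keeps the absolute error of the drift-free part
    below *precision*. The upper-boundary density is obtained from the
    lower one by the reflection (v, z_rel) -> (-v, 1 - z_rel).
    """
    if a <= 0:
        raise ValueError("boundary separation must be positive")
    if not 0.0 < z_rel < 1.0:
        raise ValueError("relative start point must be in (0, 1)")
    t_dec = np.asarray(t_dec, dtype=float)
    up = boundary == "upper"
    if boundary not in ("lower", "upper"):
        raise ValueError("boundary must be 'lower' or 'upper'")
    out = np.array(
        [
            _wfpt.wfpt_density(float(t), float(v), float(a), float(z_rel), up, float(sv), precision)
            for t in np.atleast_1d(t_dec)
        ]
    )
    return float(out[0]) if t_dec.ndim == 0 else out


def _prepare_trials(trials: pd.DataFrame):
    """Validate, drop missed trials and return (rt, upper, subject, level) arrays."""
    if (trials["condition"] == "DR").any():
        raise ValueError(
            "delayed-response trials passed to the DDM: responses after a cued "
            "delay are not boundary crossings, so this model does not apply"
        )
    t = trials[trials["choice"] != "missed"]
    rt = t["rt"].to_numpy(dtype=float)
    upper = t["correct"].to_numpy(dtype=bool)  # upper boundary codes the correct response
    return t, rt, upper


def ddm_loglik(
    trials: pd.DataFrame,
    drift_per_level: dict,
    boundary_per_level: dict,
    t_nd: float,
    sv: float = 0.0,
    st: float = 0.0,
    st_quad_points: int = 3,
    precision: float = 1e-7,
) -> float:
    """Summed log first-passage density of a trial table.

    Drift variability sv is integrated in closed form; st by midpoint
    quadrature. With sv = st = 0 this is exactly the plain Wiener
    first-passage log-likelihood. Trials with zero density (e.g. rt below
    the non-decision time) contribute -inf.
    """
    if len(trials) == 0:
        return 0.0
    _, rt, upper = _prepare_trials(trials)
    lvl = trials[trials["choice"] != "missed"]["coherence_level"].to_numpy(dtype=int)
    total = 0.0
    for i in range(rt.size):
        total += _wfpt.trial_loglik(
            rt[i],
            bool(upper[i]),
            float(drift_per_level[lvl[i]]),
            float(boundary_per_level[lvl[i]]),
            float(t_nd),
            float(sv),
            float(st),
            st_quad_points,
            precision,
        )
        if total == -np.inf:
            return -np.inf
    return float(total)


def _ez_init(rt, upper, min_rt):
    """EZ-diffusion moment-based starting values (v, a, t) for one cell.

    Robust to edge cases: accuracies at 0/1 are edge-corrected, and the
    result is clipped to sane ranges. Used only for initialization.
    """
    n = rt.size
    p = np.clip((upper.sum() + 0.5) / (n + 1.0), 0.02, 0.98)
    vrt = max(np.var(rt), 1e-4)
    L = np.log(p / (1 - p))
    x = L * (L * p * p - L * p + p - 0.5) / vrt
    v = np.sign(p - 0.5) * abs(x) ** 0.25
    v = float(np.clip(v, -5.0, 5.0))
    if abs(v) < 0.1:
        v = 0.1 if v >= 0 else -0.1
    a = float(np.clip(L / v if abs(L) > 1e-6 else 1.5, 0.5, 4.0))
    y = -v * a
    mdt = np.mean(rt) - (a / (2 * v)) * (1 - np.exp(y)) / (1 + np.exp(y))
    t0 = float(np.clip(mdt, 0.05, 0.95 * min_rt))
    return v, a, t0


@dataclass
class DDMPosterior:
    """Posterior chains plus deviance samples from a hierarchical DDM fit."""

    chains: PosteriorChains
    deviance: np.ndarray  # (n_chains, n_samples)
    spec: DDMModelSpec
    subjects: list

    def group_names(self) -> list[str]:
        return [n for n in self.chains.names() if n.startswith(("mu_", "sd_", "sv", "st"))]

    def group_rhat(self) -> dict[str, float]:
        return self.chains.rhat(self.group_names())


def fit_hddm(
    trials: pd.DataFrame,
    spec: DDMModelSpec | str = "m1",
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
) -> DDMPosterior:
    """Fit the hierarchical DDM to RT-condition trials.

    Subject drift rates follow a normal group distribution per drift
    index; boundary separations and non-decision times are log-normal.
    sv and st are estimated at the group level only. Chains are
    deterministic given (data, spec, mcmc, seed).
    """
    if isinstance(spec, str):
        spec = DDMModelSpec(spec)
    mcmc = mcmc or MCMCConfig()
    t, rt_all, upper_all = _prepare_trials(trials)
    subjects = sorted(t["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")

    # sort trials into contiguous (subject, level) blocks
    t = t.assign(_rt=rt_all, _up=upper_all.astype(np.int8))
    t = t.sort_values(["subject", "coherence_level"], kind="mergesort")
    rts = t["_rt"].to_numpy()
    uppers = t["_up"].to_numpy()
    J = len(subjects)
    start = np.zeros((J, 4), dtype=np.int64)
    end = np.zeros((J, 4), dtype=np.int64)
    sub_codes = t["subject"].to_numpy()
    lvl_codes = t["coherence_level"].to_numpy()
    pos = 0
    for j, s in enumerate(subjects):
        for l in range(4):
            n = int(np.sum((sub_codes == s) & (lvl_codes == l + 1)))
            start[j, l] = pos
            end[j, l] = pos + n
            pos += n

    n_lv = 4 if spec.drift_by_level else 1
    n_la = 4 if spec.boundary_by_level else 1

    # EZ-diffusion starting values per subject
    v0 = np.zeros((J, n_lv))
    la0 = np.zeros((J, n_la))
    lt0 = np.zeros(J)
    for j, s in enumerate(subjects):
        mask = sub_codes == s
        min_rt = rts[mask].min()
        ez_v = np.zeros(4)
        ez_a = np.zeros(4)
        ez_t = np.zeros(4)
        for l in range(4):
            i0, i1 = start[j, l], end[j, l]
            if i1 > i0:
                ez_v[l], ez_a[l], ez_t[l] = _ez_init(rts[i0:i1], uppers[i0:i1], min_rt)
            else:
                ez_v[l], ez_a[l], ez_t[l] = 1.0, 1.5, 0.5 * min_rt
        for k in range(n_lv):
            sel = spec.vmap == k
            v0[j, k] = ez_v[sel].mean()
        for k in range(n_la):
            sel = spec.amap == k
            la0[j, k] = np.log(ez_a[sel].mean())
        lt0[j] = np.log(np.clip(ez_t.mean(), 0.03, 0.9 * min_rt))

    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=mcmc.n_chains)
    all_chains = []
    all_dev = []
    for c in range(mcmc.n_chains):
        crng = np.random.default_rng(chain_seeds[c])
        jv = v0 + 0.1 * crng.standard_normal(v0.shape)
        jla = la0 + 0.05 * crng.standard_normal(la0.shape)
        jlt = np.minimum(lt0 + 0.05 * crng.standard_normal(lt0.shape), lt0)
        ch, dev = run_chain(
            rts, uppers, start, end,
            spec.vmap.astype(np.int64), spec.amap.astype(np.int64), n_lv, n_la,
            jv, jla, jlt, 0.1, 0.01,
            mcmc.n_burn, mcmc.n_samples, mcmc.thin,
            int(chain_seeds[c] % (2**31 - 1)), mcmc.st_quad_points, mcmc.precision,
        )
        all_chains.append(ch)
        all_dev.append(dev)
    packed = np.stack(all_chains)  # (chains, samples, params)
    deviance = np.stack(all_dev)

    names = _param_names(spec, subjects, n_lv, n_la)
    params = {name: packed[:, :, i] for i, name in enumerate(names)}
    # natural-scale group boundary / non-decision time (log-normal medians)
    for k in range(n_la):
        label = f"a_group({_idx_label(spec.boundary_by_level, k)})"
        params[label] = np.exp(params[f"mu_log_a({_idx_label(spec.boundary_by_level, k)})"])
    params["t_group"] = np.exp(params["mu_log_t"])
    chains = PosteriorChains(
        params,
        meta={
            "model": spec.name,
            "seed": seed,
            "burn_in": mcmc.n_burn,
            "thinning": mcmc.thin,
        },
    )
    return DDMPosterior(chains=chains, deviance=deviance, spec=spec, subjects=subjects)


def _idx_label(by_level: bool, k: int) -> str:
    return f"level{k + 1}" if by_level else "all"


def _param_names(spec, subjects, n_lv, n_la):
    names = []
    vl = [_idx_label(spec.drift_by_level, k) for k in range(n_lv)]
    al = [_idx_label(spec.boundary_by_level, k) for k in range(n_la)]
    names += [f"mu_v({l})" for l in vl]
    names += [f"sd_v({l})" for l in vl]
    names += [f"mu_log_a({l})" for l in al]
    names += [f"sd_log_a({l})" for l in al]
    names += ["mu_log_t", "sd_log_t", "sv", "st"]
    for s in subjects:
        names += [f"v[{s}]({l})" for l in vl]
    for s in subjects:
        names += [f"log_a[{s}]({l})" for l in al]
    names += [f"log_t[{s}]" for s in subjects]
    return names


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion: DIC = mean deviance + pD."""

    dic: float
    mean_deviance: float
    p_d: float


def dic(posterior: DDMPosterior, trials: pd.DataFrame) -> DICResult:
    """DIC with the plug-in effective-parameter estimate.

    pD = mean deviance minus the deviance at the posterior means of the
    subject-level parameters (and sv, st); DIC = mean deviance + pD.
    Lower is better.
    """
    dev = posterior.deviance.reshape(-1)
    if dev.size < 100:
        raise ValueError("need at least 100 deviance samples for a stable DIC")
    d_bar = float(dev.mean())
    ch = posterior.chains
    spec = posterior.spec
    t, rt, upper = _prepare_trials(trials)
    lvl = t["coherence_level"].to_numpy(dtype=int)
    subj = t["subject"].to_numpy()
    total = 0.0
    sv_hat = float(ch.pooled("sv").mean())
    st_hat = float(ch.pooled("st").mean())
    for s in posterior.subjects:
        vl = [_idx_label(spec.drift_by_level, k) for k in range(4 if spec.drift_by_level else 1)]
        al = [_idx_label(spec.boundary_by_level, k) for k in range(4 if spec.boundary_by_level else 1)]
        v_hat = {k: float(ch.pooled(f"v[{s}]({l})").mean()) for k, l in enumerate(vl)}
        a_hat = {k: float(np.exp(ch.pooled(f"log_a[{s}]({l})")).mean()) for k, l in enumerate(al)}
        t_hat = float(np.exp(ch.pooled(f"log_t[{s}]")).mean())
        mask = subj == s
        for i in np.nonzero(mask)[0]:
            total += _wfpt.trial_loglik(
                float(rt[i]),
                bool(upper[i]),
                v_hat[int(spec.vmap[lvl[i] - 1])],
                a_hat[int(spec.amap[lvl[i] - 1])],
                t_hat,
                sv_hat,
                st_hat,
                3,
                1e-7,
            )
    d_hat = -2.0 * total
    p_d = d_bar - d_hat
    return DICResult(dic=d_bar + p_d, mean_deviance=d_bar, p_d=p_d)


def posterior_predictive(
    posterior: DDMPosterior,
    design: ExperimentDesign,
    n_draws: int = 50,
    seed: int = 0,
    trials_per_level: int = 25,
) -> pd.DataFrame:
    """Simulate datasets from posterior parameter draws.

    Each draw picks one joint posterior sample per subject and simulates
    fresh trials; error responses are coded with negative response times
    (the usual convention for overlaying correct/error RT distributions).
    Returns a long table with columns draw, subject, coherence_level,
    correct, rt (signed).
    """
    if n_draws == 0:
        return pd.DataFrame(columns=["draw", "subject", "coherence_level", "correct", "rt"])
    rng = np.random.default_rng(seed)
    ch = posterior.chains
    spec = posterior.spec
    n_total = ch.n_chains * ch.n_samples
    rows = []
    vl = [_idx_label(spec.drift_by_level, k) for k in range(4 if spec.drift_by_level else 1)]
    al = [_idx_label(spec.boundary_by_level, k) for k in range(4 if spec.boundary_by_level else 1)]
    for d in range(n_draws):
        idx = int(rng.integers(n_total))
        sv = float(ch.pooled("sv")[idx])
        st = float(ch.pooled("st")[idx])
        for s in posterior.subjects:
            drift = {
                lvl + 1: float(ch.pooled(f"v[{s}]({vl[spec.vmap[lvl]]})")[idx]) for lvl in range(4)
            }
            bound = {
                lvl + 1: float(np.exp(ch.pooled(f"log_a[{s}]({al[spec.amap[lvl]]})")[idx]))
                for lvl in range(4)
            }
            t_nd = float(np.exp(ch.pooled(f"log_t[{s}]")[idx]))
            p = GenParamsDDM(
                drift_per_level=drift, boundary_per_level=bound, t_nd=t_nd, sv=sv, st=st
            )
            one = ExperimentDesign(
                n_subjects=1,
                trials_per_run=trials_per_level * 4,
                runs=("RT",),
                stimulus_window_s=design.stimulus_window_s,
            )
            sim = simulate_ddm_dataset(one, p, seed=int(rng.integers(2**31 - 1)))
            sim = sim[sim["choice"] != "missed"]
            rows.append(
                pd.DataFrame(
                    {
                        "draw": d,
                        "subject": s,
                        "coherence_level": sim["coherence_level"].to_numpy(),
                        "correct": sim["correct"].to_numpy(),
                        "rt": np.where(sim["correct"], sim["rt"], -sim["rt"]),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
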