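"""Hierarchical Bayesian estimation of response times and accuracy.

Response times follow a gamma likelihood whose shape and rate come from a
subject-level mean and variance (shape = mu^2/sigma^2, rate = mu/sigma^2);
subject means and variances are in turn gamma-distributed around group
means/sds with uniform(0.01, 30) hyperpriors. Accuracy follows a binomial
likelihood with subject rates beta-distributed around a group mean (flat
Beta(1,1) prior) and a gamma-prior variance. Both models are fit per
coherence level and separately per response condition.

Results are reported the Bayesian-estimation way: grouped chains
(sample-by-sample means over constituent levels), the proportion of
posterior-difference samples above zero, 95% highest density intervals,
and the Gelman-Rubin convergence diagnostic (see :mod:`accumaint.posterior`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._behavior_kernels import run_accuracy_chain, run_rt_chain
from .design import EASY_LEVELS, HARD_LEVELS, correct_counts
from .posterior import PosteriorChains, group_chain

__all__ = [
    "gamma_shape_rate",
    "fit_rt_model",
    "fit_accuracy_model",
    "BehaviorMCMCConfig",
    "easy_hard_chains",
    "condition_chain",
]

LEVELS = (1, 2, 3, 4)


def gamma_shape_rate(mean: float, sd: float) -> tuple[float, float]:
    """Moment transform from (mean, sd) to gamma (shape, rate)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return mean * mean / (sd * sd), mean / (sd * sd)


class BehaviorMCMCConfig:
    """Budget for the behavior samplers: 3 chains, 5000 kept, 2000 burn-in."""

    def __init__(self, n_chains: int = 3, n_samples: int = 5000, n_burn: int = 2000, thin: int = 1):
        if n_chains < 1 or n_samples < 1 or thin < 1:
            raise ValueError("invalid MCMC budget")
        self.n_chains = n_chains
        self.n_samples = n_samples
        self.n_burn = n_burn
        self.thin = thin


def _check_cells(values: pd.DataFrame, what: str):
    subjects = sorted(values["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("hierarchical fit requires at least 2 subjects")
    for s in subjects:
        for c in LEVELS:
            cell = values[(values["subject"] == s) & (values["coherence_level"] == c)]
            if len(cell) == 0:
                raise ValueError(f"no {what} for subject {s} at coherence level {c}")
    return subjects


def fit_rt_model(
    trials: pd.DataFrame,
    condition: str = "RT",
    mcmc: BehaviorMCMCConfig | None = None,
    seed: int = 0,
) -> PosteriorChains:
    """Fit the hierarchical gamma model to the response times of one condition.

    Missed trials are excluded. Returns chains named
    ``rt_mean(levelc)`` / ``rt_mean_sd(levelc)`` for the group mean/sd of
    subject mean RTs, ``rt_var(levelc)`` / ``rt_var_sd(levelc)`` for the
    group mean/sd of subject RT variances, and subject-level
    ``rt_mu[s](levelc)`` / ``rt_sig2[s](levelc)``.
    """
    mcmc = mcmc or BehaviorMCMCConfig()
    t = trials[(trials["condition"] == condition) & (trials["choice"] != "missed")]
    if t["rt"].isna().any() or (t["rt"] <= 0).any():
        raise ValueError("answered trials must carry positive response times")
    subjects = _check_cells(t, "trials")
    J = len(subjects)
    n = np.zeros((4, J))
    sx = np.zeros((4, J))
    slx = np.zeros((4, J))
    for ci, c in enumerate(LEVELS):
        for ji, s in enumerate(subjects):
            rts = t[(t["subject"] == s) & (t["coherence_level"] == c)]["rt"].to_numpy()
            if rts.size < 2:
                raise ValueError(f"need >= 2 trials for subject {s} at level {c}")
            n[ci, ji] = rts.size
            sx[ci, ji] = rts.sum()
            slx[ci, ji] = np.log(rts).sum()

    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=mcmc.n_chains)
    raw = np.stack(
        [
            run_rt_chain(n, sx, slx, mcmc.n_burn, mcmc.n_samples, mcmc.thin, int(cs))
            for cs in chain_seeds
        ]
    )
    names = []
    for prefix in ("rt_mean", "rt_mean_sd", "rt_var", "rt_var_sd"):
        names += [f"{prefix}(level{c})" for c in LEVELS]
    for c in LEVELS:
        names += [f"rt_mu[{s}](level{c})" for s in subjects]
    for c in LEVELS:
        names += [f"rt_sig2[{s}](level{c})" for s in subjects]
    params = {name: raw[:, :, i] for i, name in enumerate(names)}
    return PosteriorChains(
        params,
        meta={
            "model": "rt_gamma",
            "condition": condition,
            "seed": seed,
            "burn_in": mcmc.n_burn,
            "thinning": mcmc.thin,
            "group_params": [
                f"{p}(level{c})"
                for p in ("rt_mean", "rt_mean_sd", "rt_var", "rt_var_sd")
                for c in LEVELS
            ],
        },
    )


def fit_accuracy_model(
    trials: pd.DataFrame | None,
    condition: str = "RT",
    mcmc: BehaviorMCMCConfig | None = None,
    seed: int = 0,
    counts: pd.DataFrame | None = None,
) -> PosteriorChains:
    """Fit the hierarchical beta-binomial model to one condition's accuracy.

    Returns chains named ``acc_mean(levelc)`` (group accuracy mean),
    ``acc_var(levelc)``, the variance-prior hypers ``acc_var_mean`` /
    ``acc_var_sd`` and subject-level ``acc_theta[s](levelc)``.
    """
    mcmc = mcmc or BehaviorMCMCConfig()
    if counts is None:
        counts = correct_counts(trials, condition)
    if (counts["z"] > counts["n"]).any():
        raise ValueError("correct count exceeds trial count")
    subjects = _check_cells(counts, "correct counts")
    J = len(subjects)
    z = np.zeros((4, J))
    N = np.zeros((4, J))
    for ci, c in enumerate(LEVELS):
        for ji, s in enumerate(subjects):
            cell = counts[(counts["subject"] == s) & (counts["coherence_level"] == c)]
            z[ci, ji] = float(cell["z"].iloc[0])
            N[ci, ji] = float(cell["n"].iloc[0])

    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=mcmc.n_chains)
    raw = np.stack(
        [
            run_accuracy_chain(z, N, mcmc.n_burn, mcmc.n_samples, mcmc.thin, int(cs))
            for cs in chain_seeds
        ]
    )
    names = []
    for prefix in ("acc_mean", "acc_var", "acc_var_mean", "acc_var_sd"):
        names += [f"{prefix}(level{c})" for c in LEVELS]
    for c in LEVELS:
        names += [f"acc_theta[{s}](level{c})" for s in subjects]
    params = {name: raw[:, :, i] for i, name in enumerate(names)}
    return PosteriorChains(
        params,
        meta={
            "model": "accuracy_beta_binomial",
            "condition": condition,
            "seed": seed,
            "burn_in": mcmc.n_burn,
            "thinning": mcmc.thin,
            "group_params": [
                f"{p}(level{c})"
                for p in ("acc_mean", "acc_var", "acc_var_mean", "acc_var_sd")
                for c in LEVELS
            ],
        },
    )


def easy_hard_chains(chains: PosteriorChains, param_prefix: str):
    """Grouped (easy, hard) chains over the two constituent coherence levels.

    The grouped chain is the sample-by-sample mean of the level chains,
    with equal weight per level.
    """
    easy = group_chain([chains.pooled(f"{param_prefix}(level{c})") for c in EASY_LEVELS])
    hard = group_chain([chains.pooled(f"{param_prefix}(level{c})") for c in HARD_LEVELS])
    return easy, hard


def condition_chain(chains: PosteriorChains, param_prefix: str):
    """One grouped chain over all four coherence levels of a condition."""
    return group_chain([chains.pooled(f"{param_prefix}(level{c})") for c in LEVELS])


def group_rhat(chains: PosteriorChains) -> dict[str, float]:
    """R-hat of every group-level parameter of a behavior fit."""
    return chains.rhat(chains.meta["group_params"])
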