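"""Posterior-sample containers and the reporting statistics used throughout.

All fits in this package return a :class:`PosteriorChains`: a mapping from
parameter name to a ``(n_chains, n_samples)`` array. Differences between
conditions are summarised by the proportion of paired posterior-difference
samples above zero (a posterior probability of an ordering), 95% highest
density intervals, and the classic Gelman-Rubin potential scale reduction
factor for convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PosteriorChains",
    "group_chain",
    "prob_greater",
    "hdi",
    "gelman_rubin",
]


@dataclass
class PosteriorChains:
    """Labelled MCMC output.

    params maps parameter name -> array of shape (n_chains, n_samples);
    every parameter must have the same shape. meta records burn-in,
    thinning and the seed for provenance.
    """

    params: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.params.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent chain shapes: {shapes}")
        self.params = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in self.params.items()}

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def names(self) -> list[str]:
        return list(self.params)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat sample array."""
        return self.params[name].reshape(-1)

    def rhat(self, names=None) -> dict[str, float]:
        names = self.names() if names is None else names
        return {n: gelman_rubin(self.params[n]) for n in names}

    def summary(self, names=None, mass: float = 0.95) -> dict[str, dict]:
        names = self.names() if names is None else names
        out = {}
        for n in names:
            pooled = self.pooled(n)
            lo, hi = hdi(pooled, mass)
            out[n] = {
                "mean": float(pooled.mean()),
                "hdi_low": lo,
                "hdi_high": hi,
                "rhat": gelman_rubin(self.params[n]),
            }
        return out

    def to_frame(self):
        """Long-format DataFrame (parameter, chain, iter, value) for CSV export."""
        import pandas as pd

        rows = []
        for name, arr in self.params.items():
            n_chain, n_samp = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(n_chain), n_samp),
                        "iter": np.tile(np.arange(n_samp), n_chain),
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df, meta=None) -> "PosteriorChains":
        params = {}
        for name, g in df.groupby("parameter", sort=False):
            n_chain = g["chain"].nunique()
            params[name] = g.sort_values(["chain", "iter"])["value"].to_numpy().reshape(n_chain, -1)
        return cls(params, meta or {})


def group_chain(chains) -> np.ndarray:
    """Sample-by-sample mean of equal-length chains.

    Used to aggregate parameters, e.g. the two constituent coherence levels
    of the "easy" group into a single grouped chain.
    """
    arrs = [np.asarray(c, dtype=float) for c in chains]
    if not arrs:
        raise ValueError("no chains given")
    length = arrs[0].shape
    if any(a.shape != length for a in arrs):
        raise ValueError("chains must have equal length")
    return np.mean(arrs, axis=0)


def prob_greater(chain_a, chain_b) -> float:
    """Fraction of paired samples with a strictly greater than b.

    This is the posterior probability that the quantity behind *chain_a*
    exceeds the one behind *chain_b*, given paired posterior samples.
    """
    a = np.asarray(chain_a, dtype=float).reshape(-1)
    b = np.asarray(chain_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("paired chains must have equal length")
    return float(np.mean(a > b))


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally narrow windows resolve to the first (lowest) window
    in sorted order.
    """
    x = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HDI")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def gelman_rubin(chains) -> float:
    """Classic Gelman-Rubin potential scale reduction factor R-hat.

    With m chains of length n, within-chain variance W and between-chain
    variance B (n times the variance of chain means), the pooled posterior
    variance estimate is ``(n-1)/n * W + B/n`` and R-hat is the square root
    of its ratio to W. Values near 1 indicate convergence.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = arr.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    chain_means = arr.mean(axis=1)
    w = float(arr.var(axis=1, ddof=1).mean())
    if w <= 0.0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    b = n * float(chain_means.var(ddof=1))
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
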