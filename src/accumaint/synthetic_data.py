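"""Synthetic-data generators for every input of the pipeline.

Three families of inputs are produced:

* **DDM-based trial tables** — choices and response times simulated from a
  two-boundary drift diffusion (Euler-Maruyama integration of the Wiener
  process with drift), for the reaction-time (RT) condition, plus a
  delayed-response (DR) variant where the accumulated evidence state at
  the response cue determines the choice and the response time is a motor
  latency independent of difficulty.
* **Hierarchical behavioral trial tables** — data drawn from exactly the
  generative structure the behavior fitters assume: subject-level means
  from group distributions, gamma-distributed trial RTs and binomial
  correct counts.
* **Meta-analysis corpora** — an article database with term annotations
  and MNI activation foci, with configurable planted term-region
  associations, emulating a merged coordinate-based meta-analysis corpus.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .design import ExperimentDesign, empty_trial_table, make_trial_table

__all__ = [
    "GenParamsDDM",
    "HierBehaviorParams",
    "CorpusSpec",
    "PlantedAssociation",
    "simulate_ddm_dataset",
    "simulate_dr_dataset",
    "simulate_hier_behavior",
    "generate_meta_corpus",
    "default_ddm_params",
]


# ---------------------------------------------------------------------------
# drift-diffusion trial generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenParamsDDM:
    """Per-subject generating DDM parameters.

    drift_per_level / boundary_per_level map coherence level (1..4) to the
    drift rate v (evidence units/s) and boundary separation a. The start
    point sits midway between the boundaries (z = a/2, no response bias)
    and the diffusion scale is fixed at s = 1, the standard convention.
    sv is the between-trial standard deviation of the drift, st the width
    of the uniform between-trial non-decision-time jitter.
    """

    drift_per_level: dict
    boundary_per_level: dict
    t_nd: float = 0.3
    sv: float = 0.0
    st: float = 0.0

    def __post_init__(self):
        if any(a <= 0 for a in self.boundary_per_level.values()):
            raise ValueError("boundary separation must be positive")
        if self.t_nd < 0 or self.sv < 0 or self.st < 0:
            raise ValueError("t_nd, sv and st must be non-negative")


def default_ddm_params(
    drifts=(2.2, 1.8, 1.0, 0.6), boundary: float = 1.5, t_nd: float = 0.3,
    sv: float = 0.0, st: float = 0.0,
) -> GenParamsDDM:
    """Convenience constructor: one boundary, four difficulty-ordered drifts."""
    return GenParamsDDM(
        drift_per_level={lvl: v for lvl, v in zip((1, 2, 3, 4), drifts)},
        boundary_per_level={lvl: boundary for lvl in (1, 2, 3, 4)},
        t_nd=t_nd,
        sv=sv,
        st=st,
    )


@njit(cache=True)
def _simulate_trials(v, a, z, t_nd, sv, st, deadline, dt, seeds):
    """Euler-Maruyama first-passage simulation for a batch of trials.

    Returns (choice_upper, rt, hit) arrays: choice_upper is 1 if the upper
    boundary was reached first, rt the full response time including
    non-decision time, hit 0 for trials still undecided at the deadline.
    Evidence starts at z in (0, a); the final evidence state is returned
    for the delayed-response variant.
    """
    n = v.shape[0]
    choice_upper = np.zeros(n, dtype=np.int8)
    rt = np.full(n, np.nan)
    hit = np.zeros(n, dtype=np.int8)
    state = np.zeros(n)
    sqrt_dt = np.sqrt(dt)
    for i in range(n):
        np.random.seed(seeds[i])
        vi = v[i]
        if sv > 0.0:
            vi = vi + sv * np.random.standard_normal()
        ti = t_nd
        if st > 0.0:
            ti = t_nd + st * (np.random.random() - 0.5)
        x = z[i]
        t = 0.0
        max_t = deadline - ti
        decided = False
        while t < max_t:
            x += vi * dt + sqrt_dt * np.random.standard_normal()
            t += dt
            if x >= a[i]:
                choice_upper[i] = 1
                rt[i] = t + ti
                hit[i] = 1
                decided = True
                x = a[i]
                break
            if x <= 0.0:
                choice_upper[i] = 0
                rt[i] = t + ti
                hit[i] = 1
                decided = True
                x = 0.0
                break
        if not decided:
            rt[i] = np.nan
        state[i] = x
    return choice_upper, rt, hit, state


def _assign_trials(design: ExperimentDesign, condition: str, rng: np.random.Generator):
    """Balanced stimulus x level assignment for one subject's runs of *condition*."""
    n_runs = sum(1 for r in design.runs if r == condition)
    stims, levels = [], []
    for _ in range(n_runs):
        cells = [(s, l) for s in ("face", "house") for l in (1, 2, 3, 4)]
        reps = int(np.ceil(design.trials_per_run / len(cells)))
        pool = (cells * reps)[: design.trials_per_run]
        order = rng.permutation(len(pool))
        for k in order:
            stims.append(pool[k][0])
            levels.append(pool[k][1])
    return np.array(stims), np.array(levels, dtype=int)


def _trial_seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2**31 - 1, size=n).astype(np.int64)


def simulate_ddm_dataset(
    design: ExperimentDesign,
    params: dict[int, GenParamsDDM] | GenParamsDDM,
    seed: int,
    dt: float = 0.0005,
) -> pd.DataFrame:
    """Simulate the reaction-time condition from the drift diffusion model.

    Noisy evidence for the two responses is subtracted and accumulated from
    z = a/2 until one of the boundaries at 0 / a is reached; the upper
    boundary codes the correct response. Trials not resolved within the
    stimulus window are marked ``missed`` (window censoring, which also
    produces the handful-of-percent missed-trial rate seen in practice).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    per_subject = _normalize_params(design, params)
    frames = []
    for subj in range(1, design.n_subjects + 1):
        p = per_subject[subj]
        stims, levels = _assign_trials(design, "RT", rng)
        n = stims.size
        v = np.array([p.drift_per_level[l] for l in levels])
        a = np.array([p.boundary_per_level[l] for l in levels])
        z = a / 2.0
        choice_upper, rt, hit, _ = _simulate_trials(
            v, a, z, p.t_nd, p.sv, p.st, design.stimulus_window_s, dt, _trial_seeds(rng, n)
        )
        correct_choice = stims
        wrong_choice = np.where(stims == "face", "house", "face")
        choice = np.where(hit == 1, np.where(choice_upper == 1, correct_choice, wrong_choice), "missed")
        frames.append(
            make_trial_table(
                {
                    "subject": subj,
                    "condition": "RT",
                    "coherence_level": levels,
                    "stimulus": stims,
                    "choice": choice,
                    "correct": (choice == stims),
                    "rt": np.where(hit == 1, rt, np.nan),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else empty_trial_table()


def simulate_dr_dataset(
    design: ExperimentDesign,
    params: dict[int, GenParamsDDM] | GenParamsDDM,
    seed: int,
    dt: float = 0.0005,
    motor_latency_mean: float = 0.25,
    motor_latency_sd: float = 0.04,
) -> pd.DataFrame:
    """Simulate the delayed-response condition.

    Evidence accumulates throughout the stimulus window plus the cued
    delay; at the response cue the choice is read out from the accumulated
    state (the boundary already reached, or the sign of the state relative
    to the midpoint). Because accumulation continues past the RT-condition
    deadline, accuracy is higher than under immediate responding. The
    recorded rt is a motor latency measured from cue onset, drawn
    independently of difficulty and censored at the response window.
    """
    if design.n_dr_runs < 1:
        raise ValueError("design contains no DR run")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    per_subject = _normalize_params(design, params)
    cue_time = design.stimulus_window_s + design.dr_delay_s
    frames = []
    for subj in range(1, design.n_subjects + 1):
        p = per_subject[subj]
        stims, levels = _assign_trials(design, "DR", rng)
        n = stims.size
        v = np.array([p.drift_per_level[l] for l in levels])
        a = np.array([p.boundary_per_level[l] for l in levels])
        z = a / 2.0
        choice_upper, _, hit, state = _simulate_trials(
            v, a, z, p.t_nd, p.sv, p.st, cue_time, dt, _trial_seeds(rng, n)
        )
        # read out the frozen evidence state at the cue: boundary if hit,
        # otherwise the sign of the state relative to the unbiased start
        upper = np.where(hit == 1, choice_upper == 1, state > z)
        ties = (hit == 0) & (state == z)
        if ties.any():
            upper = np.where(ties, rng.random(n) < 0.5, upper)
        latency = motor_latency_mean + motor_latency_sd * rng.standard_normal(n)
        latency = np.maximum(latency, 1e-3)
        answered = latency <= design.dr_response_window_s
        correct_choice = stims
        wrong_choice = np.where(stims == "face", "house", "face")
        choice = np.where(answered, np.where(upper, correct_choice, wrong_choice), "missed")
        frames.append(
            make_trial_table(
                {
                    "subject": subj,
                    "condition": "DR",
                    "coherence_level": levels,
                    "stimulus": stims,
                    "choice": choice,
                    "correct": (choice == stims),
                    "rt": np.where(answered, latency, np.nan),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else empty_trial_table()


def _normalize_params(design, params):
    if isinstance(params, GenParamsDDM):
        return {s: params for s in range(1, design.n_subjects + 1)}
    missing = [s for s in range(1, design.n_subjects + 1) if s not in params]
    if missing:
        raise ValueError(f"missing DDM parameters for subjects {missing}")
    return params


def sample_subject_ddm_params(
    group: GenParamsDDM,
    n_subjects: int,
    seed: int,
    drift_sd: float = 0.3,
    boundary_sd: float = 0.1,
    t_sd: float = 0.02,
) -> dict[int, GenParamsDDM]:
    """Draw per-subject parameters around group values.

    Drifts are normal around the group drift; boundaries and non-decision
    times are log-normal (multiplicative jitter) so they stay positive.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for subj in range(1, n_subjects + 1):
        drifts = {
            l: float(v + drift_sd * rng.standard_normal())
            for l, v in group.drift_per_level.items()
        }
        bounds = {
            l: float(a * np.exp(boundary_sd / a * rng.standard_normal()))
            for l, a in group.boundary_per_level.items()
        }
        t_nd = float(group.t_nd * np.exp(t_sd / max(group.t_nd, 1e-6) * rng.standard_normal()))
        out[subj] = GenParamsDDM(
            drift_per_level=drifts,
            boundary_per_level=bounds,
            t_nd=t_nd,
            sv=group.sv,
            st=group.st,
        )
    return out


# ---------------------------------------------------------------------------
# hierarchical behavioral generation (the fitters' own generative model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierBehaviorParams:
    """Group-level generating parameters for the hierarchical behavior models.

    accuracy_mean / rt_mean map coherence level -> group mean; the *_sd
    values are the between-subject spread of subject means and the trial
    sds of the within-subject likelihoods (gamma for RTs; the accuracy
    likelihood is binomial so it has no free trial sd).
    """

    accuracy_mean: dict = field(
        default_factory=lambda: {1: 0.92, 2: 0.84, 3: 0.72, 4: 0.64}
    )
    accuracy_subject_sd: float = 0.05
    rt_mean: dict = field(default_factory=lambda: {1: 0.60, 2: 0.64, 3: 0.72, 4: 0.76})
    rt_subject_sd: float = 0.05
    rt_trial_sd: float = 0.10

    def __post_init__(self):
        for lvl, m in self.accuracy_mean.items():
            if not 0.0 < m < 1.0:
                raise ValueError("accuracy means must be in (0,1)")
            if self.accuracy_subject_sd**2 >= m * (1 - m):
                raise ValueError(
                    f"between-subject accuracy variance >= mu(1-mu) at level {lvl}; "
                    "no beta distribution has this mean/variance pair"
                )
        if any(m <= 0 for m in self.rt_mean.values()):
            raise ValueError("rt means must be positive")
        if self.rt_subject_sd <= 0 or self.rt_trial_sd <= 0:
            raise ValueError("rt sds must be positive")


def _beta_ab(mean: float, var: float) -> tuple[float, float]:
    """Moment mapping from (mean, variance) to beta (alpha, beta)."""
    if var >= mean * (1 - mean):
        raise ValueError("variance must be below mu(1-mu) for a beta distribution")
    kappa = mean * (1 - mean) / var - 1.0
    return mean * kappa, (1 - mean) * kappa


def simulate_hier_behavior(
    design: ExperimentDesign,
    params: HierBehaviorParams,
    seed: int,
    condition: str = "RT",
    trials_per_level: int | None = None,
) -> pd.DataFrame:
    """Draw trials from the hierarchical behavior models' own structure.

    Subject accuracy means come from a beta distribution around the group
    mean; correct/error outcomes are Bernoulli. Subject RT means come from
    a normal around the group mean (truncated positive) and trial RTs are
    gamma with the subject mean and the trial sd. Correctness and RT are
    generated independently — matching the separate accuracy and RT models.
    """
    if condition not in ("RT", "DR"):
        raise ValueError("condition must be RT or DR")
    rng = np.random.default_rng(seed)
    if design.n_subjects == 0:
        return empty_trial_table()
    n_runs = sum(1 for r in design.runs if r == condition)
    if trials_per_level is None:
        trials_per_level = (n_runs * design.trials_per_run) // 4
    frames = []
    for subj in range(1, design.n_subjects + 1):
        for lvl in (1, 2, 3, 4):
            m = params.accuracy_mean[lvl]
            a_, b_ = _beta_ab(m, params.accuracy_subject_sd**2)
            theta = rng.beta(a_, b_)
            mu = -1.0
            while mu <= 0.05:
                mu = params.rt_mean[lvl] + params.rt_subject_sd * rng.standard_normal()
            shape = mu**2 / params.rt_trial_sd**2
            rate = mu / params.rt_trial_sd**2
            n = trials_per_level
            half = n // 2
            stim = np.array(["face"] * half + ["house"] * (n - half))
            correct = rng.random(n) < theta
            rts = rng.gamma(shape, 1.0 / rate, size=n)
            choice = np.where(correct, stim, np.where(stim == "face", "house", "face"))
            frames.append(
                make_trial_table(
                    {
                        "subject": subj,
                        "condition": condition,
                        "coherence_level": lvl,
                        "stimulus": stim,
                        "choice": choice,
                        "correct": correct,
                        "rt": rts,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# synthetic meta-analysis corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedAssociation:
    """A term-region association planted into the synthetic corpus."""

    term: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0
    p_activation_given_term: float = 0.8
    base_rate: float = 0.1

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")
        for p in (self.p_activation_given_term, self.base_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")


@dataclass(frozen=True)
class CorpusSpec:
    """Layout of the synthetic article corpus.

    Emulates a merged coordinate-based meta-analysis database: each article
    carries a set of cognitive terms and a list of MNI activation foci.
    Articles mentioning a planted term place a focus inside the planted
    region with ``p_activation_given_term``; all other articles do so at
    ``base_rate``; remaining foci fall uniformly in a brain bounding box.
    """

    n_articles: int = 1000
    term_list: tuple = ("decision", "memory", "attention", "language", "motor")
    term_prevalence: dict | float = 0.2
    planted: tuple = ()
    foci_per_article_mean: float = 8.0
    brain_box_mm: tuple = ((-78.0, 78.0), (-112.0, 76.0), (-70.0, 86.0))

    def __post_init__(self):
        if not self.term_list:
            raise ValueError("term list must be non-empty")
        prev = self.term_prevalence
        if isinstance(prev, dict):
            vals = prev.values()
        else:
            vals = [prev]
        if any(not 0.0 <= p <= 1.0 for p in vals):
            raise ValueError("prevalences must be in [0,1]")

    def prevalence_of(self, term: str) -> float:
        if isinstance(self.term_prevalence, dict):
            return self.term_prevalence.get(term, 0.0)
        return float(self.term_prevalence)


def generate_meta_corpus(spec: CorpusSpec, seed: int):
    """Generate (term annotations, foci, planted map) for a synthetic corpus.

    Returns ``(terms, foci, planted_map)`` where ``terms`` maps article id
    -> set of terms, ``foci`` maps article id -> list of [x, y, z] MNI mm
    coordinates, and ``planted_map`` records each planted association for
    downstream recovery checks.
    """
    rng = np.random.default_rng(seed)
    planted_by_term = {p.term: p for p in spec.planted}
    terms: dict[int, set] = {}
    foci: dict[int, list] = {}
    (x0, x1), (y0, y1), (z0, z1) = spec.brain_box_mm
    for art in range(1, spec.n_articles + 1):
        tset = {t for t in spec.term_list if rng.random() < spec.prevalence_of(t)}
        n_foci = int(rng.poisson(spec.foci_per_article_mean))
        pts = []
        for p in planted_by_term.values():
            prob = p.p_activation_given_term if p.term in tset else p.base_rate
            if rng.random() < prob:
                # uniform inside the planted sphere
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                r = p.radius_mm * rng.random() ** (1 / 3)
                pts.append(list(np.asarray(p.center_mm) + r * direction))
        n_background = max(n_foci - len(pts), 0)
        bg = np.column_stack(
            [
                rng.uniform(x0, x1, n_background),
                rng.uniform(y0, y1, n_background),
                rng.uniform(z0, z1, n_background),
            ]
        )
        pts.extend(bg.tolist())
        terms[art] = tset
        foci[art] = [[float(c) for c in p] for p in pts]
    planted_map = {
        p.term: {
            "center_mm": list(p.center_mm),
            "radius_mm": p.radius_mm,
            "p_activation_given_term": p.p_activation_given_term,
            "base_rate": p.base_rate,
        }
        for p in spec.planted
    }
    return terms, foci, planted_map


def corpus_to_json(terms: dict, foci: dict) -> dict:
    """Serializable corpus: list of {id, terms, foci} articles."""
    return {
        "articles": [
            {"id": art, "terms": sorted(terms[art]), "foci": foci[art]}
            for art in sorted(terms)
        ]
    }


def corpus_from_json(obj: dict):
    terms = {a["id"]: set(a["terms"]) for a in obj["articles"]}
    foci = {a["id"]: [list(map(float, f)) for f in a["foci"]] for a in obj["articles"]}
    return terms, foci
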