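"""Forward model from decision-neuron firing to predicted BOLD.

Monkey accumulator neurons (e.g. in area LIP) ramp from a baseline firing
rate BL to a decision threshold T, faster for easy than hard decisions,
and — when the response is cued after a delay — hold firing at threshold
until the response is executed. The competing hypothesis for humans is an
accumulate-only population that stops firing once the boundary is reached.

Convolving these firing profiles with the canonical double-gamma
hemodynamic response function yields predicted BOLD time courses. A region
that both accumulates and maintains predicts a response-mode x difficulty
crossover: more activity for hard than easy decisions under immediate
(reaction-time, RT) responding, but more for easy than hard under delayed
responding (DR), because the easy decision reaches threshold sooner and is
then maintained longer. An accumulate-only region predicts hard > easy in
both response modes and no crossover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FiringParams",
    "FiringProfile",
    "BoldCurve",
    "HRFParams",
    "firing_profile",
    "canonical_hrf",
    "predict_bold",
    "crossover_summary",
    "InteractionSummary",
]

ACCUMULATE_MAINTAIN = "accumulate_maintain"
ACCUMULATE_ONLY = "accumulate_only"


@dataclass(frozen=True)
class FiringParams:
    """Schematic firing-rate model of a decision population.

    time_to_threshold maps difficulty label -> seconds from stimulus onset
    to boundary crossing (hard must be slower than easy). maintenance_until
    is the response-cue time for the DR condition (None for RT, where the
    response follows the boundary crossing immediately).
    """

    baseline_hz: float = 5.0
    threshold_hz: float = 50.0
    time_to_threshold: dict | None = None
    maintenance_until: float | None = 1.5
    post_response_decay_s: float = 0.0
    mode: str = ACCUMULATE_MAINTAIN

    def __post_init__(self):
        ttt = self.time_to_threshold or {"easy": 0.4, "hard": 0.8}
        object.__setattr__(self, "time_to_threshold", dict(ttt))
        if self.threshold_hz <= self.baseline_hz:
            raise ValueError("threshold must exceed baseline")
        if any(v <= 0 for v in self.time_to_threshold.values()):
            raise ValueError("time_to_threshold must be positive")
        if {"easy", "hard"} <= set(self.time_to_threshold):
            if self.time_to_threshold["hard"] <= self.time_to_threshold["easy"]:
                raise ValueError("hard decisions must reach threshold later than easy ones")
        if self.mode not in (ACCUMULATE_MAINTAIN, ACCUMULATE_ONLY):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FiringProfile:
    dt: float
    values: np.ndarray  # Hz, uniform grid starting at t=0
    baseline_hz: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("firing rates must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass(frozen=True)
class BoldCurve:
    dt: float
    values: np.ndarray  # arbitrary units

    @property
    def t(self) -> np.ndarray:
        return np.arange(np.asarray(self.values).size) * self.dt

    def integral(self) -> float:
        return float(np.sum(self.values) * self.dt)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (SPM-style defaults)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self):
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion",
            "undershoot_dispersion",
            "peak_undershoot_ratio",
            "kernel_length_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def firing_profile(
    params: FiringParams,
    difficulty: str,
    condition: str,
    dt: float = 0.01,
    total_s: float | None = None,
) -> FiringProfile:
    """Piecewise-linear firing rate for one difficulty x condition cell.

    The rate ramps linearly from baseline to threshold over
    ``time_to_threshold[difficulty]``. What happens at threshold depends on
    the hypothesis: an accumulate-and-maintain population in the DR
    condition holds threshold firing until the response cue
    (``maintenance_until``); in all other cases firing returns to baseline
    at the boundary crossing (instantaneously by default, exponentially if
    ``post_response_decay_s > 0``).
    """
    if condition not in ("RT", "DR"):
        raise ValueError("condition must be RT or DR")
    ttt = params.time_to_threshold[difficulty]
    maintain = condition == "DR" and params.mode == ACCUMULATE_MAINTAIN
    if maintain:
        if params.maintenance_until is None:
            raise ValueError("DR condition requires maintenance_until (cue time)")
        if params.maintenance_until < ttt:
            raise ValueError(
                "response cue precedes boundary crossing; the maintenance "
                "prediction assumes accumulation completes before the cue"
            )
    end_active = params.maintenance_until if maintain else ttt
    if total_s is None:
        total_s = end_active + max(5 * params.post_response_decay_s, 1.0)
    t = np.arange(0.0, total_s + dt / 2, dt)
    bl, th = params.baseline_hz, params.threshold_hz
    values = np.full_like(t, bl)
    ramp = t <= ttt
    values[ramp] = bl + (th - bl) * t[ramp] / ttt
    if maintain:
        values[(t > ttt) & (t <= end_active)] = th
    after = t > end_active
    if params.post_response_decay_s > 0:
        tau = params.post_response_decay_s
        values[after] = bl + (th - bl) * np.exp(-(t[after] - end_active) / tau)
    else:
        values[after] = bl
    return FiringProfile(dt=dt, values=values, baseline_hz=bl)


def canonical_hrf(dt: float, hrf: HRFParams | None = None) -> np.ndarray:
    """Double-gamma HRF kernel on a grid of spacing *dt*, scaled to unit peak.

    The kernel is the difference of two gamma densities: a positive lobe
    peaking near ``peak_delay_s`` and an undershoot near
    ``undershoot_delay_s`` scaled by ``1 / peak_undershoot_ratio``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    hrf = hrf or HRFParams()
    t = np.arange(0.0, hrf.kernel_length_s + dt / 2, dt)
    peak = stats.gamma.pdf(t, a=hrf.peak_delay_s / hrf.peak_dispersion, scale=hrf.peak_dispersion)
    under = stats.gamma.pdf(
        t, a=hrf.undershoot_delay_s / hrf.undershoot_dispersion, scale=hrf.undershoot_dispersion
    )
    kernel = peak - under / hrf.peak_undershoot_ratio
    return kernel / kernel.max()


def predict_bold(profile: FiringProfile, kernel: np.ndarray, kernel_dt: float | None = None) -> BoldCurve:
    """BOLD prediction: baseline-deviation firing convolved with the HRF.

    Linear in (profile - baseline); the output grid spans the profile plus
    the kernel tail.
    """
    if kernel_dt is not None and abs(kernel_dt - profile.dt) > 1e-12:
        raise ValueError("profile and kernel must share the same dt")
    deviation = profile.values - profile.baseline_hz
    bold = np.convolve(deviation, np.asarray(kernel, dtype=float)) * profile.dt
    return BoldCurve(dt=profile.dt, values=bold)


@dataclass(frozen=True)
class InteractionSummary:
    """Integrated BOLD amplitude per cell and the crossover-interaction test."""

    amplitude: dict  # (condition, difficulty) -> integrated BOLD
    hard_minus_easy_rt: float
    easy_minus_hard_dr: float
    crossover: bool


def crossover_summary(
    bold_easy_rt: BoldCurve,
    bold_hard_rt: BoldCurve,
    bold_easy_dr: BoldCurve,
    bold_hard_dr: BoldCurve,
) -> InteractionSummary:
    """Test for the response-mode x difficulty crossover interaction.

    The crossover flag is true iff hard > easy under RT *and* easy > hard
    under DR (integrated amplitudes) — the signature of a region that both
    accumulates evidence and maintains the choice.
    """
    curves = (bold_easy_rt, bold_hard_rt, bold_easy_dr, bold_hard_dr)
    dts = {c.dt for c in curves}
    if len(dts) > 1:
        raise ValueError("curves must share one time grid")
    amp = {
        ("RT", "easy"): bold_easy_rt.integral(),
        ("RT", "hard"): bold_hard_rt.integral(),
        ("DR", "easy"): bold_easy_dr.integral(),
        ("DR", "hard"): bold_hard_dr.integral(),
    }
    d_rt = amp[("RT", "hard")] - amp[("RT", "easy")]
    d_dr = amp[("DR", "easy")] - amp[("DR", "hard")]
    return InteractionSummary(
        amplitude=amp,
        hard_minus_easy_rt=d_rt,
        easy_minus_hard_dr=d_dr,
        crossover=bool(d_rt > 0 and d_dr > 0),
    )
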