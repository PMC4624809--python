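"""Experimental design and per-trial data containers.

The task is a two-alternative forced choice (2AFC) face/house discrimination
with four phase-coherence (difficulty) levels per stimulus class, run in two
response modes: a reaction-time (RT) condition where the response is given
during the 1 s stimulus window, and a delayed-response (DR) condition where
the response follows a 500 ms cued delay inside a 500 ms response window.

Trial tables are plain :class:`pandas.DataFrame` objects with the columns
``subject, condition, coherence_level, stimulus, choice, correct, rt`` and
round-trip through CSV unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: canonical column order of a trial table
TRIAL_COLUMNS = ["subject", "condition", "coherence_level", "stimulus", "choice", "correct", "rt"]

#: proportion phase coherence per level (1 = easiest .. 4 = hardest), per stimulus
#: class; levels 1/2 are the "easy" group and 3/4 the "hard" group
DEFAULT_COHERENCE = {
    "face": (0.53, 0.50, 0.445, 0.427),
    "house": (0.54, 0.51, 0.465, 0.437),
}

EASY_LEVELS = (1, 2)
HARD_LEVELS = (3, 4)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the behavioral study.

    Defaults mirror the study conditions: 18 participants, three runs of 112
    trials (RT, DR, RT), a 1 s stimulus window, a 0.5 s cued delay and a
    0.5 s response window in the DR condition.
    """

    n_subjects: int = 18
    trials_per_run: int = 112
    runs: tuple[str, ...] = ("RT", "DR", "RT")
    coherence: dict = field(default_factory=lambda: dict(DEFAULT_COHERENCE))
    stimulus_window_s: float = 1.0
    dr_delay_s: float = 0.5
    dr_response_window_s: float = 0.5

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.trials_per_run < 1:
            raise ValueError("trials_per_run must be >= 1")
        for cond in self.runs:
            if cond not in ("RT", "DR"):
                raise ValueError(f"unknown run condition {cond!r}")
        for stim, levels in self.coherence.items():
            if len(levels) != 4 or not all(0.0 < c < 1.0 for c in levels):
                raise ValueError(f"coherence for {stim!r} must be 4 proportions in (0,1)")
        if self.stimulus_window_s <= 0 or self.dr_delay_s <= 0 or self.dr_response_window_s <= 0:
            raise ValueError("all time windows must be positive")

    @property
    def n_rt_runs(self) -> int:
        return sum(1 for r in self.runs if r == "RT")

    @property
    def n_dr_runs(self) -> int:
        return sum(1 for r in self.runs if r == "DR")


def empty_trial_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": pd.Series(dtype=int),
            "condition": pd.Series(dtype=str),
            "coherence_level": pd.Series(dtype=int),
            "stimulus": pd.Series(dtype=str),
            "choice": pd.Series(dtype=str),
            "correct": pd.Series(dtype=bool),
            "rt": pd.Series(dtype=float),
        }
    )


def make_trial_table(records: dict) -> pd.DataFrame:
    """Assemble a trial table from column arrays, enforcing column order."""
    df = pd.DataFrame(records)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    return df[TRIAL_COLUMNS]


def validate_trial_table(df: pd.DataFrame, design: ExperimentDesign | None = None) -> None:
    """Raise ValueError if *df* violates the trial-table contract."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    if not df["condition"].isin(["RT", "DR"]).all():
        raise ValueError("condition must be RT or DR")
    if not df["coherence_level"].isin([1, 2, 3, 4]).all():
        raise ValueError("coherence_level must be in 1..4")
    if not df["choice"].isin(["face", "house", "missed"]).all():
        raise ValueError("choice must be face, house or missed")
    answered = df["choice"] != "missed"
    bad = answered & (df["correct"] != (df["choice"] == df["stimulus"]))
    if bad.any():
        raise ValueError("correct flag inconsistent with choice == stimulus")
    if design is not None:
        rts = df.loc[answered & (df["condition"] == "RT"), "rt"]
        if (rts > design.stimulus_window_s + 1e-12).any():
            raise ValueError("RT-condition rt exceeds the stimulus window")
        rts = df.loc[answered & (df["condition"] == "DR"), "rt"]
        if (rts > design.dr_response_window_s + 1e-12).any():
            raise ValueError("DR-condition rt exceeds the response window")


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trial_table(df)
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df[TRIAL_COLUMNS].to_csv(path, index=False)


def correct_counts(df: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Per subject x coherence level: number correct ``z`` and trials ``n``.

    Missed trials are excluded (the models describe given responses only).
    """
    sub = df[(df["condition"] == condition) & (df["choice"] != "missed")]
    g = sub.groupby(["subject", "coherence_level"])["correct"]
    out = g.agg(z="sum", n="count").reset_index()
    out["z"] = out["z"].astype(int)
    return out
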