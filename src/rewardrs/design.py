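"""Event-related task designs for the monetary reward task.

Each trial shows a fractal cue (2000 ms), a jittered ISI, a word stimulus
(2000 ms, anxiety-provoking or neutral depending on the session), a brief
250 ms gap, then reward/non-reward feedback; a second jittered ISI closes
the trial. Rewards are Bernoulli(0.5), independent of behaviour. A session
holds 60 trials of a single word type inside a 487-volume, TR = 1 s run.

Jitters are drawn from the discrete set {1250, 1500, ..., 2500} ms. Because
unconstrained i.i.d. jitters would not always fit the run, the per-jitter
increments above the 1250 ms floor are sampled under the run-length budget
and then randomly permuted across slots, so the design always fits and no
slot is systematically shorter than another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHASES = ("fractal", "word", "feedback")
WORD_TYPES = ("anxiety", "neutral")


@dataclass(frozen=True)
class TaskConfig:
    """Timing parameters of one scanning session (durations in ms)."""

    tr: float = 1.0                 # seconds
    n_volumes: int = 487
    n_trials: int = 60
    fractal_ms: int = 2000
    word_ms: int = 2000
    pre_feedback_isi_ms: int = 250
    feedback_ms: int = 1000         # not reported by the task description; configurable
    jitter_min_ms: int = 1250
    jitter_max_ms: int = 2500
    jitter_step_ms: int = 250
    reward_prob: float = 0.5

    @property
    def run_seconds(self) -> float:
        return self.n_volumes * self.tr

    @property
    def fixed_trial_ms(self) -> int:
        return (self.fractal_ms + self.word_ms + self.pre_feedback_isi_ms
                + self.feedback_ms)


@dataclass(frozen=True)
class TrialEvent:
    onset: float          # seconds from run start
    duration: float       # seconds
    phase: str            # fractal | word | feedback
    trial_index: int
    word_type: str
    rewarded: bool

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class SessionDesign:
    """Ordered trial events of one session plus run geometry."""

    events: list[TrialEvent]
    word_type: str
    tr: float
    n_volumes: int

    @property
    def n_trials(self) -> int:
        return len({e.trial_index for e in self.events})

    @property
    def rewarded(self) -> np.ndarray:
        """Per-trial reward outcome, ordered by trial index."""
        out = {}
        for e in self.events:
            out[e.trial_index] = e.rewarded
        return np.array([out[i] for i in sorted(out)], dtype=bool)

    def phase_events(self, phase: str) -> list[TrialEvent]:
        return [e for e in self.events if e.phase == phase]

    def feedback_events(self, rewarded: bool | None = None) -> list[TrialEvent]:
        evs = self.phase_events("feedback")
        if rewarded is None:
            return evs
        return [e for e in evs if e.rewarded == rewarded]


def _sample_jitters(rng: np.random.Generator, n_jitters: int,
                    cfg: TaskConfig, budget_ms: int) -> np.ndarray:
    """Discrete jitters whose total stays within ``budget_ms``.

    Increments above the floor are drawn sequentially from the still-
    affordable sub-range, then permuted so that the constraint does not
    bias late slots. When the budget covers the maximum jitter everywhere,
    this reduces to i.i.d. uniform draws over the full discrete set.
    """
    step = cfg.jitter_step_ms
    max_extra = cfg.jitter_max_ms - cfg.jitter_min_ms
    slack = budget_ms - n_jitters * cfg.jitter_min_ms
    if slack < 0:
        raise ValueError(
            "design cannot fit in run length: increase n_volumes or reduce "
            "n_trials")
    extras = np.empty(n_jitters, dtype=int)
    remaining = slack
    for k in range(n_jitters):
        allowed = min(max_extra, (remaining // step) * step)
        extras[k] = step * rng.integers(0, allowed // step + 1)
        remaining -= extras[k]
    rng.shuffle(extras)
    return cfg.jitter_min_ms + extras


def generate_session_design(word_type: str, seed: int,
                            cfg: TaskConfig = TaskConfig()) -> SessionDesign:
    """Generate one seeded session design.

    Reward outcomes are i.i.d. Bernoulli(``cfg.reward_prob``); jitters come
    from the discrete 1250-2500 ms set under the run-length budget. The
    same seed always reproduces the same event table.
    """
    if word_type not in WORD_TYPES:
        raise ValueError(f"word_type must be one of {WORD_TYPES}")
    rng = np.random.default_rng(seed)
    n = cfg.n_trials
    rewarded = rng.random(n) < cfg.reward_prob

    run_ms = int(round(cfg.run_seconds * 1000))
    fixed_total = n * cfg.fixed_trial_ms
    budget = run_ms - fixed_total
    n_jitters = 2 * n
    if budget < n_jitters * cfg.jitter_min_ms:
        deficit = n_jitters * cfg.jitter_min_ms + fixed_total - run_ms
        raise ValueError(
            f"design cannot fit in run length ({run_ms} ms): needs at least "
            f"{deficit} ms more; increase n_volumes or reduce n_trials")
    jitters = _sample_jitters(rng, n_jitters, cfg, budget)

    events: list[TrialEvent] = []
    t_ms = 0
    for i in range(n):
        events.append(TrialEvent(t_ms / 1000, cfg.fractal_ms / 1000,
                                 "fractal", i, word_type, bool(rewarded[i])))
        t_ms += cfg.fractal_ms + jitters[2 * i]
        events.append(TrialEvent(t_ms / 1000, cfg.word_ms / 1000,
                                 "word", i, word_type, bool(rewarded[i])))
        t_ms += cfg.word_ms + cfg.pre_feedback_isi_ms
        events.append(TrialEvent(t_ms / 1000, cfg.feedback_ms / 1000,
                                 "feedback", i, word_type, bool(rewarded[i])))
        t_ms += cfg.feedback_ms + jitters[2 * i + 1]
    assert t_ms <= run_ms, "internal error: design overruns the session"
    return SessionDesign(events, word_type, cfg.tr, cfg.n_volumes)


# ---------------------------------------------------------------------------
# BIDS-style events tables


def design_to_table(design: SessionDesign) -> pd.DataFrame:
    """Events table with columns onset, duration, trial_type, trial_index, rewarded."""
    rows = [(e.onset, e.duration, e.phase, e.trial_index, int(e.rewarded))
            for e in design.events]
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type",
                                       "trial_index", "rewarded"])


def table_to_design(table: pd.DataFrame, word_type: str, tr: float,
                    n_volumes: int) -> SessionDesign:
    events = [TrialEvent(float(r.onset), float(r.duration), str(r.trial_type),
                         int(r.trial_index), word_type, bool(r.rewarded))
              for r in table.itertuples()]
    return SessionDesign(events, word_type, tr, n_volumes)


def write_events_tsv(design: SessionDesign, path) -> None:
    design_to_table(design).to_csv(path, sep="\t", index=False,
                                   float_format="%.3f")


def read_events_tsv(path, word_type: str, tr: float,
                    n_volumes: int) -> SessionDesign:
    table = pd.read_csv(path, sep="\t")
    return table_to_design(table, word_type, tr, n_volumes)
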