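"""Experimental design for the duration-reproduction experiments.

Builds counterbalanced trial tables for the four-condition design
(SS: stable target + stable distractor, FS: flickering target + stable
distractor, SFi: stable target + flickering ipsilateral distractor,
SFc: stable target + flickering contralateral distractor), assigns
distractor timing for either the long-distractor variant (experiment 1)
or the jittered near-equal-duration variant (experiment 2), and exposes
the on-screen stimulus geometry.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("SS", "FS", "SFi", "SFc")
TARGET_DURATIONS_MS: tuple[int, ...] = (450, 650, 850)

#: target-side sequence over the four sessions, counterbalanced across
#: participants (L-R-R-L for odd participants, R-L-L-R for even).
SIDE_SEQUENCES: dict[str, tuple[str, ...]] = {
    "LRRL": ("L", "R", "R", "L"),
    "RLLR": ("R", "L", "L", "R"),
}

#: columns of a skeleton trial table, before responses are simulated
DESIGN_COLUMNS = [
    "participant_id",
    "session",
    "trial_index",
    "condition",
    "target_side",
    "distractor_side",
    "target_duration_ms",
]


class ConfigError(ValueError):
    """Raised when a design configuration cannot produce a balanced design."""


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of one duration-reproduction experiment.

    Parameters
    ----------
    experiment
        1 for the long-distractor design (distractor onset 2000-2500 ms
        before the target, offset 1000-1500 ms after it); 2 for the
        jittered design where distractor onset/offset asynchronies are
        uniform on +/- ``jitter_frac`` x target duration.
    n_participants, n_sessions, reps_per_cell
        Sample size and repetitions of each condition x duration cell
        per session (defaults 4 sessions x 15 reps, i.e. 180
        trials/session and, after side merging, 60 trials per condition
        per target duration).
    gaze_break_prob
        Per-trial probability that the simulated maximum gaze deviation
        exceeds the 2 degree fixation criterion.
    """

    experiment: int = 1
    n_participants: int = 11
    n_sessions: int = 4
    reps_per_cell: int = 15
    conditions: tuple[str, ...] = CONDITIONS
    target_durations_ms: tuple[int, ...] = TARGET_DURATIONS_MS
    jitter_frac: float = 0.30
    exp1_lead_range_ms: tuple[float, float] = (2000.0, 2500.0)
    exp1_tail_range_ms: tuple[float, float] = (1000.0, 1500.0)
    first_side_sequence: str = "LRRL"
    gaze_break_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigError(f"experiment must be 1 or 2, got {self.experiment}")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if self.reps_per_cell < 0:
            raise ConfigError("reps_per_cell must be >= 0")
        if not 0.0 <= self.jitter_frac < 1.0:
            raise ConfigError("jitter_frac must be in [0, 1)")
        if not 0.0 <= self.gaze_break_prob <= 1.0:
            raise ConfigError("gaze_break_prob must be in [0, 1]")
        if any(d <= 0 for d in self.target_durations_ms):
            raise ConfigError("target durations must be positive")
        if self.first_side_sequence not in SIDE_SEQUENCES:
            raise ConfigError(
                f"first_side_sequence must be one of {sorted(SIDE_SEQUENCES)}"
            )
        # SS/FS trials are split between ipsi- and contralateral stable
        # distractors; an exactly balanced split must exist over the
        # whole experiment.
        if (self.reps_per_cell * self.n_sessions) % 2 != 0:
            raise ConfigError(
                "reps_per_cell x n_sessions must be even so SS/FS trials can "
                "be split equally between ipsi- and contralateral distractors"
            )

    @classmethod
    def for_experiment(cls, experiment: int, **overrides) -> "DesignConfig":
        """Study-scale configuration: 11 participants in experiment 1,
        10 in experiment 2."""
        defaults = {"experiment": experiment,
                    "n_participants": 11 if experiment == 1 else 10}
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def participants(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, self.n_participants + 1)]

    def side_sequence(self, participant_index: int) -> tuple[str, ...]:
        """Target-side sequence for the 0-based ``participant_index``;
        alternates between the two counterbalancing orders."""
        keys = list(SIDE_SEQUENCES)
        first = keys.index(self.first_side_sequence)
        key = keys[(first + participant_index) % 2]
        return SIDE_SEQUENCES[key]


def _opposite(side: str) -> str:
    return "R" if side == "L" else "L"


def build_design(cfg: DesignConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Build the full skeleton trial table (no timing, no responses).

    Per session every condition x duration cell appears exactly
    ``reps_per_cell`` times.  SS and FS cells are split between ipsi- and
    contralateral stable distractors, ceil/floor within a session with the
    extra trial alternating across sessions so the split is exactly even
    over the experiment.  SFi distractors share the target's hemifield;
    SFc distractors take the opposite one.  Trial order is shuffled per
    session with one seeded generator for the whole design.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    rows: list[tuple] = []
    half, extra = divmod(cfg.reps_per_cell, 2)
    for p_idx, pid in enumerate(cfg.participants):
        seq = cfg.side_sequence(p_idx)
        for session in range(1, cfg.n_sessions + 1):
            target_side = seq[(session - 1) % len(seq)]
            session_rows: list[tuple] = []
            for cond in cfg.conditions:
                for dur in cfg.target_durations_ms:
                    if cond in ("SS", "FS"):
                        n_ipsi = half + (extra if session % 2 == 1 else 0)
                        n_contra = cfg.reps_per_cell - n_ipsi
                        sides = [target_side] * n_ipsi + [_opposite(target_side)] * n_contra
                    elif cond == "SFi":
                        sides = [target_side] * cfg.reps_per_cell
                    else:  # SFc
                        sides = [_opposite(target_side)] * cfg.reps_per_cell
                    session_rows.extend(
                        (pid, session, cond, target_side, d_side, dur)
                        for d_side in sides
                    )
            order = rng.permutation(len(session_rows))
            for trial_index, j in enumerate(order, start=1):
                pid_, sess_, cond_, tside_, dside_, dur_ = session_rows[j]
                rows.append((pid_, sess_, trial_index, cond_, tside_, dside_, dur_))

    df = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    return df


def assign_distractor_timing(
    trials: pd.DataFrame, cfg: DesignConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Set ``distractor_onset_ms``/``distractor_offset_ms`` (signed offsets
    relative to target onset/offset) on a copy of ``trials``.

    Experiment 1: the distractor leads the target by a uniform 2000-2500 ms
    and outlasts it by a uniform 1000-1500 ms.  Experiment 2: onset and
    offset asynchronies are independent uniform draws on
    +/- ``jitter_frac`` x target duration.
    """
    out = trials.copy()
    n = len(out)
    if cfg.experiment == 1:
        lead = rng.uniform(*cfg.exp1_lead_range_ms, size=n)
        tail = rng.uniform(*cfg.exp1_tail_range_ms, size=n)
        out["distractor_onset_ms"] = -lead
        out["distractor_offset_ms"] = tail
    else:
        dur = out["target_duration_ms"].to_numpy(dtype=float)
        bound = cfg.jitter_frac * dur
        out["distractor_onset_ms"] = rng.uniform(-bound, bound) if n else np.array([])
        out["distractor_offset_ms"] = rng.uniform(-bound, bound) if n else np.array([])
    return out


def distractor_duration_ms(trials: pd.DataFrame) -> pd.Series:
    """Distractor duration implied by the asynchronies:
    target duration - onset asynchrony + offset asynchrony."""
    return (
        trials["target_duration_ms"]
        - trials["distractor_onset_ms"]
        + trials["distractor_offset_ms"]
    )


@dataclass(frozen=True)
class Geometry:
    """Centers (degrees of visual angle, x positive rightward, y positive
    upward, fixation at the origin) and distances for one stimulus layout."""

    target_center_deg: tuple[float, float]
    distractor_center_deg: tuple[float, float]
    center_distance_deg: float
    edge_distance_deg: float


def stimulus_geometry(
    layout: str, target_side: str = "R", radius_deg: float = 3.0
) -> Geometry:
    """Geometry of one target/distractor layout.

    The target disk sits 7 degrees lateral and 7 degrees above fixation.
    An ipsilateral distractor sits 14 degrees below the target center; a
    contralateral one sits 14 degrees toward the opposite hemifield.  With
    3-degree radii both layouts give an 8-degree edge-to-edge separation.
    """
    if layout not in ("ipsi", "contra"):
        raise ValueError(f"layout must be 'ipsi' or 'contra', got {layout!r}")
    sx = 7.0 if target_side == "R" else -7.0
    target = (sx, 7.0)
    if layout == "ipsi":
        distractor = (sx, 7.0 - 14.0)
    else:
        distractor = (sx - math.copysign(14.0, sx), 7.0)
    center = math.hypot(target[0] - distractor[0], target[1] - distractor[1])
    return Geometry(
        target_center_deg=target,
        distractor_center_deg=distractor,
        center_distance_deg=center,
        edge_distance_deg=center - 2.0 * radius_deg,
    )
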