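"""Synthetic duration-reproduction experiments.

Generates complete trial tables (design, distractor timing, reproduced
durations, gaze deviations, exclusion flags) from the multiplicative
location-scale generative model, with one master seed driving named
substreams so regeneration is byte-identical.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .design import (
    DesignConfig,
    assign_distractor_timing,
    build_design,
)
from .params import EffectParams, FREE_CONDITIONS, REFERENCE_CONDITION
from .preprocess import GAZE_THRESHOLD_DEG

#: reproduced durations are redrawn until they exceed this floor
MIN_REPRODUCED_MS = 1.0

#: full column order of a simulated trial table
TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "trial_index",
    "condition",
    "target_side",
    "distractor_side",
    "target_duration_ms",
    "distractor_onset_ms",
    "distractor_offset_ms",
    "reproduced_ms",
    "gaze_max_dev_deg",
    "excluded",
]

# Default generating effects.  Condition multipliers follow the dilation
# ordering FS > SFi > SFc > SS, with the ipsi/contra difference present
# only in the long-distractor design (experiment 1); in experiment 2 the
# ipsi- and contralateral effects are set equal.  SD multipliers equal
# the mean multipliers (scalar timing: SD proportional to the mean).
_DEFAULT_BETA_MU = {
    1: {"SS": 1.0, "FS": 1.20, "SFi": 1.10, "SFc": 1.05},
    2: {"SS": 1.0, "FS": 1.15, "SFi": 1.08, "SFc": 1.08},
}
#: Weber fraction of the reproduction noise (SD / duration)
_WEBER_FRACTION = 0.15


def default_truth(
    cfg: DesignConfig, rng: np.random.Generator | None = None
) -> EffectParams:
    """Field-realistic generating parameters for ``cfg``.

    Duration effects are veridical (``gamma_mu[d] = d``), reproduction
    noise follows a 0.15 Weber fraction, and participant random effects
    are drawn from their population distributions (``tau_mu`` = 60 ms for
    the mean, ``tau_sigma`` = 15 ms for the SD), truncated so every cell
    SD stays positive.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    beta_mu = dict(_DEFAULT_BETA_MU[cfg.experiment])
    beta_sigma = dict(beta_mu)
    gamma_mu = {d: float(d) for d in cfg.target_durations_ms}
    gamma_sigma = {d: _WEBER_FRACTION * d for d in cfg.target_durations_ms}
    tau_mu, tau_sigma = 60.0, 15.0
    min_gamma_sigma = min(gamma_sigma.values())
    u_mu = {}
    u_sigma = {}
    for pid in cfg.participants:
        u_mu[pid] = float(rng.normal(0.0, tau_mu))
        # keep every cell SD comfortably positive
        lo = -0.8 * min_gamma_sigma
        draw = rng.normal(0.0, tau_sigma)
        while draw <= lo:
            draw = rng.normal(0.0, tau_sigma)
        u_sigma[pid] = float(draw)
    return EffectParams(
        beta_mu=beta_mu,
        beta_sigma=beta_sigma,
        gamma_mu=gamma_mu,
        gamma_sigma=gamma_sigma,
        u_mu=u_mu,
        u_sigma=u_sigma,
        tau_mu=tau_mu,
        tau_sigma=tau_sigma,
    )


def _cell_moments(
    params: EffectParams, trials: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    mean = (
        trials["condition"].map(params.beta_mu)
        * (
            trials["target_duration_ms"].map(params.gamma_mu)
            + trials["participant_id"].map(params.u_mu)
        )
    ).to_numpy(dtype=float)
    sd = (
        trials["condition"].map(params.beta_sigma)
        * (
            trials["target_duration_ms"].map(params.gamma_sigma)
            + trials["participant_id"].map(params.u_sigma)
        )
    ).to_numpy(dtype=float)
    return mean, sd


def sample_reproduced(
    params: EffectParams, trials: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Draw reproduced durations (ms) for each trial row.

    Each draw is Normal(beta_mu[c](gamma_mu[d]+u_mu[s]),
    beta_sigma[c](gamma_sigma[d]+u_sigma[s])), redrawn until it exceeds
    the 1 ms floor; at realistic parameters redraws are vanishingly rare
    so the likelihood is treated as an untruncated normal.
    """
    mean, sd = _cell_moments(params, trials)
    if np.any(~np.isfinite(mean)) or np.any(~np.isfinite(sd)):
        bad = trials.loc[~np.isfinite(mean) | ~np.isfinite(sd)].iloc[0]
        raise ValueError(
            "parameters missing for cell "
            f"(condition={bad['condition']}, duration={bad['target_duration_ms']}, "
            f"participant={bad['participant_id']})"
        )
    if np.any(sd <= 0):
        bad = trials.loc[sd <= 0].iloc[0]
        raise ValueError(
            "nonpositive cell standard deviation in cell "
            f"(condition={bad['condition']}, duration={bad['target_duration_ms']}, "
            f"participant={bad['participant_id']})"
        )
    x = rng.normal(mean, sd)
    bad = x < MIN_REPRODUCED_MS
    while np.any(bad):
        x[bad] = rng.normal(mean[bad], sd[bad])
        bad = x < MIN_REPRODUCED_MS
    return x


def simulate_gaze(
    cfg: DesignConfig, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Maximum gaze deviation (deg) per trial: a two-component uniform
    mixture -- with probability ``gaze_break_prob`` a fixation break
    uniform on (2, 6], otherwise held fixation uniform on [0, 2)."""
    breaks = rng.random(n_trials) < cfg.gaze_break_prob
    held = rng.uniform(0.0, GAZE_THRESHOLD_DEG, size=n_trials)
    # 2 + 4*(1 - U[0,1)) lies in (2, 6]
    broken = GAZE_THRESHOLD_DEG + 4.0 * (1.0 - rng.random(n_trials))
    return np.where(breaks, broken, held)


def simulate_experiment(
    cfg: DesignConfig,
    params: EffectParams | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, EffectParams]:
    """Generate one complete experiment.

    Returns the trial table (one row per trial, ``TRIAL_COLUMNS``) and the
    generating truth.  The master seed (``seed`` or ``cfg.seed``) is split
    into named substreams for design shuffling, distractor timing, truth
    random effects, responses and gaze, so each stage is independently
    reproducible.
    """
    master = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_design, s_timing, s_truth, s_resp, s_gaze = ss.spawn(5)

    trials = build_design(cfg, rng=np.random.default_rng(s_design))
    trials = assign_distractor_timing(trials, cfg, np.random.default_rng(s_timing))
    if params is None:
        params = default_truth(cfg, rng=np.random.default_rng(s_truth))
    params.validate_cells()
    trials["reproduced_ms"] = sample_reproduced(
        params, trials, np.random.default_rng(s_resp)
    )
    trials["gaze_max_dev_deg"] = simulate_gaze(
        cfg, len(trials), np.random.default_rng(s_gaze)
    )
    trials["excluded"] = trials["gaze_max_dev_deg"] > GAZE_THRESHOLD_DEG
    return trials[TRIAL_COLUMNS], params


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the tidy trial CSV (header mandatory, 1-based indices)."""
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)
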