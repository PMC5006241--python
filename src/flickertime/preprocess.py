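"""Trial exclusion, side merging and the distractor-duration diagnostic.

Trials where gaze strayed more than 2 degrees from fixation are dropped;
left- and right-target trials are merged into a single analysis cell per
condition; and for the jittered-distractor design a per-participant,
per-duration Pearson correlation between distractor duration and
reproduced duration checks that responses track the target, not the
distractor.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: fixation criterion: deviations strictly greater than this are excluded
GAZE_THRESHOLD_DEG = 2.0


def apply_gaze_exclusion(
    trials: pd.DataFrame, threshold_deg: float = GAZE_THRESHOLD_DEG
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose maximum gaze deviation exceeds ``threshold_deg``.

    The threshold is strict: a deviation of exactly 2 degrees is kept.
    Returns the kept trials and a per-participant report with columns
    ``n_trials``, ``n_excluded``, ``fraction_excluded``.
    """
    if "gaze_max_dev_deg" not in trials.columns:
        raise KeyError("trial table has no 'gaze_max_dev_deg' column")
    keep = trials["gaze_max_dev_deg"] <= threshold_deg
    kept = trials.loc[keep].copy()
    if len(trials):
        grouped = trials.groupby("participant_id", sort=True)
        report = pd.DataFrame(
            {
                "n_trials": grouped.size(),
                "n_excluded": grouped.apply(
                    lambda g: int((g["gaze_max_dev_deg"] > threshold_deg).sum()),
                    include_groups=False,
                ),
            }
        )
        report["fraction_excluded"] = report["n_excluded"] / report["n_trials"]
    else:
        report = pd.DataFrame(
            columns=["n_trials", "n_excluded", "fraction_excluded"]
        )
        report.index.name = "participant_id"
    return kept, report


def merge_target_sides(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse left- and right-target trials into one analysis cell per
    condition.

    Row count is unchanged; the returned table carries a ``cell`` column
    equal to the side-free condition label, so the 4 conditions x 2 target
    sides of raw cells become exactly 4 analysis cells.
    """
    out = trials.copy()
    out["cell"] = out["condition"].astype(str)
    return out


def distractor_correlations(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x target duration Pearson correlation between
    distractor duration and reproduced duration.

    Distractor duration is derived as
    ``target_duration - onset_asynchrony + offset_asynchrony``.  The
    two-sided p-value is the classic t-transform with n-2 degrees of
    freedom.  Cells with fewer than 3 trials or zero variance on either
    axis are flagged ``defined = False`` instead of raising.
    """
    required = {
        "participant_id",
        "target_duration_ms",
        "distractor_onset_ms",
        "distractor_offset_ms",
        "reproduced_ms",
    }
    missing = required - set(trials.columns)
    if missing:
        raise KeyError(f"trial table missing columns: {sorted(missing)}")

    rows = []
    for (pid, dur), grp in trials.groupby(
        ["participant_id", "target_duration_ms"], sort=True
    ):
        dd = (
            grp["target_duration_ms"]
            - grp["distractor_onset_ms"]
            + grp["distractor_offset_ms"]
        ).to_numpy(dtype=float)
        rep = grp["reproduced_ms"].to_numpy(dtype=float)
        n = len(grp)
        defined = n >= 3 and np.std(dd) > 0 and np.std(rep) > 0
        if defined:
            r, p = stats.pearsonr(dd, rep)
        else:
            r, p = np.nan, np.nan
        rows.append(
            {
                "participant_id": pid,
                "target_duration_ms": dur,
                "n_trials": n,
                "pearson_r": r,
                "p_value": p,
                "defined": defined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "target_duration_ms",
            "n_trials",
            "pearson_r",
            "p_value",
            "defined",
        ],
    )
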