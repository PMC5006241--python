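"""Posterior summaries, condition comparisons and parameter recovery.

Point estimates are posterior medians (50th percentiles of the pooled
draws) with equal-tailed 95% credible intervals.  The condition
comparisons are one-sided posterior-probability tests over the fixed
family of six contrasts among the dilation ratios, Bonferroni-corrected
for the family size.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import EffectParams
from . import sampler as _sampler

#: metadata columns of a pooled-draws table, everything else is a parameter
META_COLUMNS = ("chain", "iteration")

#: comparison family: (label, left parameter, right parameter or None for
#: the "larger than 1" null); "a_gt_b" tests a > b one-sided
COMPARISONS: list[tuple[str, str, str | None]] = [
    ("FS_gt_1", "beta_mu.FS", None),
    ("SFi_gt_1", "beta_mu.SFi", None),
    ("SFc_gt_1", "beta_mu.SFc", None),
    ("FS_gt_SFi", "beta_mu.FS", "beta_mu.SFi"),
    ("FS_gt_SFc", "beta_mu.FS", "beta_mu.SFc"),
    ("SFi_gt_SFc", "beta_mu.SFi", "beta_mu.SFc"),
]


def parameter_columns(samples: pd.DataFrame) -> list[str]:
    return [c for c in samples.columns if c not in META_COLUMNS]


def summarize_posterior(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter median and equal-tailed 95% credible interval.

    Percentiles (2.5/50/97.5) use the linear-interpolation quantile rule.
    """
    cols = parameter_columns(samples)
    if len(samples) == 0 or not cols:
        raise ValueError("posterior sample table is empty")
    values = samples[cols].to_numpy(dtype=float)
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5], axis=0)
    out = pd.DataFrame(
        {"median": med, "cri_low": lo, "cri_high": hi}, index=pd.Index(cols, name="parameter")
    )
    out.attrs["quantile_rule"] = "linear interpolation"
    return out


def condition_ratio_tests(
    samples: pd.DataFrame, family: list[tuple[str, str, str | None]] = COMPARISONS
) -> pd.DataFrame:
    """One-sided posterior-probability tests of the dilation-ratio family.

    The raw p of "a > b" is the fraction of pooled draws violating the
    direction (a <= b, or a <= 1 for the against-baseline tests); the
    corrected p is Bonferroni over the family, min(1, family_size x raw).
    """
    if len(samples) == 0:
        raise ValueError("posterior sample table is empty")
    m = len(family)
    rows = []
    for label, left, right in family:
        if left not in samples.columns:
            raise KeyError(f"posterior draws missing parameter {left!r}")
        a = samples[left].to_numpy(dtype=float)
        if right is None:
            b = 1.0
        else:
            if right not in samples.columns:
                raise KeyError(f"posterior draws missing parameter {right!r}")
            b = samples[right].to_numpy(dtype=float)
        raw = float(np.mean(a <= b))
        rows.append(
            {
                "label": label,
                "raw_p": raw,
                "corrected_p": min(1.0, m * raw),
                "family_size": m,
            }
        )
    return pd.DataFrame(rows, columns=["label", "raw_p", "corrected_p", "family_size"])


def recovery_report(truth: EffectParams, summary: pd.DataFrame) -> dict:
    """Compare a posterior summary against the generating truth.

    Per parameter: truth, median estimate, bias (estimate - truth) and
    whether the 95% credible interval covers the truth.  Aggregates: mean
    absolute bias of the dilation ratios (beta_mu) and the overall
    coverage fraction.
    """
    flat_truth = truth.to_flat_dict()
    missing = [name for name in flat_truth if name not in summary.index]
    if missing:
        raise KeyError(f"summary missing parameters: {missing}")
    rows = []
    for name, true_value in flat_truth.items():
        est = float(summary.loc[name, "median"])
        lo = float(summary.loc[name, "cri_low"])
        hi = float(summary.loc[name, "cri_high"])
        rows.append(
            {
                "parameter": name,
                "truth": float(true_value),
                "estimate": est,
                "bias": est - float(true_value),
                "covered": bool(lo <= true_value <= hi),
            }
        )
    beta_rows = [r for r in rows if r["parameter"].startswith("beta_mu.")]
    return {
        "parameters": rows,
        "mean_abs_bias_beta_mu": float(
            np.mean([abs(r["bias"]) for r in beta_rows])
        ),
        "coverage_fraction": float(np.mean([r["covered"] for r in rows])),
    }


class DurationResults:
    """Posterior of a fitted `DurationModel`.

    Carries the pooled post-warmup draws (`samples`), the individual
    chains, and convenience accessors for estimates, credible intervals,
    comparisons, convergence diagnostics and recovery checks.
    """

    def __init__(self, model, samples: pd.DataFrame, chains, n_warmup: int, seed: int):
        self.model = model
        self.samples = samples
        self.chains = chains
        self.n_warmup = n_warmup
        self.seed = seed

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior medians, one entry per parameter."""
        return self.summary_frame()["median"]

    @property
    def dilation_ratios(self) -> pd.Series:
        """Median reproduced-duration ratios vs the SS baseline."""
        return self.params.filter(like="beta_mu.")

    def params_object(self) -> EffectParams:
        return self.model.layout.unpack(
            self.summary_frame()["median"].reindex(self.model.layout.names).to_numpy()
        )

    def summary_frame(self) -> pd.DataFrame:
        return summarize_posterior(self.samples)

    def compare_conditions(self) -> pd.DataFrame:
        return condition_ratio_tests(self.samples)

    def rhat(self) -> pd.Series:
        return _sampler.rhat(self.chains, self.n_warmup, names=self.model.layout.names)

    def recovery(self, truth: EffectParams) -> dict:
        return recovery_report(truth, self.summary_frame())

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of estimates and comparisons."""
        sf = self.summary_frame()
        comps = self.compare_conditions()
        n_draws = len(self.samples)
        n_chains = len(self.chains)
        lines = [
            "Hierarchical location-scale model of reproduced durations",
            "=" * 60,
            f"observations: {self.model.nobs}    "
            f"participants: {len(self.model.layout.participants)}",
            f"pooled draws: {n_draws} ({n_chains} chains, "
            f"warmup {self.n_warmup})",
            "",
            "Dilation ratios vs SS (posterior median [95% CrI])",
            "-" * 60,
        ]
        for name in ("beta_mu.FS", "beta_mu.SFi", "beta_mu.SFc"):
            if name in sf.index:
                r = sf.loc[name]
                lines.append(
                    f"  {name:<14s} {r['median']:7.3f}  "
                    f"[{r['cri_low']:7.3f}, {r['cri_high']:7.3f}]"
                )
        lines += ["", "Comparisons (one-sided posterior p, Bonferroni x 6)",
                  "-" * 60]
        for _, row in comps.iterrows():
            lines.append(
                f"  {row['label']:<12s} raw p = {row['raw_p']:6.4f}   "
                f"corrected p = {row['corrected_p']:6.4f}"
            )
        return "\n".join(lines)

    def plot_condition_effects(self, ax=None):
        """Point-and-interval plot of the dilation ratios vs SS."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        sf = self.summary_frame()
        labels = ["FS", "SFi", "SFc"]
        names = [f"beta_mu.{c}" for c in labels]
        med = sf.loc[names, "median"].to_numpy()
        lo = sf.loc[names, "cri_low"].to_numpy()
        hi = sf.loc[names, "cri_high"].to_numpy()
        xs = np.arange(len(labels))
        ax.errorbar(xs, med, yerr=[med - lo, hi - med], fmt="o", capsize=4)
        ax.axhline(1.0, color="0.5", lw=1, ls="--")
        ax.set_xticks(xs, labels)
        ax.set_ylabel("reproduced-duration ratio vs SS")
        return ax

    # -- persistence -------------------------------------------------------
    def save_posterior(self, path) -> None:
        self.samples.to_csv(path, index=False)

    def save_summary(self, csv_path=None, json_path=None) -> None:
        sf = self.summary_frame()
        comps = self.compare_conditions()
        if csv_path is not None:
            sf.to_csv(csv_path)
        if json_path is not None:
            payload = {
                "quantile_rule": "linear interpolation",
                "n_draws": int(len(self.samples)),
                "n_chains": int(len(self.chains)),
                "n_warmup": int(self.n_warmup),
                "parameters": {
                    name: {
                        "median": float(row["median"]),
                        "cri_low": float(row["cri_low"]),
                        "cri_high": float(row["cri_high"]),
                    }
                    for name, row in sf.iterrows()
                },
                "comparisons": comps.to_dict(orient="records"),
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
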