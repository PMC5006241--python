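"""Multiplicative-effects parameters shared by the generator and the model.

Both the reproduced-duration mean and its standard deviation are modelled
as a condition multiplier applied to the sum of a duration effect and a
per-participant random effect:

    mean(c, d, s) = beta_mu[c]  * (gamma_mu[d]  + u_mu[s])
    sd(c, d, s)   = beta_sigma[c] * (gamma_sigma[d] + u_sigma[s])

with the SS condition fixed to 1 for both moments, so the free
``beta_mu`` entries are directly the dilation ratios relative to SS.
The same container describes simulation truth and fitted values.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

REFERENCE_CONDITION = "SS"
FREE_CONDITIONS: tuple[str, ...] = ("FS", "SFi", "SFc")


@dataclass
class EffectParams:
    """Condition multipliers, duration effects and participant random
    effects for the mean and SD of reproduced durations.

    ``beta_mu``/``beta_sigma`` map condition name -> positive multiplier
    (SS fixed to 1); ``gamma_mu``/``gamma_sigma`` map target duration (ms)
    -> ms-scale effect; ``u_mu``/``u_sigma`` map participant id -> ms-scale
    deviation.  ``tau_mu``/``tau_sigma`` are the population SDs of the
    random effects.
    """

    beta_mu: dict[str, float]
    beta_sigma: dict[str, float]
    gamma_mu: dict[int, float]
    gamma_sigma: dict[int, float]
    u_mu: dict[str, float]
    u_sigma: dict[str, float]
    tau_mu: float = 60.0
    tau_sigma: float = 15.0

    def __post_init__(self) -> None:
        for name, beta in (("beta_mu", self.beta_mu), ("beta_sigma", self.beta_sigma)):
            if beta.get(REFERENCE_CONDITION) != 1:
                raise ValueError(
                    f"{name}[{REFERENCE_CONDITION}] must be exactly 1 "
                    f"(reference condition), got {beta.get(REFERENCE_CONDITION)}"
                )

    # -- structure ---------------------------------------------------------
    @property
    def conditions(self) -> list[str]:
        return list(self.beta_mu)

    @property
    def durations(self) -> list[int]:
        return list(self.gamma_mu)

    @property
    def participants(self) -> list[str]:
        return list(self.u_mu)

    def cell_mean(self, condition: str, duration_ms: int, participant: str) -> float:
        return self.beta_mu[condition] * (
            self.gamma_mu[duration_ms] + self.u_mu[participant]
        )

    def cell_sd(self, condition: str, duration_ms: int, participant: str) -> float:
        return self.beta_sigma[condition] * (
            self.gamma_sigma[duration_ms] + self.u_sigma[participant]
        )

    def validate_cells(self) -> None:
        """Check the positivity invariant sd(c, d, s) > 0 for every cell."""
        for c in self.conditions:
            if self.beta_mu[c] <= 0 or self.beta_sigma[c] <= 0:
                raise ValueError(f"condition multipliers must be positive ({c})")
            for d in self.durations:
                for s in self.participants:
                    if self.cell_sd(c, d, s) <= 0:
                        raise ValueError(
                            "nonpositive cell standard deviation in cell "
                            f"(condition={c}, duration={d}, participant={s})"
                        )

    # -- (de)serialisation -------------------------------------------------
    def to_flat_dict(self) -> dict[str, float]:
        """Flat name -> value mapping, names like ``beta_mu.FS`` and
        ``gamma_mu.450``; the fixed SS entries are omitted."""
        out: dict[str, float] = {}
        for c in FREE_CONDITIONS:
            out[f"beta_mu.{c}"] = float(self.beta_mu[c])
        for c in FREE_CONDITIONS:
            out[f"beta_sigma.{c}"] = float(self.beta_sigma[c])
        for d in self.durations:
            out[f"gamma_mu.{d}"] = float(self.gamma_mu[d])
        for d in self.durations:
            out[f"gamma_sigma.{d}"] = float(self.gamma_sigma[d])
        for s in self.participants:
            out[f"u_mu.{s}"] = float(self.u_mu[s])
        for s in self.participants:
            out[f"u_sigma.{s}"] = float(self.u_sigma[s])
        out["tau_mu"] = float(self.tau_mu)
        out["tau_sigma"] = float(self.tau_sigma)
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict[str, float]) -> "EffectParams":
        beta_mu = {REFERENCE_CONDITION: 1.0}
        beta_sigma = {REFERENCE_CONDITION: 1.0}
        gamma_mu: dict[int, float] = {}
        gamma_sigma: dict[int, float] = {}
        u_mu: dict[str, float] = {}
        u_sigma: dict[str, float] = {}
        tau_mu = tau_sigma = None
        for name, value in flat.items():
            if name == "tau_mu":
                tau_mu = float(value)
                continue
            if name == "tau_sigma":
                tau_sigma = float(value)
                continue
            group, key = name.split(".", 1)
            if group == "beta_mu":
                beta_mu[key] = float(value)
            elif group == "beta_sigma":
                beta_sigma[key] = float(value)
            elif group == "gamma_mu":
                gamma_mu[int(key)] = float(value)
            elif group == "gamma_sigma":
                gamma_sigma[int(key)] = float(value)
            elif group == "u_mu":
                u_mu[key] = float(value)
            elif group == "u_sigma":
                u_sigma[key] = float(value)
            else:
                raise ValueError(f"unknown parameter name {name!r}")
        if tau_mu is None or tau_sigma is None:
            raise ValueError("flat dict missing tau_mu/tau_sigma")
        return cls(beta_mu, beta_sigma, gamma_mu, gamma_sigma, u_mu, u_sigma,
                   tau_mu, tau_sigma)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "EffectParams":
        with open(path) as fh:
            return cls.from_flat_dict(json.load(fh))


# the same container plays both roles
GenerativeParams = EffectParams
ModelParams = EffectParams
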