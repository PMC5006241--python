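"""Hierarchical Bayesian location-scale model of reproduced durations.

Reproduced durations are normal within each condition x target duration x
participant cell, with both moments built multiplicatively:

    mean(c, d, s) = beta_mu[c]    * (gamma_mu[d]    + u_mu[s])
    sd(c, d, s)   = beta_sigma[c] * (gamma_sigma[d] + u_sigma[s])

The SS (stable target, stable distractor) condition is the reference and
its multipliers are fixed to 1, so ``beta_mu[c]`` is directly the ratio of
reproduced duration under condition ``c`` to that under SS -- the time
dilation ratio of interest.  Random effects are hierarchically shrunk,
``u ~ Normal(0, tau)`` with half-Cauchy priors on the taus.

Priors (weakly informative on the millisecond scale):

* free condition multipliers: Normal(1, 0.5^2) truncated to (0, inf)
* ``gamma_mu[d]``: Normal(d, 300^2)
* ``gamma_sigma[d]``: half-Normal(300)
* ``u_mu[s] | tau_mu``: Normal(0, tau_mu^2); likewise for ``u_sigma``
* ``tau_mu``, ``tau_sigma``: half-Cauchy(0, 100)

`DurationModel.fit` samples the posterior with block-wise adaptive
random-walk Metropolis (positive parameters proposed on the log scale),
defaulting to 3 runs x 2000 iterations with the latter 1000 of each
pooled to 3000 draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import EffectParams, FREE_CONDITIONS, REFERENCE_CONDITION
from .sampler import Chain, pool_chains, run_chain

_LOG2PI = math.log(2.0 * math.pi)

# prior hyperparameters
BETA_PRIOR_LOC, BETA_PRIOR_SCALE = 1.0, 0.5
GAMMA_MU_PRIOR_SCALE = 300.0
GAMMA_SIGMA_PRIOR_SCALE = 300.0
TAU_PRIOR_SCALE = 100.0

# normal mass of Normal(1, 0.5) above zero, i.e. Phi(2)
_BETA_TRUNC_MASS = 0.5 * (1.0 + math.erf(2.0 / math.sqrt(2.0)))
_LOG_BETA_TRUNC_MASS = math.log(_BETA_TRUNC_MASS)

REQUIRED_COLUMNS = (
    "participant_id",
    "condition",
    "target_duration_ms",
    "reproduced_ms",
)


class ParamLayout:
    """Fixed flattening of `EffectParams` into a parameter vector.

    Order: free beta_mu, free beta_sigma, gamma_mu, gamma_sigma, u_mu,
    u_sigma, tau_mu, tau_sigma.  ``positive`` marks the coordinates that
    the sampler proposes on the log scale (betas, gamma_sigma, taus).
    """

    def __init__(self, participants, durations):
        self.participants = tuple(participants)
        self.durations = tuple(int(d) for d in durations)
        s = len(self.participants)
        k = len(self.durations)
        names: list[str] = []
        names += [f"beta_mu.{c}" for c in FREE_CONDITIONS]
        names += [f"beta_sigma.{c}" for c in FREE_CONDITIONS]
        names += [f"gamma_mu.{d}" for d in self.durations]
        names += [f"gamma_sigma.{d}" for d in self.durations]
        names += [f"u_mu.{p}" for p in self.participants]
        names += [f"u_sigma.{p}" for p in self.participants]
        names += ["tau_mu", "tau_sigma"]
        self.names = names
        self.dim = len(names)

        o = 0
        self.sl_beta_mu = slice(o, o + 3); o += 3
        self.sl_beta_sigma = slice(o, o + 3); o += 3
        self.sl_gamma_mu = slice(o, o + k); o += k
        self.sl_gamma_sigma = slice(o, o + k); o += k
        self.sl_u_mu = slice(o, o + s); o += s
        self.sl_u_sigma = slice(o, o + s); o += s
        self.sl_tau = slice(o, o + 2); o += 2
        assert o == self.dim

        positive = np.zeros(self.dim, dtype=bool)
        positive[self.sl_beta_mu] = True
        positive[self.sl_beta_sigma] = True
        positive[self.sl_gamma_sigma] = True
        positive[self.sl_tau] = True
        self.positive = positive

    # -- pack / unpack -----------------------------------------------------
    def pack(self, params: EffectParams) -> np.ndarray:
        x = np.empty(self.dim)
        x[self.sl_beta_mu] = [params.beta_mu[c] for c in FREE_CONDITIONS]
        x[self.sl_beta_sigma] = [params.beta_sigma[c] for c in FREE_CONDITIONS]
        x[self.sl_gamma_mu] = [params.gamma_mu[d] for d in self.durations]
        x[self.sl_gamma_sigma] = [params.gamma_sigma[d] for d in self.durations]
        x[self.sl_u_mu] = [params.u_mu[p] for p in self.participants]
        x[self.sl_u_sigma] = [params.u_sigma[p] for p in self.participants]
        x[self.sl_tau] = [params.tau_mu, params.tau_sigma]
        return x

    def unpack(self, x: np.ndarray) -> EffectParams:
        ref = {REFERENCE_CONDITION: 1.0}
        return EffectParams(
            beta_mu={**ref, **dict(zip(FREE_CONDITIONS, x[self.sl_beta_mu]))},
            beta_sigma={**ref, **dict(zip(FREE_CONDITIONS, x[self.sl_beta_sigma]))},
            gamma_mu=dict(zip(self.durations, x[self.sl_gamma_mu])),
            gamma_sigma=dict(zip(self.durations, x[self.sl_gamma_sigma])),
            u_mu=dict(zip(self.participants, x[self.sl_u_mu])),
            u_sigma=dict(zip(self.participants, x[self.sl_u_sigma])),
            tau_mu=float(x[self.sl_tau][0]),
            tau_sigma=float(x[self.sl_tau][1]),
        )

    # -- unconstrained transform -------------------------------------------
    def to_unconstrained(self, x: np.ndarray) -> np.ndarray:
        z = np.asarray(x, dtype=float).copy()
        z[self.positive] = np.log(z[self.positive])
        return z

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        x = np.asarray(z, dtype=float).copy()
        x[self.positive] = np.exp(x[self.positive])
        return x

    def log_jacobian(self, z: np.ndarray) -> float:
        return float(np.sum(z[self.positive]))

    def blocks(self) -> list[np.ndarray]:
        return [
            np.arange(self.dim)[sl]
            for sl in (
                self.sl_beta_mu,
                self.sl_beta_sigma,
                self.sl_gamma_mu,
                self.sl_gamma_sigma,
                self.sl_u_mu,
                self.sl_u_sigma,
                self.sl_tau,
            )
        ]


class DurationModel:
    """Location-scale model of reproduced durations, built from a tidy
    trial table (one row per kept trial).

    Parameters
    ----------
    trials
        DataFrame with at least ``participant_id``, ``condition``,
        ``target_duration_ms`` and ``reproduced_ms`` columns (the output
        of the synthetic generator after gaze exclusion).

    The likelihood is evaluated from per-cell sufficient statistics
    (count, sum, sum of squares), so its cost is independent of the
    number of trials.
    """

    def __init__(self, trials: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
        if missing:
            raise KeyError(f"trial table missing columns: {missing}")
        if len(trials) == 0:
            raise ValueError("trial table is empty")
        unknown = set(trials["condition"]) - {REFERENCE_CONDITION, *FREE_CONDITIONS}
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

        self.trials = trials
        participants = sorted(trials["participant_id"].astype(str).unique())
        durations = sorted(int(d) for d in trials["target_duration_ms"].unique())
        self.layout = ParamLayout(participants, durations)
        self.nobs = len(trials)

        cond_order = [REFERENCE_CONDITION, *FREE_CONDITIONS]
        cond_code = trials["condition"].map({c: i for i, c in enumerate(cond_order)})
        dur_code = trials["target_duration_ms"].astype(int).map(
            {d: i for i, d in enumerate(durations)}
        )
        subj_code = trials["participant_id"].astype(str).map(
            {p: i for i, p in enumerate(participants)}
        )
        y = trials["reproduced_ms"].to_numpy(dtype=float)

        cells = pd.DataFrame(
            {"c": cond_code.to_numpy(), "d": dur_code.to_numpy(),
             "s": subj_code.to_numpy(), "y": y, "y2": y * y}
        )
        agg = cells.groupby(["c", "d", "s"], sort=True).agg(
            n=("y", "size"), ysum=("y", "sum"), yssq=("y2", "sum")
        ).reset_index()
        self._cell_c = agg["c"].to_numpy()
        self._cell_d = agg["d"].to_numpy()
        self._cell_s = agg["s"].to_numpy()
        self._cell_n = agg["n"].to_numpy(dtype=float)
        self._cell_sum = agg["ysum"].to_numpy()
        self._cell_ssq = agg["yssq"].to_numpy()
        self._dur_values = np.asarray(durations, dtype=float)

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame) -> "DurationModel":
        return cls(trials)

    # -- densities on the flat natural-scale vector ------------------------
    def loglike_vec(self, x: np.ndarray) -> float:
        lay = self.layout
        b_mu = np.concatenate(([1.0], x[lay.sl_beta_mu]))
        b_sg = np.concatenate(([1.0], x[lay.sl_beta_sigma]))
        g_mu = x[lay.sl_gamma_mu]
        g_sg = x[lay.sl_gamma_sigma]
        u_mu = x[lay.sl_u_mu]
        u_sg = x[lay.sl_u_sigma]
        mu = b_mu[self._cell_c] * (g_mu[self._cell_d] + u_mu[self._cell_s])
        sd = b_sg[self._cell_c] * (g_sg[self._cell_d] + u_sg[self._cell_s])
        if np.any(sd <= 0.0) or not np.all(np.isfinite(sd)):
            return -math.inf
        quad = (self._cell_ssq - 2.0 * mu * self._cell_sum
                + self._cell_n * mu * mu) / (2.0 * sd * sd)
        return float(
            -0.5 * self.nobs * _LOG2PI
            - np.dot(self._cell_n, np.log(sd))
            - quad.sum()
        )

    def logprior_vec(self, x: np.ndarray) -> float:
        lay = self.layout
        betas = np.concatenate((x[lay.sl_beta_mu], x[lay.sl_beta_sigma]))
        g_sg = x[lay.sl_gamma_sigma]
        taus = x[lay.sl_tau]
        if np.any(betas <= 0) or np.any(g_sg <= 0) or np.any(taus <= 0):
            return -math.inf
        lp = 0.0
        # truncated normal on the free condition multipliers
        zb = (betas - BETA_PRIOR_LOC) / BETA_PRIOR_SCALE
        lp += float(
            np.sum(-0.5 * _LOG2PI - math.log(BETA_PRIOR_SCALE) - 0.5 * zb * zb)
        ) - betas.size * _LOG_BETA_TRUNC_MASS
        # gamma_mu centered on the nominal duration
        zg = (x[lay.sl_gamma_mu] - self._dur_values) / GAMMA_MU_PRIOR_SCALE
        lp += float(
            np.sum(-0.5 * _LOG2PI - math.log(GAMMA_MU_PRIOR_SCALE) - 0.5 * zg * zg)
        )
        # half-normal on gamma_sigma
        zs = g_sg / GAMMA_SIGMA_PRIOR_SCALE
        lp += float(
            np.sum(math.log(2.0) - 0.5 * _LOG2PI
                   - math.log(GAMMA_SIGMA_PRIOR_SCALE) - 0.5 * zs * zs)
        )
        # hierarchical normals on random effects
        tau_mu, tau_sigma = taus
        for u, tau in ((x[lay.sl_u_mu], tau_mu), (x[lay.sl_u_sigma], tau_sigma)):
            zu = u / tau
            lp += float(
                np.sum(-0.5 * _LOG2PI - math.log(tau) - 0.5 * zu * zu)
            )
        # half-Cauchy on the taus
        zt = taus / TAU_PRIOR_SCALE
        lp += float(
            np.sum(math.log(2.0) - math.log(math.pi) - math.log(TAU_PRIOR_SCALE)
                   - np.log1p(zt * zt))
        )
        return lp

    def logpost_vec(self, x: np.ndarray) -> float:
        lp = self.logprior_vec(x)
        if not math.isfinite(lp):
            return -math.inf
        ll = self.loglike_vec(x)
        if not math.isfinite(ll):
            return -math.inf
        return lp + ll

    def logpost_z(self, z: np.ndarray) -> float:
        x = self.layout.to_natural(z)
        lp = self.logpost_vec(x)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.layout.log_jacobian(z)

    # -- fitting -----------------------------------------------------------
    def start_params(self) -> EffectParams:
        """Moment-matching start: condition multipliers at 1, duration
        effects at per-duration sample means/SDs, random effects at 0."""
        grp = self.trials.groupby(self.trials["target_duration_ms"].astype(int))
        means = grp["reproduced_ms"].mean()
        sds = grp["reproduced_ms"].std().fillna(50.0).clip(lower=10.0)
        lay = self.layout
        return EffectParams(
            beta_mu={REFERENCE_CONDITION: 1.0, **{c: 1.0 for c in FREE_CONDITIONS}},
            beta_sigma={REFERENCE_CONDITION: 1.0, **{c: 1.0 for c in FREE_CONDITIONS}},
            gamma_mu={d: float(means[d]) for d in lay.durations},
            gamma_sigma={d: float(sds[d]) for d in lay.durations},
            u_mu={p: 0.0 for p in lay.participants},
            u_sigma={p: 0.0 for p in lay.participants},
            tau_mu=50.0,
            tau_sigma=20.0,
        )

    def _initial_scales(self) -> np.ndarray:
        # per block: beta_mu, beta_sigma (log), gamma_mu (ms), gamma_sigma
        # (log), u_mu (ms), u_sigma (ms), taus (log)
        return np.array([0.02, 0.03, 5.0, 0.05, 5.0, 5.0, 0.2])

    def _recentering_directions(self) -> tuple[list[np.ndarray], np.ndarray]:
        """Proposal directions along the additive-decomposition ridges.

        A constant can shift between the duration effects and the
        participant random effects without changing any cell moment, so
        axis-aligned blocks cross that ridge slowly.  Two coordinated
        moves fix this: gamma_mu up / every u_mu down (exactly
        likelihood-invariant), and log gamma_sigma up / every u_sigma
        down by the matching ms amount (approximately invariant at the
        ~100 ms scale of gamma_sigma)."""
        lay = self.layout
        d_mu = np.zeros(lay.dim)
        d_mu[lay.sl_gamma_mu] = 1.0
        d_mu[lay.sl_u_mu] = -1.0
        d_sigma = np.zeros(lay.dim)
        d_sigma[lay.sl_gamma_sigma] = 1.0  # log scale
        d_sigma[lay.sl_u_sigma] = -float(np.mean(self._dur_values)) * 0.15
        return [d_mu, d_sigma], np.array([5.0, 0.05])

    def fit(
        self,
        n_chains: int = 3,
        n_iter: int = 2000,
        n_warmup: int = 1000,
        seed: int = 0,
        jitter: float = 0.05,
    ):
        """Sample the posterior and return a `DurationResults`.

        Defaults follow the analysis scheme: 3 independent runs of 2000
        Metropolis iterations; the first 1000 of each (the adaptation
        phase) are discarded and the remaining 3 x 1000 = 3000 draws are
        pooled.  ``jitter`` is the SD of the unconstrained-scale
        perturbation applied to each chain's moment-matching start.
        """
        from .results import DurationResults  # deferred: avoids a cycle

        if n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= n_warmup < n_iter:
            raise ValueError("need 0 <= n_warmup < n_iter")

        lay = self.layout
        z0 = lay.to_unconstrained(lay.pack(self.start_params()))
        blocks = lay.blocks()
        seeds = np.random.SeedSequence(seed).spawn(n_chains)
        chains: list[Chain] = []
        for child in seeds:
            rng = np.random.default_rng(child)
            z_init = z0 + jitter * rng.standard_normal(lay.dim)
            # the jittered start must stay inside the support
            while not math.isfinite(self.logpost_z(z_init)):
                z_init = z0 + jitter * rng.standard_normal(lay.dim)
            directions, direction_scales = self._recentering_directions()
            chain = run_chain(
                self.logpost_z,
                z_init,
                n_iter,
                rng,
                blocks=blocks,
                scales=self._initial_scales(),
                directions=directions,
                direction_scales=direction_scales,
                adapt_frac=n_warmup / n_iter,
            )
            # store natural-scale draws; log_post reported without the
            # change-of-variable Jacobian term
            nat = chain.draws.copy()
            nat[:, lay.positive] = np.exp(nat[:, lay.positive])
            jac = chain.draws[:, lay.positive].sum(axis=1)
            chains.append(
                Chain(
                    draws=nat,
                    log_post=chain.log_post - jac,
                    accept_rate=chain.accept_rate,
                    scales=chain.scales,
                    n_iter=chain.n_iter,
                )
            )
        samples = pool_chains(chains, n_warmup, names=lay.names)
        return DurationResults(
            model=self,
            samples=samples,
            chains=chains,
            n_warmup=n_warmup,
            seed=seed,
        )


# -- reference implementations on EffectParams -----------------------------
# These walk the trial table row by row through scipy.stats and are the
# readable counterparts of the vectorised sufficient-statistic path above;
# the two are tested for agreement.

def log_likelihood(params: EffectParams, trials: pd.DataFrame) -> float:
    """Sum of normal log-densities of ``reproduced_ms`` over trials, with
    per-cell moments from ``params``.  Raises if any observed cell has a
    nonpositive SD or a missing parameter."""
    params.validate_cells()
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table missing columns: {missing}")
    mean = trials["condition"].map(params.beta_mu) * (
        trials["target_duration_ms"].astype(int).map(params.gamma_mu)
        + trials["participant_id"].map(params.u_mu)
    )
    sd = trials["condition"].map(params.beta_sigma) * (
        trials["target_duration_ms"].astype(int).map(params.gamma_sigma)
        + trials["participant_id"].map(params.u_sigma)
    )
    bad = mean.isna() | sd.isna() | (sd <= 0)
    if bad.any():
        row = trials.loc[bad].iloc[0]
        raise ValueError(
            "invalid cell standard deviation or missing parameter in cell "
            f"(condition={row['condition']}, "
            f"duration={row['target_duration_ms']}, "
            f"participant={row['participant_id']})"
        )
    return float(
        stats.norm.logpdf(
            trials["reproduced_ms"].to_numpy(dtype=float),
            loc=mean.to_numpy(dtype=float),
            scale=sd.to_numpy(dtype=float),
        ).sum()
    )


def log_prior(params: EffectParams) -> float:
    """Joint log-prior of ``params``; ``-inf`` outside the support."""
    lp = 0.0
    beta_dist = stats.truncnorm(
        a=-BETA_PRIOR_LOC / BETA_PRIOR_SCALE, b=np.inf,
        loc=BETA_PRIOR_LOC, scale=BETA_PRIOR_SCALE,
    )
    for beta in (params.beta_mu, params.beta_sigma):
        for c in FREE_CONDITIONS:
            lp += float(beta_dist.logpdf(beta[c]))
    for d, g in params.gamma_mu.items():
        lp += float(stats.norm.logpdf(g, loc=d, scale=GAMMA_MU_PRIOR_SCALE))
    for g in params.gamma_sigma.values():
        lp += float(stats.halfnorm.logpdf(g, scale=GAMMA_SIGMA_PRIOR_SCALE))
    if params.tau_mu <= 0 or params.tau_sigma <= 0:
        return -math.inf
    for u in params.u_mu.values():
        lp += float(stats.norm.logpdf(u, scale=params.tau_mu))
    for u in params.u_sigma.values():
        lp += float(stats.norm.logpdf(u, scale=params.tau_sigma))
    for tau in (params.tau_mu, params.tau_sigma):
        lp += float(stats.halfcauchy.logpdf(tau, scale=TAU_PRIOR_SCALE))
    return lp


def log_posterior(params: EffectParams, trials: pd.DataFrame) -> float:
    """``log_likelihood + log_prior``; support violations propagate as
    ``-inf`` instead of raising."""
    lp = log_prior(params)
    if not math.isfinite(lp):
        return -math.inf
    try:
        ll = log_likelihood(params, trials)
    except ValueError:
        return -math.inf
    return lp + ll
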