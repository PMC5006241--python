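"""Block-wise adaptive random-walk Metropolis sampling.

The sampler targets an arbitrary log-density over a flat parameter
vector.  Parameters are updated in blocks with Gaussian proposals whose
per-block scales are adapted toward a target acceptance rate during the
first half of the run (the warmup) and frozen afterwards, so the retained
half is a fixed Markov kernel.  The default scheme is the one used for
the reproduced-duration model: three independent runs of 2000 iterations
each, keeping the latter 1000 of each and pooling to 3000 draws.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Chain:
    """One Metropolis run: iteration-ordered draws plus bookkeeping."""

    draws: np.ndarray  # (n_iter, dim)
    log_post: np.ndarray  # (n_iter,)
    accept_rate: np.ndarray  # per block, measured after adaptation froze
    scales: np.ndarray  # final per-block proposal scales
    n_iter: int

    @property
    def dim(self) -> int:
        return self.draws.shape[1]


def run_chain(
    log_post,
    init,
    n_iter: int,
    rng: np.random.Generator,
    blocks: list[np.ndarray] | None = None,
    scales: np.ndarray | None = None,
    directions: list[np.ndarray] | None = None,
    direction_scales: np.ndarray | None = None,
    target_accept: float = 0.3,
    adapt_frac: float = 0.5,
    adapt_window: int = 50,
) -> Chain:
    """Run one adaptive random-walk Metropolis chain.

    Parameters
    ----------
    log_post
        Callable mapping a parameter vector to a log-density (may return
        ``-inf`` outside the support).
    init
        Starting vector; its log-density must be finite.
    blocks
        List of index arrays updated one at a time per iteration
        (default: a single block over all coordinates).
    scales
        Initial per-block proposal SDs (default 0.1).  During the first
        ``adapt_frac`` of the run each scale is multiplied by
        ``exp(rate - target_accept)`` every ``adapt_window`` iterations,
        then frozen.
    directions
        Optional fixed direction vectors; after the coordinate blocks,
        each iteration also proposes ``x + scale * N(0,1) * direction``.
        Symmetric, so plain Metropolis acceptance applies; useful for
        ridges the axis-aligned blocks traverse slowly.
    """
    x = np.atleast_1d(np.asarray(init, dtype=float)).copy()
    lp = float(log_post(x))
    if not math.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point")

    dim = x.size
    if blocks is None:
        blocks = [np.arange(dim)]
    blocks = [np.asarray(b, dtype=int) for b in blocks]
    n_blocks = len(blocks)
    scales = (
        np.full(n_blocks, 0.1, dtype=float)
        if scales is None
        else np.asarray(scales, dtype=float).copy()
    )
    if scales.size != n_blocks:
        raise ValueError("one proposal scale per block is required")
    directions = [np.asarray(d, dtype=float) for d in (directions or [])]
    n_dirs = len(directions)
    dir_scales = (
        np.full(n_dirs, 0.1, dtype=float)
        if direction_scales is None
        else np.asarray(direction_scales, dtype=float).copy()
    )
    if dir_scales.size != n_dirs:
        raise ValueError("one proposal scale per direction is required")

    n_adapt = int(adapt_frac * n_iter)
    n_moves = n_blocks + n_dirs
    window_acc = np.zeros(n_moves)
    post_acc = np.zeros(n_moves)

    draws = np.empty((n_iter, dim))
    lp_trace = np.empty(n_iter)

    for i in range(n_iter):
        for b, idx in enumerate(blocks):
            prop = x.copy()
            prop[idx] = prop[idx] + scales[b] * rng.standard_normal(idx.size)
            lp_prop = float(log_post(prop))
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                if i < n_adapt:
                    window_acc[b] += 1
                else:
                    post_acc[b] += 1
        for k, direction in enumerate(directions):
            prop = x + dir_scales[k] * rng.standard_normal() * direction
            lp_prop = float(log_post(prop))
            if math.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                if i < n_adapt:
                    window_acc[n_blocks + k] += 1
                else:
                    post_acc[n_blocks + k] += 1
        if i < n_adapt and (i + 1) % adapt_window == 0:
            rate = window_acc / adapt_window
            scales *= np.exp(rate[:n_blocks] - target_accept)
            np.clip(scales, 1e-8, 1e4, out=scales)
            if n_dirs:
                dir_scales *= np.exp(rate[n_blocks:] - target_accept)
                np.clip(dir_scales, 1e-8, 1e4, out=dir_scales)
            window_acc[:] = 0.0
        draws[i] = x
        lp_trace[i] = lp

    n_post = max(n_iter - n_adapt, 1)
    return Chain(
        draws=draws,
        log_post=lp_trace,
        accept_rate=post_acc / n_post,
        scales=np.concatenate([scales, dir_scales]),
        n_iter=n_iter,
    )


def pool_chains(
    chains: list[Chain],
    n_warmup: int,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate post-warmup draws with chain/iteration labels.

    Chains are labelled 1-based; ``iteration`` is the 1-based iteration
    index within its chain (warmup included in the count), so 3 chains of
    2000 iterations with ``n_warmup=1000`` pool to 3000 rows labelled
    1001..2000.
    """
    if not chains:
        raise ValueError("at least one chain is required")
    for c in chains:
        if n_warmup >= c.n_iter:
            raise ValueError(
                f"n_warmup ({n_warmup}) must be smaller than the chain "
                f"length ({c.n_iter})"
            )
    dim = chains[0].dim
    if names is None:
        names = [f"x{j}" for j in range(dim)]
    if len(names) != dim:
        raise ValueError("one name per parameter is required")

    frames = []
    for k, chain in enumerate(chains, start=1):
        post = chain.draws[n_warmup:]
        frame = pd.DataFrame(post, columns=names)
        frame["chain"] = k
        frame["iteration"] = np.arange(n_warmup + 1, chain.n_iter + 1)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def rhat(
    chains: list[Chain],
    n_warmup: int = 0,
    names: list[str] | None = None,
) -> pd.Series:
    """Split-chain Gelman-Rubin potential scale reduction per parameter.

    Each post-warmup chain segment is split in half; the statistic is
    sqrt(((n-1)/n * W + B/n) / W) over the resulting half-chains.
    Parameters with zero within-chain variance are returned as NaN
    (undefined) rather than raising.
    """
    if len(chains) < 2:
        raise ValueError("rhat requires at least 2 chains")
    halves = []
    for c in chains:
        post = c.draws[n_warmup:]
        if len(post) < 4:
            raise ValueError("chains too short to split for rhat")
        mid = len(post) // 2
        halves.append(post[:mid])
        halves.append(post[mid : 2 * mid])
    arr = np.stack(halves)  # (m, n, dim)
    m, n, dim = arr.shape
    means = arr.mean(axis=1)  # (m, dim)
    variances = arr.var(axis=1, ddof=1)  # (m, dim)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (n - 1) / n * w + b / n
        values = np.where(w > 0, np.sqrt(var_plus / w), np.nan)
    if names is None:
        names = [f"x{j}" for j in range(dim)]
    return pd.Series(values, index=names, name="rhat")
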