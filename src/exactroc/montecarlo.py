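"""Monte Carlo simulation of null AUC values.

Each replicate draws n TP and m TN scores from the null model and records
the trapezoidal AUC as an integer *deficit* nm·(1 − AUC), keeping the
lattice arithmetic exact.  The AUC per replicate is obtained from a single
argsort of the pooled scores (rank-sum form of the Mann–Whitney count),
so 10^6–10^8 replicates are feasible on one core.

Reproducibility: replicates are generated in fixed logical blocks of
``BLOCK_REPS`` draws, each block from its own child of the seed's
``SeedSequence``.  The deficit stream therefore depends only on the seed
and the replicate index, not on how the computation is chunked.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .models import NullModel

__all__ = ["MCResult", "simulate_auc", "percentile", "mc_tail_probability"]

#: logical block size: replicates [k·BLOCK_REPS, (k+1)·BLOCK_REPS) always
#: come from spawn key (k,) of the seed sequence; sized so a block of a
#: thousand-observation design stays well inside memory
BLOCK_REPS = 20_000


@dataclass(frozen=True)
class MCResult:
    """Simulated AUC deficits under a null model."""

    deficits: np.ndarray  # integer deficits in [0, nm], length = reps
    n: int
    m: int
    model: NullModel
    seed: int
    reps: int

    @property
    def nm(self) -> int:
        return self.n * self.m

    def aucs(self) -> np.ndarray:
        return 1.0 - self.deficits / self.nm


def _simulate_block(model: NullModel, n: int, m: int, reps: int,
                    rng: np.random.Generator) -> np.ndarray:
    tp = model.sample_tp((reps, n), rng)
    tn = model.sample_tn((reps, m), rng)
    pooled = np.concatenate([tp, tn], axis=1)
    order = np.argsort(pooled, axis=1, kind="stable")
    # sum of 0-based ranks of the TP columns; ties have probability zero
    # under a continuous model, so plain ordinal ranks suffice here
    rank_sum = ((order < n) * np.arange(n + m)).sum(axis=1)
    u = rank_sum - n * (n - 1) // 2
    return (n * m - u).astype(np.int64)


def simulate_auc(model: NullModel, n: int, m: int, reps: int,
                 seed: int) -> MCResult:
    """Simulate ``reps`` independent null AUC values.

    Returns integer deficits; identical output for identical
    ``(model, n, m, reps, seed)`` regardless of internal chunking.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    ss = np.random.SeedSequence(seed)
    n_blocks = (reps + BLOCK_REPS - 1) // BLOCK_REPS
    children = ss.spawn(n_blocks)
    out = np.empty(reps, dtype=np.int64)
    for k in range(n_blocks):
        lo = k * BLOCK_REPS
        hi = min(reps, lo + BLOCK_REPS)
        rng = np.random.default_rng(children[k])
        out[lo:hi] = _simulate_block(model, n, m, hi - lo, rng)
    return MCResult(deficits=out, n=n, m=m, model=model, seed=seed, reps=reps)


def percentile(result: MCResult, alpha: float) -> Fraction:
    """Empirical 100·alpha percentile of the simulated AUC distribution.

    Superlevel-set estimator inf{x : F̂(x) ≥ alpha}: sort the simulated
    AUCs and take the ⌈alpha·k⌉-th smallest.  Returned as the exact
    lattice fraction (nm − deficit)/nm.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k = result.reps
    # AUC ascending == deficit descending
    deficits = np.sort(result.deficits)[::-1]
    idx = int(np.ceil(alpha * k)) - 1
    d = int(deficits[idx])
    return Fraction(result.nm - d, result.nm)


def percentile_deficit(result: MCResult, alpha: float) -> int:
    """Deficit index of :func:`percentile` (smaller = higher AUC)."""
    frac = percentile(result, alpha)
    return result.nm - int(frac * result.nm)


def _threshold_deficit(nm: int, auc_threshold) -> int:
    """Largest deficit d with 1 − d/nm ≥ threshold, robust to float noise."""
    frac = Fraction(auc_threshold).limit_denominator(10**9)
    d = (1 - frac) * nm
    return int(d) if d >= 0 else -1


def mc_tail_probability(result: MCResult, auc_threshold) -> tuple[float, float]:
    """Empirical P(AUC ≥ threshold) with its binomial standard error."""
    d_max = _threshold_deficit(result.nm, auc_threshold)
    hits = int(np.count_nonzero(result.deficits <= d_max))
    p = hits / result.reps
    se = float(np.sqrt(p * (1.0 - p) / result.reps))
    return p, se


def deficit_counts(result: MCResult) -> np.ndarray:
    """Histogram of deficits over the full lattice 0..nm."""
    return np.bincount(result.deficits, minlength=result.nm + 1)
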