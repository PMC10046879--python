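"""Hypothesis testing on the null AUC distribution.

One-sided upper tests: the acceptance region is [0, c] where the critical
value c is the smallest lattice AUC with P(AUC > c) ≤ α under the null;
an observed AUC above c rejects.  p-values are inclusive upper-tail
probabilities P(AUC ≥ observed).  Bonferroni correction divides the
type-one error probability by the number of simultaneous hypotheses —
with composite biomarkers built from feature pairs this number grows
combinatorially, pushing the working α deep into the tail where only the
exact computation is trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .interpolation import AUCDistribution

__all__ = [
    "TestSpec",
    "p_value",
    "critical_value",
    "bonferroni_alpha",
    "composite_hypothesis_count",
    "delta_for_auc",
]


@dataclass(frozen=True)
class TestSpec:
    """One-sided upper test at a given confidence level, Bonferroni-corrected
    for a number of simultaneous hypotheses."""

    __test__ = False  # keep pytest from collecting this as a test class

    level: float = 0.99          # confidence level; type-one alpha = 1 - level
    hypotheses: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.hypotheses < 1:
            raise ValueError("hypotheses must be at least 1")

    @property
    def alpha(self) -> float:
        return 1.0 - self.level

    @property
    def corrected_alpha(self) -> float:
        return bonferroni_alpha(self.level, self.hypotheses)


def _deficit_at_or_above(nm: int, auc_obs) -> int:
    """Largest deficit whose lattice AUC is ≥ auc_obs (next lattice point at
    or above an off-lattice observation)."""
    frac = Fraction(auc_obs).limit_denominator(10**9)
    if not 0 <= frac <= 1:
        raise ValueError("observed AUC must lie in [0, 1]")
    return math.floor((1 - frac) * nm)


def p_value(auc_obs, dist: AUCDistribution) -> float:
    """One-sided upper p-value P(AUC ≥ auc_obs), inclusive at lattice points."""
    d = _deficit_at_or_above(dist.nm, auc_obs)
    return float(np.sum(dist.probs[:d + 1]))


def critical_value(spec: TestSpec, dist: AUCDistribution) -> Fraction:
    """Smallest lattice AUC c with P(AUC > c) ≤ corrected α.

    Conservative on the discrete lattice: rejection requires observed > c.
    Raises if the distribution's resolvable tail cannot represent α (the
    exact tail would need deepening).
    """
    alpha = spec.corrected_alpha
    cum = dist.upper_tail()  # cum[i] = P(AUC >= 1 - i/nm) = P(AUC > 1-(i+1)/nm)
    if alpha < cum[0]:
        raise ValueError(
            f"corrected alpha {alpha:.3e} is below the topmost tail mass "
            f"{cum[0]:.3e}; the null cannot resolve this level at these "
            "sample sizes")
    # P(AUC > 1 - d/nm) = cum[d-1]; want the largest d with cum[d-1] <= alpha
    d = int(np.searchsorted(cum, alpha, side="right"))
    return Fraction(dist.nm - d, dist.nm)


def bonferroni_alpha(level: float, hypotheses: int) -> float:
    """Corrected per-hypothesis type-one error (1 − level)/hypotheses."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if hypotheses < 1:
        raise ValueError("hypotheses must be at least 1")
    return (1.0 - level) / hypotheses


def composite_hypothesis_count(n_features: int, directions_per_pair: int,
                               cohorts: int) -> int:
    """Number of simultaneously tested composite biomarkers:
    binomial(n_features, 2) · directions_per_pair · cohorts."""
    if n_features < 2:
        raise ValueError("need at least two features to form pairs")
    if directions_per_pair < 1 or cohorts < 1:
        raise ValueError("directions_per_pair and cohorts must be positive")
    return math.comb(n_features, 2) * directions_per_pair * cohorts


def delta_for_auc(target_auc: float) -> float:
    """Equal-variance binormal mean difference with population AUC
    ``target_auc``: delta = √2 · Φ⁻¹(target_auc)."""
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie in (0.5, 1)")
    return float(math.sqrt(2.0) * stats.norm.ppf(target_auc))
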