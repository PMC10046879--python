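"""Geometric interpolation between the exact tail and the Monte Carlo body.

Write x_i for P(AUC = 1 − i/nm) and k_i for the number of ROC curves with
deficit i.  In the far upper tail the ratio of subsequent probability
differences tracks the ratio of subsequent count differences up to a
constant:

    Δx_i / Δx_{i−1} ≈ C · Δk_i / Δk_{i−1},      Δx_i = x_i − x_{i−1},

with equality at C = 1 when the TP and TN score distributions coincide
(then x_i = k_i·n!m!/(n+m)! exactly).  Rearranged, the recurrence

    x_i ≈ x_{i−1} + C · Δk_i · Δx_{i−1} / Δk_{i−1}

extends an exactly computed tail x_0..x_T deficit by deficit until it
meets the Monte Carlo body.  C is fitted by bisection so that the bridged
upper-tail mass at a Monte Carlo percentile equals the Monte Carlo
estimate of that mass.

For highly unbalanced designs the ratio drifts instead of stabilising; an
alternative coefficient path rises monotonically from the tail value to 1
at the distribution's median deficit (where the S-shaped distribution
function has Δx_i/Δx_{i−1} = 1):

    c_i = 1 − (1 − C_tail) · ((i_med − i)/(i_med − i_tail))^p,   p > 0,

with p fitted by the same percentile-matching criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .counting import CountTable
from .exact_tail import TailTable
from .montecarlo import MCResult, deficit_counts, percentile_deficit

__all__ = [
    "BridgeCoefficient",
    "AUCDistribution",
    "fit_C",
    "geometric_bridge",
    "assemble_distribution",
    "ratio_diagnostics",
]

log = logging.getLogger(__name__)

#: relative mismatch at block junctions above which a diagnostic is emitted
JUNCTION_TOL = 0.05


@dataclass(frozen=True)
class BridgeCoefficient:
    """Fitted coefficient of the geometric recurrence.

    ``form`` is ``"constant"`` (a single C) or ``"exponent"`` (a monotone
    path from ``C`` at the tail end to 1 at the median deficit index,
    with exponent ``p``).
    """

    form: str
    C: float
    p: float | None = None
    i_med: int | None = None
    i_tail: int | None = None

    def path(self, i: np.ndarray) -> np.ndarray:
        """Coefficient c_i at deficits ``i``."""
        if self.form == "constant":
            return np.full_like(np.asarray(i, dtype=float), self.C)
        frac = (self.i_med - np.asarray(i, dtype=float)) / (self.i_med - self.i_tail)
        frac = np.clip(frac, 0.0, None)
        return 1.0 - (1.0 - self.C) * frac ** self.p


@dataclass(frozen=True)
class AUCDistribution:
    """Null distribution of the AUC over the full lattice 0..nm.

    ``source`` flags each deficit as ``exact``, ``interpolated`` or
    ``monte_carlo``; the three blocks are contiguous from the top of the
    lattice downward.
    """

    n: int
    m: int
    probs: np.ndarray       # P(deficit = i), i = 0..nm
    source: np.ndarray      # str array, same length
    junction_exact: int     # last exact deficit
    junction_mc: int        # last interpolated deficit (MC body beyond)

    @property
    def nm(self) -> int:
        return self.n * self.m

    def upper_tail(self) -> np.ndarray:
        """cum[i] = P(AUC ≥ 1 − i/nm) = Σ_{j≤i} probs[j]."""
        return np.cumsum(self.probs)

    def support_size(self) -> int:
        return self.nm + 1


def _bridge_deltas(tail_probs: np.ndarray, counts: CountTable,
                   coeff: BridgeCoefficient, i_stop: int) -> np.ndarray:
    """Extend x beyond the exact range by the geometric recurrence."""
    T = len(tail_probs) - 1
    if counts.i_max < i_stop:
        raise ValueError("count table does not cover the bridged range")
    if T < 1:
        raise ValueError("need at least two exact tail entries to bridge")
    x = np.empty(i_stop + 1)
    x[:T + 1] = tail_probs
    dx_prev = tail_probs[T] - tail_probs[T - 1]
    dk_prev = counts[T] - counts[T - 1]
    # last usable ratio Δx/Δk, carried across Δk = 0 plateaus
    ratio = dx_prev / float(dk_prev) if dk_prev != 0 else None
    cs = coeff.path(np.arange(i_stop + 1))
    for i in range(T + 1, i_stop + 1):
        dk_i = counts[i] - counts[i - 1]
        if ratio is None:
            raise ValueError("Δk vanished at the bridge anchor; "
                             "extend the exact tail by one deficit")
        dx_i = cs[i] * float(dk_i) * ratio
        x[i] = x[i - 1] + dx_i
        if dk_i != 0:
            ratio = dx_i / float(dk_i)
        else:
            log.info("Δk = 0 at deficit %d; carrying previous Δx/Δk forward", i)
    return x


def geometric_bridge(tail: TailTable, counts: CountTable,
                     coeff: BridgeCoefficient, i_stop: int) -> np.ndarray:
    """Probabilities x_0..x_{i_stop}: exact up to the tail's i_max, then
    extended by the geometric recurrence with coefficient path ``coeff``."""
    if i_stop <= tail.i_max:
        raise ValueError("i_stop must exceed the exact tail range")
    return _bridge_deltas(tail.probs, counts, coeff, i_stop)


def _bridged_upper_mass(tail: TailTable, counts: CountTable, C: float,
                        d_star: int, form: str = "constant",
                        p: float | None = None, i_med: int | None = None) -> float:
    coeff = BridgeCoefficient(form=form, C=C, p=p, i_med=i_med,
                              i_tail=tail.i_max)
    if d_star <= tail.i_max:
        return float(np.sum(tail.probs[:d_star + 1]))
    with np.errstate(over="ignore"):
        # extreme bracket endpoints (C ~ 1e3) can overflow to inf, which
        # still carries the right sign for the bisection
        x = _bridge_deltas(tail.probs, counts, coeff, d_star)
        return float(np.sum(x))


def fit_C(tail: TailTable, counts: CountTable, mc: MCResult,
          match_alpha: float = 0.999, form: str = "constant",
          rel_tol: float = 1e-6,
          bracket: tuple[float, float] = (1e-3, 1e3)) -> BridgeCoefficient:
    """Fit the bridge coefficient by percentile matching.

    The Monte Carlo estimate of the 100·``match_alpha`` percentile is a
    lattice AUC with deficit d*; the coefficient is chosen by bisection
    (on log C, or on log p for the exponent form) so that the bridged
    upper-tail mass at d* equals the empirical fraction of simulated AUCs
    at or above that percentile.  With identical TP/TN distributions and
    an exact empirical distribution this recovers C = 1.
    """
    if tail.i_max < 2:
        raise ValueError("tail must contain at least three entries")
    if not 0.0 < match_alpha < 1.0:
        raise ValueError("match_alpha must lie in (0, 1)")
    d_star = percentile_deficit(mc, match_alpha)
    target = float(np.count_nonzero(mc.deficits <= d_star)) / mc.reps
    if d_star <= tail.i_max:
        # exact tail already reaches the match percentile; no bridge needed
        log.info("match percentile inside the exact tail; returning C = 1")
        return BridgeCoefficient(form="constant", C=1.0, i_tail=tail.i_max)

    if form == "constant":
        def objective(logc: float) -> float:
            return (_bridged_upper_mass(tail, counts, float(np.exp(logc)),
                                        d_star) - target)

        lo, hi = np.log(bracket[0]), np.log(bracket[1])
        if objective(lo) * objective(hi) > 0:
            raise ValueError(
                "no sign change for C in the bracket %s; widen the bracket or "
                "try the exponent form" % (bracket,))
        while hi - lo > rel_tol:  # bisection on log C => relative tolerance
            mid = 0.5 * (lo + hi)
            if objective(lo) * objective(mid) <= 0:
                hi = mid
            else:
                lo = mid
        C = float(np.exp(0.5 * (lo + hi)))
        return BridgeCoefficient(form="constant", C=C, i_tail=tail.i_max)

    if form == "exponent":
        i_med = int(np.median(mc.deficits))
        C_tail = _tail_ratio_estimate(tail, counts)

        def objective_p(logp: float) -> float:
            return (_bridged_upper_mass(tail, counts, C_tail, d_star,
                                        form="exponent", p=float(np.exp(logp)),
                                        i_med=i_med) - target)

        lo, hi = np.log(1e-2), np.log(1e2)
        if objective_p(lo) * objective_p(hi) > 0:
            raise ValueError("no sign change for the exponent p; the tail "
                             "ratio estimate may be unsuitable")
        while hi - lo > rel_tol:
            mid = 0.5 * (lo + hi)
            if objective_p(lo) * objective_p(mid) <= 0:
                hi = mid
            else:
                lo = mid
        p = float(np.exp(0.5 * (lo + hi)))
        return BridgeCoefficient(form="exponent", C=C_tail, p=p, i_med=i_med,
                                 i_tail=tail.i_max)

    raise ValueError(f"unknown coefficient form {form!r}")


def _tail_ratio_estimate(tail: TailTable, counts: CountTable) -> float:
    """Anchor coefficient for the exponent form: the mean normalised ratio
    over the last few exact deficits."""
    ratios = ratio_diagnostics(tail, counts)
    vals = [r for _, r in ratios[-5:] if np.isfinite(r)]
    if not vals:
        raise ValueError("no finite normalised ratios at the tail end")
    return float(np.mean(vals))


def ratio_diagnostics(tail: TailTable,
                      counts: CountTable) -> list[tuple[int, float]]:
    """Normalised ratios (Δx_i/Δx_{i−1}) / (Δk_i/Δk_{i−1}) for i ≥ 2.

    The constancy of this sequence is what justifies a constant C; with
    identical TP/TN distributions it is identically 1.  Indices where a
    difference vanishes are reported with value NaN rather than computed.
    """
    if tail.i_max < 2:
        raise ValueError("tail must contain at least three entries")
    out: list[tuple[int, float]] = []
    for i in range(2, tail.i_max + 1):
        dx_i = tail.probs[i] - tail.probs[i - 1]
        dx_p = tail.probs[i - 1] - tail.probs[i - 2]
        dk_i = counts[i] - counts[i - 1]
        dk_p = counts[i - 1] - counts[i - 2]
        if dx_p == 0 or dk_i == 0 or dk_p == 0:
            out.append((i, float("nan")))
            continue
        out.append((i, float((dx_i / dx_p) / (dk_i / float(dk_p)))))
    return out


def assemble_distribution(tail: TailTable, bridged: np.ndarray | None,
                          mc: MCResult | None) -> AUCDistribution:
    """Merge exact tail, bridged extension and Monte Carlo body into one
    distribution over the full deficit lattice 0..nm.

    The exact block covers deficits 0..tail.i_max, the bridge continues to
    the end of ``bridged``, and the Monte Carlo empirical frequencies fill
    the remainder.  A junction mismatch above ``JUNCTION_TOL`` (relative,
    between the bridged upper-tail mass at the junction and its empirical
    counterpart) triggers a warning with diagnostics.
    """
    n, m = tail.n, tail.m
    nm = n * m
    probs = np.zeros(nm + 1)
    source = np.array(["monte_carlo"] * (nm + 1), dtype=object)

    j_exact = tail.i_max
    probs[:j_exact + 1] = tail.probs
    source[:j_exact + 1] = "exact"

    if bridged is not None:
        j_mc = len(bridged) - 1
        if j_mc > nm:
            raise ValueError("bridged range exceeds the lattice")
        probs[j_exact + 1:j_mc + 1] = bridged[j_exact + 1:]
        source[j_exact + 1:j_mc + 1] = "interpolated"
    else:
        j_mc = j_exact

    if mc is not None:
        if (mc.n, mc.m) != (n, m):
            raise ValueError("Monte Carlo result has mismatched sample sizes")
        freq = deficit_counts(mc) / mc.reps
        if j_mc < nm:
            probs[j_mc + 1:] = freq[j_mc + 1:]
        # junction diagnostic: bridged vs empirical upper-tail mass at j_mc
        bridged_mass = float(np.sum(probs[:j_mc + 1]))
        empirical_mass = float(np.count_nonzero(mc.deficits <= j_mc)) / mc.reps
        if empirical_mass > 0 and bridged_mass > 0:
            rel = abs(bridged_mass - empirical_mass) / empirical_mass
            if rel > JUNCTION_TOL:
                warnings.warn(
                    f"junction mismatch at deficit {j_mc}: bridged upper-tail "
                    f"mass {bridged_mass:.3e} vs empirical {empirical_mass:.3e} "
                    f"({100 * rel:.1f}% relative)", RuntimeWarning)
    elif j_mc < nm:
        raise ValueError("no Monte Carlo body to cover deficits beyond "
                         f"{j_mc}")

    total = probs.sum()
    if total > 1.0 + 1e-6:
        warnings.warn(f"assembled mass {total:.6f} exceeds 1", RuntimeWarning)
    return AUCDistribution(n=n, m=m, probs=probs, source=source,
                           junction_exact=j_exact, junction_mc=j_mc)
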