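"""Empirical ROC curves and the trapezoidal AUC.

The trapezoidal AUC of a two-sample score set equals U/(nm), where U is the
Mann–Whitney count of (TP, TN) pairs with the TN score below the TP score,
ties counted one half.  Everything downstream — exact tails, Monte Carlo,
bridging — lives on the lattice {0, 1/nm, ..., 1}, so the AUC is kept as an
exact rational and the *deficit* nm·(1 − AUC) as an integer (half-integer
under ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCSample",
    "AUCValue",
    "trapezoidal_auc",
    "roc_points",
    "partial_auc",
    "read_scores_tsv",
    "read_scores_two_files",
    "write_roc_points_tsv",
]


@dataclass(frozen=True)
class ROCSample:
    """Scores of ``n`` true positives (cases) and ``m`` true negatives."""

    tp_scores: tuple
    tn_scores: tuple

    def __init__(self, tp_scores: Sequence[float], tn_scores: Sequence[float]):
        tp = tuple(float(v) for v in tp_scores)
        tn = tuple(float(v) for v in tn_scores)
        if len(tp) < 1 or len(tn) < 1:
            raise ValueError("need at least one TP and one TN score")
        if not all(np.isfinite(tp)) or not all(np.isfinite(tn)):
            raise ValueError("scores must be finite real numbers")
        object.__setattr__(self, "tp_scores", tp)
        object.__setattr__(self, "tn_scores", tn)

    @property
    def n(self) -> int:
        return len(self.tp_scores)

    @property
    def m(self) -> int:
        return len(self.tn_scores)

    def swapped(self) -> "ROCSample":
        return ROCSample(self.tn_scores, self.tp_scores)


@dataclass(frozen=True)
class AUCValue:
    """Trapezoidal AUC with its exact rational representation.

    ``u_wins`` is the Mann–Whitney count with the half-tie convention; it is
    stored doubled (``u2 = 2·U``) so the value is always an exact integer.
    """

    u2: int
    n: int
    m: int

    @property
    def u_wins(self) -> Fraction:
        return Fraction(self.u2, 2)

    @property
    def value(self) -> Fraction:
        return Fraction(self.u2, 2 * self.n * self.m)

    @property
    def deficit(self) -> Fraction:
        """nm·(1 − AUC); an integer for tie-free samples."""
        return self.n * self.m - self.u_wins

    def __float__(self) -> float:
        return self.u2 / (2.0 * self.n * self.m)


def trapezoidal_auc(sample: ROCSample) -> AUCValue:
    """Trapezoidal AUC = U/(nm) with ties counted one half.

    Computed by rank-sum rather than a pairwise loop, so it scales as
    (n+m)·log(n+m).
    """
    tp = np.asarray(sample.tp_scores)
    tn = np.asarray(sample.tn_scores)
    n, m = tp.size, tn.size
    combined = np.concatenate([tp, tn])
    ranks = stats.rankdata(combined)  # midranks for ties
    # U = sum of TP ranks − n(n+1)/2; midranks make 2U an exact integer
    u2 = int(round(2.0 * (ranks[:n].sum() - n * (n + 1) / 2.0)))
    return AUCValue(u2=u2, n=n, m=m)


def roc_points(sample: ROCSample) -> list[tuple[Fraction, Fraction]]:
    """Empirical ROC staircase as exact (FPR, TPR) pairs.

    The threshold sweeps from above the largest score downward; tied TP/TN
    scores are grouped into a single diagonal step.  The trapezoid area
    under the returned polyline equals :func:`trapezoidal_auc`.
    """
    n, m = sample.n, sample.m
    scores = np.concatenate([sample.tp_scores, sample.tn_scores])
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(m, dtype=int)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]

    pts: list[tuple[Fraction, Fraction]] = [(Fraction(0), Fraction(0))]
    tp_seen = 0
    fp_seen = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp_seen += int(labels[i:j].sum())
        fp_seen += int((1 - labels[i:j]).sum())
        pts.append((Fraction(fp_seen, m), Fraction(tp_seen, n)))
        i = j
    return pts


def _staircase_area(pts: Sequence[tuple[Fraction, Fraction]],
                    fpr_hi: Fraction) -> Fraction:
    """Trapezoid area under a polyline restricted to FPR in [0, fpr_hi]."""
    area = Fraction(0)
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x0 >= fpr_hi:
            break
        if x1 <= fpr_hi:
            area += (x1 - x0) * (y0 + y1) / 2
        else:  # clip the segment at fpr_hi
            t = (fpr_hi - x0) / (x1 - x0)
            y_cut = y0 + t * (y1 - y0)
            area += (fpr_hi - x0) * (y0 + y_cut) / 2
            break
    return area


def partial_auc(sample: ROCSample, fpr_hi: float) -> float:
    """Area under the empirical ROC restricted to FPR in [0, ``fpr_hi``]."""
    hi = Fraction(fpr_hi).limit_denominator(10**12)
    if not 0 < hi <= 1:
        raise ValueError("fpr_hi must lie in (0, 1]")
    return float(_staircase_area(roc_points(sample), hi))


# ---------------------------------------------------------------------------
# plain-text I/O

_TP_LABELS = {"TP", "1", "CASE", "POS", "POSITIVE"}
_TN_LABELS = {"TN", "0", "CONTROL", "NEG", "NEGATIVE"}


def read_scores_tsv(path) -> ROCSample:
    """Read a two-column TSV of (label, score) rows.

    Labels may be TP/TN, 1/0, case/control, pos/neg (case-insensitive).
    A header line is detected and skipped if its second field is not numeric.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["label", "score"], dtype=str)
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    labels = df["label"].str.strip().str.upper()
    scores = df["score"].astype(float)
    is_tp = labels.isin(_TP_LABELS)
    is_tn = labels.isin(_TN_LABELS)
    if not (is_tp | is_tn).all():
        bad = labels[~(is_tp | is_tn)].unique()
        raise ValueError(f"unrecognised labels in score file: {list(bad)}")
    return ROCSample(scores[is_tp].tolist(), scores[is_tn].tolist())


def read_scores_two_files(tp_path, tn_path) -> ROCSample:
    """Read TP and TN scores from two single-column text files."""
    tp = np.loadtxt(tp_path, ndmin=1)
    tn = np.loadtxt(tn_path, ndmin=1)
    return ROCSample(tp.tolist(), tn.tolist())


def write_roc_points_tsv(sample: ROCSample, path) -> None:
    """Write the ROC staircase as a (fpr, tpr) TSV."""
    pts = roc_points(sample)
    df = pd.DataFrame({"fpr": [float(x) for x, _ in pts],
                       "tpr": [float(y) for _, y in pts]})
    df.to_csv(path, sep="\t", index=False)
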