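"""Reproducible synthetic inputs and worked micro-examples.

Everything here is generated from recorded seeds and parameters; no
external data.  Scores in the hand-built configurations are small integers
— only ranks matter for the ROC.
"""

from __future__ import annotations

import numpy as np

from .exact_tail import partition_to_word, partitions_box, TP
from .models import BinormalModel
from .roc_core import ROCSample

__all__ = ["binormal_sample", "five_curve_configurations"]


def binormal_sample(delta: float, n: int, m: int, seed: int) -> ROCSample:
    """One sample from the equal-variance binormal model: n TP scores from
    N(delta, 1), m TN scores from N(0, 1).  Bit-identical for a given seed."""
    model = BinormalModel(delta=delta)
    rng = np.random.default_rng(seed)
    return ROCSample(model.sample_tp(n, rng).tolist(),
                     model.sample_tn(m, rng).tolist())


def five_curve_configurations() -> list[ROCSample]:
    """The five distinct score configurations with AUC exactly 26/30 for
    n = 5 TPs and m = 6 TNs.

    One configuration per partition of the deficit 4 into at most 5 parts
    each at most 6; each yields a distinct ROC staircase.  Scores are the
    integers 1..11 assigned along the interleaving word.
    """
    n, m = 5, 6
    samples = []
    for part in partitions_box(4, n, m):
        word = partition_to_word(part, n, m)
        tp_scores = [float(pos + 1) for pos, lab in enumerate(word) if lab == TP]
        tn_scores = [float(pos + 1) for pos, lab in enumerate(word) if lab != TP]
        samples.append(ROCSample(tp_scores, tn_scores))
    return samples
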