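"""Confusion-matrix metrics for essentiality calls and flux comparison.

Predictions from knockout screens are compared against experimental
essentiality calls (e.g. a genome-wide knockout library grown on minimal
medium) through a 2x2 confusion matrix. Accuracy and the Matthews
correlation coefficient (MCC) summarize agreement; squared log-scale
Pearson correlation compares two flux solutions across reactions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyMatrixError, InsufficientDataError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts over (predicted, experimental) essentiality calls.

    tp: predicted essential & experimentally essential;
    fp: predicted essential & experimentally nonessential;
    fn: predicted nonessential & experimentally essential;
    tn: both nonessential.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn


def accuracy(cm):
    """(tp + tn) / total."""
    if cm.total == 0:
        raise EmptyMatrixError("cannot compute accuracy of an empty matrix")
    return (cm.tp + cm.tn) / cm.total


def matthews_cc(cm):
    """Matthews correlation coefficient, in [-1, 1].

    Returns 0 (with a warning) when any marginal is zero, the usual
    degenerate-classifier convention.
    """
    marginals = (
        (cm.tp + cm.fp),
        (cm.tp + cm.fn),
        (cm.tn + cm.fp),
        (cm.tn + cm.fn),
    )
    if any(m == 0 for m in marginals):
        warnings.warn("degenerate confusion-matrix marginal; MCC set to 0",
                      stacklevel=2)
        return 0.0
    numerator = cm.tp * cm.tn - cm.fp * cm.fn
    return numerator / math.sqrt(math.prod(marginals))


def flux_r_squared(fluxes_a, fluxes_b, floor=1e-14):
    """Squared Pearson correlation of log10 flux magnitudes.

    Zero (and sub-floor) fluxes are replaced by ``floor`` before taking
    logs so that inactive reactions can participate; only ids present in
    both maps are compared.
    """
    shared = sorted(set(fluxes_a) & set(fluxes_b))
    if len(shared) < 2:
        raise InsufficientDataError(
            f"need at least 2 shared reactions, got {len(shared)}"
        )
    a = np.log10(np.maximum(np.abs([fluxes_a[k] for k in shared]), floor))
    b = np.log10(np.maximum(np.abs([fluxes_b[k] for k in shared]), floor))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        # zero variance: identical-constant vectors correlate perfectly
        return 1.0 if np.allclose(a - a[0], b - b[0]) else 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def read_experimental_calls(path):
    """Read a TSV of ``gene<TAB>{essential,nonessential}`` into a dict."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["gene", "call"], dtype=str)
    calls = {}
    for gene, call in zip(table["gene"], table["call"]):
        call = call.strip().lower()
        if call not in {"essential", "nonessential"}:
            raise ValueError(f"unknown essentiality call {call!r} for {gene}")
        calls[gene.strip()] = call
    return calls


def compare_calls(predicted, experimental):
    """Build a confusion matrix over genes present in both call sets.

    Returns ``(matrix, excluded)`` where ``excluded`` lists experimental
    genes absent from the predictions (the comparison is restricted to
    genes actually modeled).
    """
    tp = fp = fn = tn = 0
    excluded = []
    for gene, observed in sorted(experimental.items()):
        prediction = predicted.get(gene)
        if prediction is None:
            excluded.append(gene)
            continue
        if prediction == "essential":
            tp += observed == "essential"
            fp += observed == "nonessential"
        else:
            fn += observed == "essential"
            tn += observed == "nonessential"
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn), excluded


def metric_report(cm):
    """Accuracy (percent, 1 decimal) and MCC (3 decimals) as printed."""
    return {
        "accuracy_percent": round(100.0 * accuracy(cm), 1),
        "mcc": round(matthews_cc(cm), 3),
        "n": cm.total,
    }
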