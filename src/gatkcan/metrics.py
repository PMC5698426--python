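"""Performance measures: TPR, conditional FPR, precision, MCC, FPR per Mb.

Truth conventions for called-variant evaluation: a true mutation is a
positive (TP when predicted), a false mutation among the called variants is
a negative (TN when filtered). The conditional FPR (cFPR) is the fraction
of those negatives that survive filtering — the clinically relevant error
rate on the called set — while FPR per Mb relates surviving predictions to
a sampled count of reference sites. Every ratio with a zero denominator is
defined as 0 (the MCC convention, extended) so cohort sweeps never divide
by zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

from .types import ConfusionCounts, Label, MetricSet, Prediction

__all__ = [
    "confusion",
    "confusion_from_arrays",
    "mcc",
    "rates",
    "fpr_per_mb",
    "adjusted_metrics",
    "metric_set",
]


def _as_label(value) -> Label:
    if isinstance(value, Prediction):
        return value.label
    if isinstance(value, Label):
        return value
    if isinstance(value, str):
        return Label(value)
    # integer encoding from the estimators: 1 = true mutation
    return Label.TRUE_MUTATION if int(value) == 1 else Label.ARTIFACT


def confusion(preds: Mapping, truths: Mapping) -> ConfusionCounts:
    """Tally TP/FP/TN/FN over every predicted key; each needs a truth label."""
    tp = fp = tn = fn = 0
    for key, pred in preds.items():
        if key not in truths:
            raise KeyError(f"no truth label for predicted key {key}")
        p = _as_label(pred) is Label.TRUE_MUTATION
        t = _as_label(truths[key]) is Label.TRUE_MUTATION
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_from_arrays(pred, truth) -> ConfusionCounts:
    """Tally from parallel 0/1 arrays (1 = true mutation)."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth, strict=True):
        if p and t:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return num / math.sqrt(denom)


def _ratio(num: int, denom: int) -> float:
    return num / denom if denom else 0.0


def rates(c: ConfusionCounts) -> MetricSet:
    """TPR = TP/(TP+FN), cFPR = FP/(FP+TN), precision = TP/(TP+FP)."""
    return MetricSet(
        tpr=_ratio(c.tp, c.tp + c.fn),
        cfpr=_ratio(c.fp, c.fp + c.tn),
        precision=_ratio(c.tp, c.tp + c.fp),
        mcc=mcc(c),
    )


def metric_set(c: ConfusionCounts, fpr_per_mb_value: float | None = None) -> MetricSet:
    r = rates(c)
    return MetricSet(
        tpr=r.tpr, cfpr=r.cfpr, precision=r.precision, mcc=r.mcc, fpr_per_mb=fpr_per_mb_value
    )


def fpr_per_mb(n_predicted: int, n_reference_sites: int) -> float:
    """Surviving predictions per megabase of sampled reference sites."""
    if n_reference_sites < 1:
        raise ValueError("n_reference_sites must be >= 1")
    return n_predicted / (n_reference_sites / 1e6)


def adjusted_metrics(preds: Mapping, truths: Mapping, subset: Iterable) -> MetricSet:
    """The same measures restricted to a subset of variant keys.

    Mirrors evaluation on externally agreed somatic variants: only keys in
    ``subset`` are tallied. The subset must be non-empty and contained in
    the predicted keys.
    """
    subset = set(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    missing = subset - set(preds)
    if missing:
        raise KeyError(f"subset keys absent from predictions: {sorted(missing)[:3]}...")
    sub_preds = {k: preds[k] for k in subset}
    return metric_set(confusion(sub_preds, truths))
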