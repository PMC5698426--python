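"""Variant classification: hard filtering, the trained rule, cohort runs.

Thin functional surface over the estimators in :mod:`gatkcan.estimators`.
Known-SNP/germline sites are removed *before* classification: a germline
match is not an artifact call, it simply leaves the somatic candidate set.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import pandas as pd

from .estimators import HardFilterClassifier, ThresholdRuleClassifier
from .features import build_feature_frame
from .stats import DerivedStats
from .types import (
    AnnotationVector,
    Label,
    Prediction,
    SiteCatalog,
    ThresholdSet,
    VariantCall,
    VariantClass,
)

__all__ = [
    "hard_filter_snv",
    "hard_filter_indel",
    "exclude_known_sites",
    "classify_variant",
    "classify_cohort",
]


def _annotation_row(a: AnnotationVector, dnm: float = float("inf"), mw_p: float | None = None):
    import numpy as np

    return pd.DataFrame(
        [
            {
                "qd": np.nan if a.qd is None else a.qd,
                "fs": np.nan if a.fs is None else a.fs,
                "mq": np.nan if a.mq is None else a.mq,
                "mq_rank_sum": np.nan if a.mq_rank_sum is None else a.mq_rank_sum,
                "read_pos_rank_sum": np.nan
                if a.read_pos_rank_sum is None
                else a.read_pos_rank_sum,
                "dnm": dnm,
                "mw_p": np.nan if mw_p is None else mw_p,
            }
        ]
    )


def hard_filter_snv(a: AnnotationVector) -> Prediction:
    """GATK SNV hard filter: artifact iff QD < 2.0, FS > 60.0, MQ < 40.0,
    MQRankSum < −12.5 or ReadPosRankSum < −8.0; missing and boundary values pass."""
    clf = HardFilterClassifier(scope="snv").fit()
    return clf.predict_detailed(_annotation_row(a))[0]


def hard_filter_indel(a: AnnotationVector) -> Prediction:
    """GATK indel hard filter: artifact iff QD < 2.0, FS > 200.0 or
    ReadPosRankSum < −20.0."""
    clf = HardFilterClassifier(scope="indel").fit()
    return clf.predict_detailed(_annotation_row(a))[0]


def exclude_known_sites(
    calls: Sequence[VariantCall], *lists: SiteCatalog
) -> tuple[list[VariantCall], int]:
    """Drop calls exactly matching any known-SNP/germline list; keep order.

    Returns (kept calls, number dropped).
    """
    kept: list[VariantCall] = []
    dropped = 0
    for call in calls:
        if any(
            lst.contains_exact(call.chrom, call.pos, call.ref_allele, call.alt_allele)
            for lst in lists
        ):
            dropped += 1
        else:
            kept.append(call)
    return kept, dropped


def classify_variant(v: VariantCall, d: DerivedStats, t: ThresholdSet) -> Prediction:
    """Apply the trained rule to one call given its derived statistics.

    dNM == 0 (exact catalog match) short-circuits to TRUE_MUTATION no matter
    what the annotations say; otherwise any strict cutoff violation makes an
    artifact. ReadPosRankSum is never consulted.
    """
    if t.scope is not v.variant_class:
        raise ValueError(
            f"threshold scope {t.scope.value} does not match variant class "
            f"{v.variant_class.value}"
        )
    rule = ThresholdRuleClassifier.from_threshold_set(t)
    row = _annotation_row(v.annotations, dnm=d.dnm, mw_p=d.mw_p)
    return rule.predict_detailed(row)[0]


def classify_cohort(
    calls: Sequence[VariantCall],
    catalog: SiteCatalog,
    snp_lists: Sequence[SiteCatalog] = (),
    thresholds_snv: ThresholdSet | None = None,
    thresholds_indel: ThresholdSet | None = None,
) -> tuple[dict[tuple, Prediction], Counter, int]:
    """Classify a cohort of calls; returns (predictions, failure tally, n_excluded).

    Known-site exclusion runs first; the per-site strand test is computed
    once across tumors and shared; each call is then routed to the threshold
    set matching its variant class. Calls of a class without a threshold set
    are skipped. Fully deterministic.
    """
    kept, dropped = exclude_known_sites(calls, *snp_lists)
    frame = build_feature_frame(kept, catalog)
    predictions: dict[tuple, Prediction] = {}
    tally: Counter = Counter()
    for scope, ts in (
        (VariantClass.SNV, thresholds_snv),
        (VariantClass.INDEL, thresholds_indel),
    ):
        if ts is None:
            continue
        if ts.scope is not scope:
            raise ValueError(f"threshold set for {scope.value} has scope {ts.scope.value}")
        mask = frame["variant_class"] == scope.value
        if not mask.any():
            continue
        rule = ThresholdRuleClassifier.from_threshold_set(ts)
        sub = frame[mask]
        preds = rule.predict_detailed(sub)
        for (_, row), pred in zip(sub.iterrows(), preds):
            key = (row["tumor_id"], row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            predictions[key] = pred
            for stat in pred.failed_statistics:
                tally[stat] += 1
    return predictions, tally, dropped
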