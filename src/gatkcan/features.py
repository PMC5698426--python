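"""Assemble the per-variant feature table the classifier and trainer consume.

One row per called variant with the six filtering statistics: the five VCF
annotations plus the derived catalog distance (dNM) and the cohort-level
strand-difference P value (shared by every tumor carrying the site).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import StrandDiffSample, strand_diff_test
from .types import Label, SiteCatalog, VariantCall

__all__ = ["build_feature_frame", "strand_test_by_site", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ["qd", "fs", "mq", "mq_rank_sum", "read_pos_rank_sum", "dnm", "mw_p"]


def strand_test_by_site(calls: Sequence[VariantCall]) -> dict[tuple, float]:
    """Two-sided strand-difference P per (chrom, pos, alt) site across tumors.

    A site observed in a single tumor is untestable — a one-sample
    Mann-Whitney across tumors is undefined — and gets no entry (the
    statistic stays missing and passes its cutoff). Calls without strand
    counts do not contribute.
    """
    by_site: dict[tuple, list[VariantCall]] = {}
    for call in calls:
        if call.strand_counts is not None:
            by_site.setdefault(call.site_key, []).append(call)
    pvals: dict[tuple, float] = {}
    for site, site_calls in by_site.items():
        if len(site_calls) < 2:
            continue
        alt_diffs = tuple(c.strand_counts.alt_fwd - c.strand_counts.alt_rev for c in site_calls)
        ref_diffs = tuple(c.strand_counts.ref_fwd - c.strand_counts.ref_rev for c in site_calls)
        pvals[site] = strand_diff_test(StrandDiffSample(alt_diffs, ref_diffs))
    return pvals


def build_feature_frame(
    calls: Sequence[VariantCall],
    catalog: SiteCatalog,
    truth: Mapping[tuple, Label] | None = None,
    stages: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per call: identity, annotations, dNM, cohort strand-test P.

    Missing statistics are NaN. When ``truth`` is given a ``label`` column is
    added (1 = true mutation, 0 = artifact); when ``stages`` maps tumor ids
    to stages a ``stage`` column is added.
    """
    pvals = strand_test_by_site(calls)
    rows = []
    for call in calls:
        ann = call.annotations
        row = {
            "tumor_id": call.tumor_id,
            "chrom": call.chrom,
            "pos": call.pos,
            "ref": call.ref_allele,
            "alt": call.alt_allele,
            "variant_class": call.variant_class.value,
            "qual": call.qual,
            "qd": np.nan if ann.qd is None else ann.qd,
            "fs": np.nan if ann.fs is None else ann.fs,
            "mq": np.nan if ann.mq is None else ann.mq,
            "mq_rank_sum": np.nan if ann.mq_rank_sum is None else ann.mq_rank_sum,
            "read_pos_rank_sum": np.nan
            if ann.read_pos_rank_sum is None
            else ann.read_pos_rank_sum,
            "dnm": _dnm(call, catalog),
            "mw_p": pvals.get(call.site_key, np.nan),
        }
        if truth is not None:
            row["label"] = int(truth[call.key] is Label.TRUE_MUTATION)
        if stages is not None:
            row["stage"] = stages[call.tumor_id]
        rows.append(row)
    return pd.DataFrame(rows)


def _dnm(call: VariantCall, catalog: SiteCatalog) -> float:
    from .stats import dnm

    return dnm(call.chrom, call.pos, call.ref_allele, call.alt_allele, catalog)
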