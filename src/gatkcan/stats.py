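"""Site and cohort statistics consumed by the filtering rule.

Implements the six statistics the decision rule compares against its trained
cutoffs: quality-by-depth (QD), Phred-scaled Fisher strand bias (FS),
Mann-Whitney rank-sum z approximations (MQRankSum / ReadPosRankSum style),
the cohort-level Mann-Whitney strand-difference test, the nearest
known-mutation distance dNM, and intermutation distances (IMD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .types import DNM_INF, SiteCatalog, StrandCounts

__all__ = [
    "DerivedStats",
    "StrandDiffSample",
    "quality_by_depth",
    "fisher_strand",
    "rank_sum_z",
    "strand_diff_test",
    "dnm",
    "intermutation_distances",
]

#: Phred cap used when the Fisher exact p underflows to numerically 0.
DEFAULT_PHRED_CAP = 500.0

#: Largest per-group size at which the strand test uses the exact U distribution.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class DerivedStats:
    """The two catalog/cohort statistics attached to a call before filtering."""

    dnm: float  # bp; 0 iff exact catalog match; inf when chromosome uncatalogued
    mw_p: float | None  # two-sided strand-difference P, None when untestable


@dataclass(frozen=True)
class StrandDiffSample:
    """Per-site forward-minus-reverse read-count differences across tumors."""

    alt_diffs: tuple[int, ...]
    ref_diffs: tuple[int, ...]


def quality_by_depth(qual: float, depth: int) -> float:
    """Variant quality divided by the unfiltered depth (QD)."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if qual < 0:
        raise ValueError(f"qual must be >= 0, got {qual}")
    return qual / depth


def fisher_strand(c: StrandCounts, phred_cap: float = DEFAULT_PHRED_CAP) -> float:
    """Phred-scaled two-sided Fisher exact P for strand bias (FS).

    The two-sided p sums every 2x2 table with fixed margins whose
    hypergeometric probability is at most that of the observed table
    (probability-mass rule). Returns ``-10*log10(p)``, capped at
    ``phred_cap`` when p underflows to 0, and clamped below at 0 so a
    p of exactly 1 maps to 0.0.
    """
    table = c.table
    if table.sum() == 0:
        raise ValueError("all-zero strand count table")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    p = min(float(p), 1.0)
    if p <= 0.0:
        return phred_cap
    return min(max(-10.0 * math.log10(p), 0.0), phred_cap) + 0.0


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_z(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U z approximation of y (ALT-linked) versus x (REF-linked).

    Mid-ranks for ties, tie-corrected variance, and a 0.5 continuity
    correction. Negative when the ALT-associated values are stochastically
    smaller than the REF-associated ones — the sign convention of the
    GATK-style rank-sum annotations, where a strongly negative value flags
    ALT reads with degraded quality or position.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([y, x])
    ranks = _midranks(combined)
    r_y = ranks[:n2].sum()
    u_y = r_y - n2 * (n2 + 1) / 2.0  # number of (y, x) pairs with y > x, ties 1/2
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:  # all observations identical
        return 0.0
    diff = u_y - mean_u
    # continuity correction shrinks |diff| by 0.5, never across zero
    diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    return diff / math.sqrt(var_u)


def strand_diff_test(s: StrandDiffSample) -> float:
    """Two-sided Mann-Whitney P that alt and ref strand differences share a distribution.

    For one called site, compares forward-minus-reverse ALT read counts
    against the corresponding REF differences across the tumors carrying the
    site; under no strand bias both difference samples straddle zero. Uses
    the exact U distribution when both groups have at most 8 tie-free
    observations, the tie-corrected normal approximation (with continuity
    correction) otherwise.
    """
    alt = np.asarray(s.alt_diffs, dtype=float)
    ref = np.asarray(s.ref_diffs, dtype=float)
    if alt.size == 0 or ref.size == 0:
        raise ValueError("both difference samples must be non-empty")
    if np.array_equal(alt, ref):
        return 1.0
    no_ties = np.unique(np.concatenate([alt, ref])).size == alt.size + ref.size
    method = "exact" if (no_ties and alt.size <= EXACT_MAX_N and ref.size <= EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(alt, ref, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def dnm(chrom: str, pos: int, ref: str, alt: str, catalog: SiteCatalog) -> float:
    """Distance in bp from a called variant to its nearest known mutation.

    0 iff the normalized (chrom, pos, ref, alt) is itself a catalog entry;
    otherwise the minimum |pos - p| over same-chromosome catalog positions;
    ``inf`` when the chromosome has no catalog entries. Same-chromosome
    only — there is no meaningful cross-chromosome base-pair distance.
    """
    if catalog.contains_exact(chrom, pos, ref, alt):
        return 0.0
    d = catalog.nearest_distance(chrom, pos)
    # colocated catalog entry with different alleles: 0 is reserved for exact matches
    if d == 0.0:
        return 1.0
    return d


def intermutation_distances(
    positions_by_chrom: Mapping[str, Sequence[int]],
) -> tuple[dict[str, np.ndarray], float]:
    """Successive within-chromosome distances (IMD) and their pooled median.

    Positions must be sorted within each chromosome; chromosomes with fewer
    than two mutations contribute an empty distance list. The pooled median
    is NaN when no chromosome has two or more mutations.
    """
    imds: dict[str, np.ndarray] = {}
    pooled: list[np.ndarray] = []
    for chrom, pos in positions_by_chrom.items():
        arr = np.asarray(pos, dtype=np.int64)
        if np.any(np.diff(arr) < 0):
            raise ValueError(f"positions on {chrom} are not sorted")
        d = np.diff(arr)
        imds[chrom] = d
        if d.size:
            pooled.append(d)
    median = float(np.median(np.concatenate(pooled))) if pooled else float("nan")
    return imds, median
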