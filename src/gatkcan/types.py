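"""Core value types shared across the toolkit.

Coordinates are 1-based and fully closed throughout, as in VCF and in the
tab-separated catalog files; all genomic distances are in base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "VariantClass",
    "Label",
    "StrandCounts",
    "AnnotationVector",
    "VariantCall",
    "SiteCatalog",
    "ThresholdSet",
    "Prediction",
    "ConfusionCounts",
    "MetricSet",
    "variant_key",
    "normalize_alleles",
]

#: Sentinel for "no catalog entry on this chromosome" nearest-distance queries.
DNM_INF = math.inf


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"


class Label(str, Enum):
    TRUE_MUTATION = "TRUE_MUTATION"
    ARTIFACT = "ARTIFACT"


@dataclass(frozen=True)
class StrandCounts:
    """Strand-resolved read counts for the REF and one ALT allele."""

    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        for name in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"strand count {name} must be >= 0, got {v}")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.ref_fwd, self.ref_rev], [self.alt_fwd, self.alt_rev]], dtype=np.int64
        )

    @property
    def depth(self) -> int:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev


@dataclass(frozen=True)
class AnnotationVector:
    """GATK-style site annotations; ``None`` means the annotation is absent.

    Missing annotations are never coerced to 0 — downstream filters treat an
    absent statistic as passing its cutoff (rank sums, for instance, are
    undefined at homozygous-ALT sites).
    """

    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None

    def __post_init__(self) -> None:
        if self.fs is not None and self.fs < 0:
            raise ValueError(f"FS is Phred-scaled and must be >= 0, got {self.fs}")
        if self.mq is not None and self.mq < 0:
            raise ValueError(f"MQ must be >= 0, got {self.mq}")


@dataclass(frozen=True)
class VariantCall:
    """One called variant (one ALT allele) in one tumor."""

    tumor_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float
    annotations: AnnotationVector = field(default_factory=AnnotationVector)
    strand_counts: StrandCounts | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return VariantClass.SNV
        return VariantClass.INDEL

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.tumor_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def site_key(self) -> tuple[str, int, str]:
        """Identity of the site across tumors: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt_allele)


def variant_key(
    tumor_id: str, chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, str, int, str, str]:
    return (tumor_id, chrom, pos, ref, alt)


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a ref/alt pair by trimming shared suffix then prefix.

    Keeps at least one base on each side; trimming a shared prefix advances
    the 1-based position accordingly. This is the usual parsimony
    normalization for indel representations that do not need the reference
    sequence context.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class SiteCatalog:
    """Per-chromosome sorted known-mutation sites with nearest-distance queries.

    Backs three inputs: the known-mutation catalog feeding dNM, known-SNP
    lists, and germline exclusion lists. Exact lookups are on normalized
    (chrom, pos, ref, alt); distance queries are position-only.
    """

    def __init__(
        self, entries: Iterable[tuple[str, int, str, str, str | None]] = ()
    ) -> None:
        self._keys: set[tuple[str, int, str, str]] = set()
        self._entries: dict[tuple[str, int, str, str], str | None] = {}
        self._positions: dict[str, np.ndarray] = {}
        pos_lists: dict[str, set[int]] = {}
        for chrom, pos, ref, alt, *gene in entries:
            g = gene[0] if gene else None
            npos, nref, nalt = normalize_alleles(int(pos), ref, alt)
            key = (chrom, npos, nref, nalt)
            self._keys.add(key)
            self._entries.setdefault(key, g)
            pos_lists.setdefault(chrom, set()).add(npos)
        for chrom, pos_set in pos_lists.items():
            self._positions[chrom] = np.array(sorted(pos_set), dtype=np.int64)

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self) -> Iterator[tuple[str, int, str, str, str | None]]:
        for (chrom, pos, ref, alt) in sorted(self._keys):
            yield chrom, pos, ref, alt, self._entries[(chrom, pos, ref, alt)]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._positions)

    def positions(self, chrom: str) -> np.ndarray:
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def contains_exact(self, chrom: str, pos: int, ref: str, alt: str) -> bool:
        return (chrom,) + normalize_alleles(pos, ref, alt) in self._keys

    def nearest_distance(self, chrom: str, pos: int) -> float:
        """Distance in bp to the nearest catalog position on ``chrom``.

        Returns ``inf`` when the chromosome carries no catalog entries.
        """
        arr = self._positions.get(chrom)
        if arr is None or arr.size == 0:
            return DNM_INF
        i = int(np.searchsorted(arr, pos))
        best = DNM_INF
        if i < arr.size:
            best = min(best, abs(int(arr[i]) - pos))
        if i > 0:
            best = min(best, abs(int(arr[i - 1]) - pos))
        return float(best)


# Statistic names used in ThresholdSet files, failure tallies and VCF FILTER tags.
STAT_DNM = "dNM"
STAT_FS = "FS"
STAT_MQ = "MQ"
STAT_MQRANKSUM = "MQRankSum"
STAT_QD = "QD"
STAT_MW = "MannWhitneyP"
STAT_READPOS = "ReadPosRankSum"

SNV_CUTOFF_NAMES = ("dnm_min", "fs_max", "mq_min", "mq_rank_sum_min", "qd_min", "mw_p_min")
INDEL_CUTOFF_NAMES = ("dnm_min", "fs_max", "qd_min", "mw_p_min")


@dataclass(frozen=True)
class ThresholdSet:
    """Trained cutoffs for one variant class plus the fitness weight α.

    SNV scope carries all six cutoffs; indel scope carries exactly four
    (dNM, FS, QD, Mann-Whitney P) — mapping-quality statistics are not part
    of the indel rule.
    """

    scope: VariantClass
    alpha: float
    dnm_min: float
    fs_max: float
    qd_min: float
    mw_p_min: float
    mq_min: float | None = None
    mq_rank_sum_min: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.scope is VariantClass.SNV:
            if self.mq_min is None or self.mq_rank_sum_min is None:
                raise ValueError("SNV threshold set requires mq_min and mq_rank_sum_min")
        else:
            if self.mq_min is not None or self.mq_rank_sum_min is not None:
                raise ValueError("indel threshold set must not carry MQ cutoffs")

    @property
    def cutoffs(self) -> dict[str, float]:
        names = (
            SNV_CUTOFF_NAMES if self.scope is VariantClass.SNV else INDEL_CUTOFF_NAMES
        )
        return {n: getattr(self, n) for n in names}


@dataclass(frozen=True)
class Prediction:
    label: Label
    failed_statistics: frozenset[str] = frozenset()
    shortcut_used: bool = False

    def __post_init__(self) -> None:
        if (
            self.label is Label.TRUE_MUTATION
            and self.failed_statistics
            and not self.shortcut_used
        ):
            raise ValueError("TRUE_MUTATION with failed statistics requires the dNM==0 shortcut")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    tpr: float
    cfpr: float
    precision: float
    mcc: float
    fpr_per_mb: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "tpr": self.tpr,
            "cfpr": self.cfpr,
            "precision": self.precision,
            "mcc": self.mcc,
            "fpr_per_mb": self.fpr_per_mb,
        }
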