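"""Synthetic tumor-only cohorts with the class structure the filter separates.

Generates mutation catalogs, labeled per-tumor variant streams (VCF + truth
TSV), and indel training pools, without any external data. The two classes
differ exactly where the method looks:

* true mutations sit at known-mutation catalog sites (dNM = 0, the default
  fraction is 0.9) or far from them, with clean annotations and balanced
  strand counts;
* artifacts sit near catalog sites (small dNM) or far, with low QD,
  depressed MQ, negative MQRankSum, and alt reads split asymmetrically
  across strands — the same mechanism drives both a high FS and a small
  cohort-level strand-difference P, since recurrent sites share the bias
  across tumors.

Emitted FS is recomputed from the emitted strand counts, so annotations are
internally consistent. A fixed seed reproduces the cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as gio
from .stats import fisher_strand
from .types import AnnotationVector, Label, SiteCatalog, StrandCounts, VariantCall

__all__ = [
    "CohortSpec",
    "DEFAULT_GENOME",
    "generate_catalog",
    "simulate_cohort",
    "generate_cohort",
    "simulate_indel_pools",
    "reference_site_sampler",
]

_BASES = np.array(list("ACGT"))

#: Toy exome-scale genome: three contigs, 120 Mb total.
DEFAULT_GENOME: dict[str, int] = {
    "chr1": 50_000_000,
    "chr2": 40_000_000,
    "chr3": 30_000_000,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of one synthetic cohort.

    Defaults mirror the study conditions the method was built for: ten
    tumors with a 2/3/2/3 stage mix, ~267 called variants per tumor of
    which ~10% are true mutations, and 90% of true mutations coinciding
    with a catalog entry. Class-conditional annotation distributions are
    (mean, sd) normals, truncated to keep the classes separable.
    """

    n_tumors: int = 10
    stage_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I": 2, "II": 3, "III": 2, "IV": 3}
    )
    genome: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_true_mutations: int = 27
    n_artifacts: int = 240
    frac_true_at_catalog: float = 0.9
    artifact_near_catalog_frac: float = 0.5
    near_catalog_band: tuple[int, int] = (10, 900)
    min_far_distance: int = 20_000
    # (mean, sd, lo, hi) per class. Artifacts deliberately straddle the GATK
    # hard-filter defaults — only part of the class fails QD < 2.0 or
    # ReadPosRankSum < -8.0 — so the default filter leaves a large residual
    # cFPR and the catalog-distance and strand statistics carry the signal.
    qd_true: tuple[float, float, float, float] = (15.0, 3.0, 5.0, 40.0)
    qd_artifact: tuple[float, float, float, float] = (2.5, 1.2, 0.3, 6.0)
    mq_true: tuple[float, float, float, float] = (60.0, 2.0, 52.0, 70.0)
    mq_artifact: tuple[float, float, float, float] = (45.0, 4.0, 35.0, 48.0)
    mqrs_true: tuple[float, float, float, float] = (0.0, 1.0, -4.0, 4.0)
    mqrs_artifact: tuple[float, float, float, float] = (-6.0, 3.0, -14.0, 2.0)
    rprs_true: tuple[float, float, float, float] = (0.0, 1.0, -4.0, 4.0)
    rprs_artifact: tuple[float, float, float, float] = (-4.0, 3.0, -12.0, 2.0)
    alt_fwd_prob_true: float = 0.5
    alt_fwd_prob_artifact: float = 0.9
    mean_depth: float = 60.0
    allelic_fraction: tuple[float, float] = (0.2, 0.6)
    annotation_missing_rate: float = 0.05
    site_pool_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if sum(self.stage_counts.values()) != self.n_tumors:
            raise ValueError("stage_counts must sum to n_tumors")
        if not 0.0 <= self.frac_true_at_catalog <= 1.0:
            raise ValueError("frac_true_at_catalog must be in [0, 1]")
        if self.n_true_mutations < 0 or self.n_artifacts < 0:
            raise ValueError("variant counts must be >= 0")


def generate_catalog(
    genome: Mapping[str, int], n_sites: int, seed: int = 0
) -> SiteCatalog:
    """Uniform, duplicate-free known-mutation catalog over the genome model.

    Sites are allocated to chromosomes proportionally to length and placed
    uniformly without replacement.
    """
    total = sum(genome.values())
    if n_sites > total:
        raise ValueError(f"cannot place {n_sites} sites on a {total} bp genome")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    chroms = sorted(genome)
    entries = []
    remaining = n_sites
    for i, chrom in enumerate(chroms):
        length = genome[chrom]
        if i == len(chroms) - 1:
            k = remaining
        else:
            k = int(round(n_sites * length / total))
            k = min(k, remaining)
        remaining -= k
        if k == 0:
            continue
        positions = rng.choice(length, size=k, replace=False) + 1
        for pos, g in zip(np.sort(positions), range(k)):
            ref, alt = _random_snv_alleles(rng)
            entries.append((chrom, int(pos), ref, alt, f"GENE_{chrom}_{g:05d}"))
    return SiteCatalog(entries)


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


def _truncated_normal(
    rng: np.random.Generator, params: tuple[float, float, float, float]
) -> float:
    mean, sd, lo, hi = params
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _far_position(
    rng: np.random.Generator,
    genome: Mapping[str, int],
    catalog: SiteCatalog,
    min_far: int,
) -> tuple[str, int]:
    chroms = sorted(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(10_000):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(1, genome[chrom] + 1))
        if catalog.nearest_distance(chrom, pos) >= min_far:
            return chrom, pos
    raise RuntimeError("could not place a far-from-catalog site; genome too dense")


def _build_site_pools(
    spec: CohortSpec, catalog: SiteCatalog, rng: np.random.Generator
) -> tuple[list[dict], list[dict]]:
    catalog_entries = list(catalog)
    used: set[tuple[str, int, str]] = set()

    def register(chrom: str, pos: int, ref: str, alt: str, **kw) -> dict | None:
        key = (chrom, pos, alt)
        if key in used:
            return None
        used.add(key)
        return {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, **kw}

    n_pool_true = max(int(np.ceil(spec.site_pool_factor * spec.n_true_mutations)), spec.n_true_mutations)
    n_pool_art = max(int(np.ceil(spec.site_pool_factor * spec.n_artifacts)), spec.n_artifacts)
    true_pool: list[dict] = []
    while len(true_pool) < n_pool_true:
        if catalog_entries and rng.random() < spec.frac_true_at_catalog:
            chrom, pos, ref, alt, _ = catalog_entries[int(rng.integers(len(catalog_entries)))]
            site = register(chrom, pos, ref, alt, at_catalog=True)
        else:
            chrom, pos = _far_position(rng, spec.genome, catalog, spec.min_far_distance)
            ref, alt = _random_snv_alleles(rng)
            site = register(chrom, pos, ref, alt, at_catalog=False)
        if site is not None:
            true_pool.append(site)
    artifact_pool: list[dict] = []
    lo_band, hi_band = spec.near_catalog_band
    while len(artifact_pool) < n_pool_art:
        if catalog_entries and rng.random() < spec.artifact_near_catalog_frac:
            chrom, cpos, _, _, _ = catalog_entries[int(rng.integers(len(catalog_entries)))]
            offset = int(rng.integers(lo_band, hi_band + 1)) * (1 if rng.random() < 0.5 else -1)
            pos = max(1, min(cpos + offset, spec.genome[chrom]))
            if catalog.nearest_distance(chrom, pos) == 0:
                continue
        else:
            chrom, pos = _far_position(rng, spec.genome, catalog, spec.min_far_distance)
        ref, alt = _random_snv_alleles(rng)
        if catalog.contains_exact(chrom, pos, ref, alt):
            continue
        site = register(chrom, pos, ref, alt, at_catalog=False)
        if site is not None:
            artifact_pool.append(site)
    return true_pool, artifact_pool


def _draw_strand_counts(
    spec: CohortSpec, rng: np.random.Generator, is_true: bool
) -> StrandCounts:
    depth = max(int(rng.poisson(spec.mean_depth)), 12)
    af = float(rng.uniform(*spec.allelic_fraction))
    alt_depth = int(np.clip(rng.binomial(depth, af), 2, depth - 2))
    ref_depth = depth - alt_depth
    p_fwd = spec.alt_fwd_prob_true if is_true else spec.alt_fwd_prob_artifact
    alt_fwd = int(rng.binomial(alt_depth, p_fwd))
    ref_fwd = int(rng.binomial(ref_depth, 0.5))
    return StrandCounts(
        ref_fwd=ref_fwd,
        ref_rev=ref_depth - ref_fwd,
        alt_fwd=alt_fwd,
        alt_rev=alt_depth - alt_fwd,
    )


def simulate_cohort(
    spec: CohortSpec, catalog: SiteCatalog
) -> tuple[list[VariantCall], dict[tuple, Label], dict[str, str]]:
    """Draw one labeled cohort in memory.

    Returns (calls, truth labels keyed by (tumor_id, chrom, pos, ref, alt),
    tumor stage map). Sites come from shared pools so they recur across
    tumors, which is what makes the cohort-level strand test informative.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    true_pool, artifact_pool = _build_site_pools(spec, catalog, rng)
    stages: dict[str, str] = {}
    stage_cycle = [s for s, k in spec.stage_counts.items() for _ in range(k)]
    calls: list[VariantCall] = []
    truth: dict[tuple, Label] = {}
    for t in range(spec.n_tumors):
        tumor_id = f"T{t + 1:03d}"
        stages[tumor_id] = stage_cycle[t]
        true_idx = rng.choice(len(true_pool), size=spec.n_true_mutations, replace=False)
        art_idx = rng.choice(len(artifact_pool), size=spec.n_artifacts, replace=False)
        for pool, idx, label in (
            (true_pool, true_idx, Label.TRUE_MUTATION),
            (artifact_pool, art_idx, Label.ARTIFACT),
        ):
            is_true = label is Label.TRUE_MUTATION
            for i in sorted(int(j) for j in idx):
                site = pool[i]
                sc = _draw_strand_counts(spec, rng, is_true)
                fs = fisher_strand(sc)
                qd = _truncated_normal(rng, spec.qd_true if is_true else spec.qd_artifact)
                mq = _truncated_normal(rng, spec.mq_true if is_true else spec.mq_artifact)
                mqrs = _truncated_normal(rng, spec.mqrs_true if is_true else spec.mqrs_artifact)
                rprs = _truncated_normal(rng, spec.rprs_true if is_true else spec.rprs_artifact)
                if rng.random() < spec.annotation_missing_rate:
                    mqrs = None
                if rng.random() < spec.annotation_missing_rate:
                    rprs = None
                call = VariantCall(
                    tumor_id=tumor_id,
                    chrom=site["chrom"],
                    pos=site["pos"],
                    ref_allele=site["ref"],
                    alt_allele=site["alt"],
                    qual=round(qd * sc.depth, 2),
                    annotations=AnnotationVector(
                        qd=round(qd, 3),
                        fs=round(fs, 3),
                        mq=round(mq, 2),
                        mq_rank_sum=None if mqrs is None else round(mqrs, 3),
                        read_pos_rank_sum=None if rprs is None else round(rprs, 3),
                    ),
                    strand_counts=sc,
                )
                calls.append(call)
                truth[call.key] = label
    return calls, truth, stages


def generate_cohort(
    spec: CohortSpec, catalog: SiteCatalog, out_dir: str | Path
) -> dict[str, object]:
    """Emit a cohort as per-tumor VCFs plus truth, tumor-stage and provenance files.

    Returns a manifest dict (also written as ``provenance.json``) listing the
    files, the spec and the seed; rerunning with the same spec reproduces
    every file byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls, truth, stages = simulate_cohort(spec, catalog)
    by_tumor: dict[str, list[VariantCall]] = {}
    for call in calls:
        by_tumor.setdefault(call.tumor_id, []).append(call)
    vcfs = {}
    for tumor_id in sorted(by_tumor):
        path = out_dir / f"{tumor_id}.vcf"
        gio.write_vcf(by_tumor[tumor_id], path)
        vcfs[tumor_id] = path.name
    gio.write_truth_labels(truth, out_dir / "truth.tsv")
    with open(out_dir / "tumors.tsv", "w") as fh:
        fh.write("tumor_id\tstage\tvcf\n")
        for tumor_id in sorted(by_tumor):
            fh.write(f"{tumor_id}\t{stages[tumor_id]}\t{vcfs[tumor_id]}\n")
    gio.write_site_catalog(catalog, out_dir / "catalog.tsv")
    spec_doc = asdict(spec)
    spec_doc["stage_counts"] = dict(spec.stage_counts)
    spec_doc["genome"] = dict(spec.genome)
    manifest = {
        "spec": spec_doc,
        "seed": spec.seed,
        "files": {
            "vcfs": vcfs,
            "truth": "truth.tsv",
            "tumors": "tumors.tsv",
            "catalog": "catalog.tsv",
        },
    }
    (out_dir / "provenance.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def simulate_indel_pools(
    catalog: SiteCatalog,
    n_reported: int = 539,
    n_artifacts: int = 112,
    spec: CohortSpec | None = None,
    seed: int = 0,
) -> tuple[list[VariantCall], list[VariantCall], SiteCatalog]:
    """Reported-indel and artifact-indel pools plus the matching catalog.

    Mirrors the indel study conditions (539 reported indels, 112 artifacts
    by default). "Reported" indels are known mutations, so a fraction of
    them (``spec.frac_true_at_catalog``) are placed *into* the returned
    catalog — the input catalog augmented with those exact indel entries —
    giving them dNM = 0; the rest sit far from every known site. Artifact
    indels sit near known sites or far, with artifact-class QD and strand
    bias. Alleles are 1 bp insertions/deletions; each pool is emitted under
    one pseudo-tumor id since the indel split carries no tumor grouping.
    """
    spec = spec if spec is not None else CohortSpec(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    snv_entries = list(catalog)
    reported: list[VariantCall] = []
    artifacts: list[VariantCall] = []
    extra_entries: list[tuple[str, int, str, str, str | None]] = []
    seen: set[tuple[str, int]] = set()

    def make_indel(chrom: str, pos: int, ref: str) -> tuple[str, str]:
        ins = str(_BASES[int(rng.integers(4))])
        if rng.random() < 0.5:
            return ref, ref + ins
        return ref + ins, ref

    while len(reported) < n_reported:
        in_catalog = rng.random() < spec.frac_true_at_catalog
        chrom, pos = _far_position(rng, spec.genome, catalog, spec.min_far_distance)
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = str(_BASES[int(rng.integers(4))])
        ref_allele, alt_allele = make_indel(chrom, pos, ref)
        if in_catalog:
            extra_entries.append((chrom, pos, ref_allele, alt_allele, None))
        sc = _draw_strand_counts(spec, rng, True)
        qd = _truncated_normal(rng, spec.qd_true)
        reported.append(
            VariantCall(
                tumor_id="INDEL_REPORTED",
                chrom=chrom,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                qual=round(qd * sc.depth, 2),
                annotations=AnnotationVector(qd=round(qd, 3), fs=round(fisher_strand(sc), 3)),
                strand_counts=sc,
            )
        )
    while len(artifacts) < n_artifacts:
        if snv_entries and rng.random() < spec.artifact_near_catalog_frac:
            chrom, cpos, _, _, _ = snv_entries[int(rng.integers(len(snv_entries)))]
            lo, hi = spec.near_catalog_band
            pos = max(1, min(cpos + int(rng.integers(lo, hi + 1)), spec.genome[chrom]))
        else:
            chrom, pos = _far_position(rng, spec.genome, catalog, spec.min_far_distance)
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = str(_BASES[int(rng.integers(4))])
        ref_allele, alt_allele = make_indel(chrom, pos, ref)
        sc = _draw_strand_counts(spec, rng, False)
        qd = _truncated_normal(rng, spec.qd_artifact)
        artifacts.append(
            VariantCall(
                tumor_id="INDEL_ARTIFACT",
                chrom=chrom,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                qual=round(qd * sc.depth, 2),
                annotations=AnnotationVector(qd=round(qd, 3), fs=round(fisher_strand(sc), 3)),
                strand_counts=sc,
            )
        )
    indel_catalog = SiteCatalog(snv_entries + extra_entries)
    return reported, artifacts, indel_catalog


def reference_site_sampler(
    genome: Mapping[str, int], fraction: float, seed: int = 0
) -> int:
    """Deterministic count of sampled reference sites for FPR-per-Mb denominators.

    A fixed-size draw: exactly ``round(fraction * total_sites)``, so the
    denominator is reproducible for a given genome model and fraction.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    total = sum(genome.values())
    return int(round(fraction * total))
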