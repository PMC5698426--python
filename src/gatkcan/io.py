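"""File formats: annotated VCF, tabular site catalogs and truth labels, threshold JSON.

VCF 4.2 via pysam; catalogs, site lists and truth labels are headered TSV;
threshold sets and run provenance are JSON. All other modules stay in-memory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from .types import (
    INDEL_CUTOFF_NAMES,
    SNV_CUTOFF_NAMES,
    AnnotationVector,
    Label,
    Prediction,
    SiteCatalog,
    StrandCounts,
    ThresholdSet,
    VariantCall,
    VariantClass,
)

__all__ = [
    "VCFParseError",
    "ConfigurationError",
    "read_vcf",
    "write_vcf",
    "write_classified_vcf",
    "read_site_catalog",
    "write_site_catalog",
    "read_truth_labels",
    "write_truth_labels",
    "read_threshold_set",
    "write_threshold_set",
    "ARTIFACT_FILTER",
]

#: FILTER id written for calls predicted to be artifacts.
ARTIFACT_FILTER = "gatkcan_artifact"

#: Default per-sample FORMAT key carrying ref_fwd,ref_rev,alt_fwd,alt_rev counts
#: (GATK StrandAlleleCountsBySample layout, one fwd/rev pair per allele).
DEFAULT_STRAND_KEY = "SAC"

_INFO_KEYS = {
    "QD": "qd",
    "FS": "fs",
    "MQ": "mq",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
}


class VCFParseError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def _info_float(rec: "pysam.VariantRecord", key: str) -> float | None:
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, tuple):
        val = val[0]
    return None if val is None else float(val)


def read_vcf(
    path: str | Path,
    tumor_id: str,
    strand_key: str = DEFAULT_STRAND_KEY,
    require_strand_counts: bool = False,
) -> list[VariantCall]:
    """Read one tumor's called variants, one ``VariantCall`` per ALT allele.

    Multi-allelic records are split; site-level annotations are shared by the
    split calls and strand counts are sliced per allele from ``strand_key``
    (ref pair first, then one fwd/rev pair per ALT). Absent annotations stay
    missing — they are never coerced to 0.
    """
    path = Path(path)
    calls: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vcf:
        has_strand = strand_key in vcf.header.formats or strand_key in vcf.header.info
        if require_strand_counts and not has_strand:
            raise ConfigurationError(
                f"{path}: strand-count key {strand_key!r} not declared in header"
            )
        try:
            for rec in vcf:
                annotations = AnnotationVector(
                    **{attr: _info_float(rec, key) for key, attr in _INFO_KEYS.items()}
                )
                sac = _strand_values(rec, strand_key)
                alts = rec.alts or ()
                for i, alt in enumerate(alts):
                    sc = None
                    if sac is not None and len(sac) >= 4 + 2 * i:
                        sc = StrandCounts(
                            ref_fwd=int(sac[0]),
                            ref_rev=int(sac[1]),
                            alt_fwd=int(sac[2 + 2 * i]),
                            alt_rev=int(sac[3 + 2 * i]),
                        )
                    elif require_strand_counts:
                        raise ConfigurationError(
                            f"{path}: record {rec.chrom}:{rec.pos} lacks {strand_key!r} values"
                        )
                    calls.append(
                        VariantCall(
                            tumor_id=tumor_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=str(alt),
                            qual=float(rec.qual) if rec.qual is not None else 0.0,
                            annotations=annotations,
                            strand_counts=sc,
                        )
                    )
        except (ValueError, OSError) as exc:
            if isinstance(exc, ConfigurationError):
                raise
            raise VCFParseError(f"{path}: malformed VCF record: {exc}") from exc
    return calls


def _strand_values(rec: "pysam.VariantRecord", strand_key: str) -> tuple[int, ...] | None:
    if rec.samples:
        sample = rec.samples[0]
        if strand_key in sample and sample[strand_key] is not None:
            vals = sample[strand_key]
            if not isinstance(vals, tuple):
                vals = (vals,)
            if all(v is not None for v in vals):
                return tuple(int(v) for v in vals)
    if strand_key in rec.info:
        vals = rec.info[strand_key]
        if not isinstance(vals, tuple):
            vals = (vals,)
        return tuple(int(v) for v in vals)
    return None


def _build_header(sample_id: str, contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("QD", 1, "Float", "Variant quality divided by unfiltered depth")
    header.info.add("FS", 1, "Float", "Phred-scaled Fisher exact strand-bias P")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add("MQRankSum", 1, "Float", "Mann-Whitney z of ALT vs REF mapping quality")
    header.info.add(
        "ReadPosRankSum", 1, "Float", "Mann-Whitney z of ALT vs REF within-read position"
    )
    header.info.add("FAILED", ".", "String", "Statistics whose cutoff the call violated")
    header.info.add("DNM0", 0, "Flag", "Call matched the known-mutation catalog exactly")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add(
        "SAC", ".", "Integer", "Strand allele counts: ref fwd,rev then alt fwd,rev per allele"
    )
    header.filters.add(ARTIFACT_FILTER, None, None, "Predicted artifact")
    header.add_sample(sample_id)
    return header


def _emit(
    calls: Sequence[VariantCall],
    path: str | Path,
    predictions: Mapping[tuple, Prediction] | None,
) -> None:
    if not calls:
        tumor_ids = {"sample"}
    else:
        tumor_ids = {c.tumor_id for c in calls}
    if len(tumor_ids) != 1:
        raise ValueError(f"one VCF holds one tumor; got tumor ids {sorted(tumor_ids)}")
    sample_id = next(iter(tumor_ids))
    contigs = sorted({c.chrom for c in calls})
    header = _build_header(sample_id, contigs)
    ordered = sorted(calls, key=lambda c: (contigs.index(c.chrom), c.pos, c.alt_allele))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in ordered:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref_allele, call.alt_allele),
            )
            rec.qual = call.qual
            ann = call.annotations
            for key, attr in _INFO_KEYS.items():
                val = getattr(ann, attr)
                if val is not None:
                    rec.info[key] = val
            sc = call.strand_counts
            rec.samples[sample_id]["GT"] = (0, 1)
            if sc is not None:
                rec.samples[sample_id]["SAC"] = (sc.ref_fwd, sc.ref_rev, sc.alt_fwd, sc.alt_rev)
            if predictions is not None:
                pred = predictions.get(call.key)
                if pred is None:
                    raise ValueError(f"no prediction for call {call.key}")
                if pred.label is Label.TRUE_MUTATION:
                    rec.filter.add("PASS")
                    if pred.shortcut_used:
                        rec.info["DNM0"] = True
                else:
                    rec.filter.add(ARTIFACT_FILTER)
                if pred.failed_statistics:
                    rec.info["FAILED"] = tuple(sorted(pred.failed_statistics))
            out.write(rec)


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write one tumor's calls as uncompressed VCF 4.2 (no FILTER decisions)."""
    _emit(calls, path, None)


def write_classified_vcf(
    calls: Sequence[VariantCall],
    predictions: Mapping[tuple, Prediction],
    path: str | Path,
) -> None:
    """Write calls with FILTER ``PASS`` / artifact tag and the failed statistics in INFO."""
    _emit(calls, path, predictions)


_CATALOG_COLUMNS = ("chrom", "pos", "ref", "alt")


def _read_sites_table(path: str | Path, extra_required: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: missing header line") from exc
    required = [*_CATALOG_COLUMNS, *extra_required]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing header column(s) {missing}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos != pos.round())
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based file row, after the header
        raise ValueError(f"{path}: non-integer pos at row {row}: {df['pos'][bad.idxmax()]!r}")
    df["pos"] = pos.astype(int)
    return df


def read_site_catalog(path: str | Path) -> SiteCatalog:
    """Read a headered TSV (chrom, pos, ref, alt[, gene]) into a sorted catalog.

    Duplicate rows collapse to one entry; positions sort per chromosome.
    """
    df = _read_sites_table(path)
    gene = df["gene"] if "gene" in df.columns else pd.Series([None] * len(df))
    entries = [
        (str(c), int(p), str(r), str(a), None if g is None or pd.isna(g) else str(g))
        for c, p, r, a, g in zip(df["chrom"], df["pos"], df["ref"], df["alt"], gene)
    ]
    return SiteCatalog(entries)


def write_site_catalog(catalog: SiteCatalog, path: str | Path) -> None:
    rows = [
        {"chrom": c, "pos": p, "ref": r, "alt": a, "gene": g if g is not None else ""}
        for c, p, r, a, g in catalog
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth_labels(path: str | Path) -> dict[tuple, Label]:
    """Read truth labels keyed by (tumor_id, chrom, pos, ref, alt)."""
    df = _read_sites_table(path, extra_required=("tumor_id", "label"))
    labels: dict[tuple, Label] = {}
    for t, c, p, r, a, lab in zip(
        df["tumor_id"], df["chrom"], df["pos"], df["ref"], df["alt"], df["label"]
    ):
        key = (str(t), str(c), int(p), str(r), str(a))
        if key in labels:
            raise ValueError(f"duplicate truth label for {key}")
        labels[key] = Label(lab)
    return labels


def write_truth_labels(labels: Mapping[tuple, Label], path: str | Path) -> None:
    rows = [
        {"tumor_id": k[0], "chrom": k[1], "pos": k[2], "ref": k[3], "alt": k[4], "label": v.value}
        for k, v in sorted(labels.items(), key=lambda kv: kv[0])
    ]
    pd.DataFrame(rows, columns=["tumor_id", "chrom", "pos", "ref", "alt", "label"]).to_csv(
        path, sep="\t", index=False
    )


# Comparison direction of every cutoff: a call fails when its statistic falls
# on the artifact side of the cutoff, strictly.
_DIRECTIONS = {
    "dnm_min": "artifact_if_below",  # only for 0 < dNM < cutoff; dNM == 0 shortcuts
    "fs_max": "artifact_if_above",
    "mq_min": "artifact_if_below",
    "mq_rank_sum_min": "artifact_if_below",
    "qd_min": "artifact_if_below",
    "mw_p_min": "artifact_if_below",
}


def write_threshold_set(ts: ThresholdSet, path: str | Path) -> None:
    doc = {
        "scope": ts.scope.value,
        "alpha": ts.alpha,
        "cutoffs": {
            name: {"value": value, "direction": _DIRECTIONS[name]}
            for name, value in ts.cutoffs.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_threshold_set(path: str | Path) -> ThresholdSet:
    doc = json.loads(Path(path).read_text())
    scope = VariantClass(doc["scope"])
    expected = SNV_CUTOFF_NAMES if scope is VariantClass.SNV else INDEL_CUTOFF_NAMES
    cutoffs = doc.get("cutoffs", {})
    missing = [n for n in expected if n not in cutoffs]
    if missing:
        raise ValueError(f"{path}: {scope.value} threshold set lacks cutoff(s) {missing}")
    extra = [n for n in cutoffs if n not in expected]
    if extra:
        raise ValueError(f"{path}: unexpected cutoff(s) {extra} for scope {scope.value}")
    values = {n: float(cutoffs[n]["value"]) for n in expected}
    return ThresholdSet(scope=scope, alpha=float(doc["alpha"]), **values)
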