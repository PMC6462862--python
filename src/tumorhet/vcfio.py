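"""Read/write the formats the pipeline touches.

Variants travel as VCF 4.2 with a flat, single-caller INFO schema
(GENE, IMPACT, CADD, QSS, POPAF, CLINVAR, PFAM, PROVEAN, SIFT, POLYPHEN)
and per-sample AD/DP carrying per-region read support.  Multi-allelic
records are rejected with instruction to pre-split, which keeps VAF
semantics unambiguous.  Coordinates are 1-based in and out.

Also here: FASTA (+ .fai sidecar) via pysam, gene lists (one symbol per
line, ``#`` comments), signature catalogs and CNV segment tables as TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .exceptions import SchemaError
from .signatures import CHANNELS, SignatureCatalog
from .types import AnnotatedVariant, CNVSegment

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("IMPACT", "1", "String", "Predicted impact (HIGH/MODERATE/LOW/MODIFIER)"),
    ("CADD", "1", "Float", "CADD scaled score"),
    ("QSS", "1", "Float", "Caller quality (QSS for SNVs, QSI for indels)"),
    ("POPAF", "1", "Float", "Population allele frequency"),
    ("CLINVAR", "1", "String", "ClinVar status"),
    ("PFAM", "0", "Flag", "Variant falls in a Pfam domain"),
    ("PROVEAN", "1", "String", "PROVEAN call (damaging/benign)"),
    ("SIFT", "1", "String", "SIFT call (damaging/benign)"),
    ("POLYPHEN", "1", "String", "PolyPhen call (damaging/benign)"),
]

_PREDICTOR_KEYS = {"PROVEAN": "PROVEAN", "SIFT": "SIFT", "PolyPhen": "POLYPHEN"}


def _build_header(samples: Sequence[str], contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.add_line(f"##contig=<ID={contig}>")
    for name, number, vtype, desc in _INFO_FIELDS:
        header.add_meta(
            "INFO",
            items=[("ID", name), ("Number", number), ("Type", vtype), ("Description", desc)],
        )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Read depth per allele (ref, alt)")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Total read depth")],
    )
    for sample in samples:
        header.add_sample(sample)
    return header


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    path: str | Path,
    region_ids: Optional[Sequence[str]] = None,
) -> None:
    """Write variants as sorted VCF 4.2 with the flat annotation schema.

    ``region_ids`` fixes the sample-column order; by default the union of
    regions seen in the variants (sorted) is used.
    """
    path = Path(path)
    if region_ids is None:
        seen: set[str] = set()
        for v in variants:
            seen.update(v.per_region_support)
        region_ids = sorted(seen)
    contigs = sorted({v.chrom for v in variants})
    header = _build_header(region_ids, contigs)
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.filter.add("PASS")
            if v.gene:
                rec.info["GENE"] = v.gene
            rec.info["IMPACT"] = v.impact
            if v.cadd is not None:
                rec.info["CADD"] = v.cadd
            if v.qss is not None:
                rec.info["QSS"] = v.qss
            if v.pop_af is not None:
                rec.info["POPAF"] = v.pop_af
            if v.clinvar != "none":
                rec.info["CLINVAR"] = v.clinvar
            if v.pfam_domain:
                rec.info["PFAM"] = True
            for pred, key in _PREDICTOR_KEYS.items():
                call = v.predictor_calls.get(pred)
                if call is not None and call != "missing":
                    rec.info[key] = call
            for region in region_ids:
                if region in v.per_region_support:
                    alt_reads, total = v.per_region_support[region]
                    rec.samples[region]["AD"] = (total - alt_reads, alt_reads)
                    rec.samples[region]["DP"] = total
            out.write(rec)


def read_vcf(
    path: str | Path, region_ids: Optional[Sequence[str]] = None
) -> list[AnnotatedVariant]:
    """Read a flat-schema VCF into AnnotatedVariants.

    Unknown INFO keys are ignored; missing annotation keys become None.
    Multi-allelic records and AD/DP inconsistencies raise SchemaError
    naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    variants: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        if region_ids is None:
            region_ids = list(vcf.header.samples)
        for i, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise SchemaError(
                    f"{path} record {i} ({rec.chrom}:{rec.pos}): multi-allelic records "
                    "are not supported; split them first"
                )
            info = rec.info
            predictor_calls = {}
            for pred, key in _PREDICTOR_KEYS.items():
                if key in info:
                    predictor_calls[pred] = str(info[key])
            support = {}
            for region in region_ids:
                if region not in rec.samples:
                    raise SchemaError(f"{path} has no sample column {region!r}")
                sample = rec.samples[region]
                ad = sample.get("AD")
                dp = sample.get("DP")
                if ad is None or dp is None or ad[0] is None:
                    continue
                alt_reads = int(ad[1])
                total = int(dp)
                if alt_reads > total:
                    raise SchemaError(
                        f"{path} record {i} ({rec.chrom}:{rec.pos}): AD alt count "
                        f"{alt_reads} exceeds DP {total} for sample {region!r}"
                    )
                support[region] = (alt_reads, total)
            try:
                variants.append(
                    AnnotatedVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        gene=str(info.get("GENE", "")),
                        impact=str(info.get("IMPACT", "MODIFIER")),
                        cadd=float(info["CADD"]) if "CADD" in info else None,
                        qss=float(info["QSS"]) if "QSS" in info else None,
                        pop_af=float(info["POPAF"]) if "POPAF" in info else None,
                        clinvar=str(info.get("CLINVAR", "none")),
                        pfam_domain=bool(info.get("PFAM", False)),
                        predictor_calls=predictor_calls,
                        per_region_support=support,
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path} record {i}: {exc}") from exc
    return variants


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA and build the .fai index sidecar."""
    path = Path(path)
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
    pysam.faidx(str(path))


def read_fasta(path: str | Path) -> dict[str, str]:
    with pysam.FastaFile(str(path)) as fasta:
        return {name: fasta.fetch(name) for name in fasta.references}


# ---------------------------------------------------------------------------
# Gene lists, catalogs, segment tables
# ---------------------------------------------------------------------------

def load_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' starts a comment."""
    genes: set[str] = set()
    for line in Path(path).read_text().splitlines():
        symbol = line.split("#", 1)[0].strip()
        if symbol:
            genes.add(symbol)
    return genes


def load_catalog(path: str | Path) -> SignatureCatalog:
    """Load a TSV signature catalog (rows = signatures, 96 context columns).

    Columns must be the canonical 96 channels in canonical order.  Rows are
    renormalized when within 1e-6 of summing to 1; anything further off is a
    SchemaError.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(CHANNELS):
        raise SchemaError(
            f"{path}: catalog columns must be the 96 canonical channels in canonical order"
        )
    names = [str(n) for n in df.index]
    if len(set(names)) != len(names):
        raise SchemaError(f"{path}: duplicate signature names")
    matrix = df.to_numpy(dtype=float)
    sums = matrix.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = [names[i] for i in np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]]
        raise SchemaError(f"{path}: rows do not sum to 1: {bad}")
    return SignatureCatalog(names, matrix)


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(catalog.matrix, index=catalog.names, columns=list(CHANNELS))
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_segments(path: str | Path, bed0: bool = False) -> list[CNVSegment]:
    """Read a CNV segment TSV (chrom, start, end, copy_number[, minor_cn]).

    Coordinates are 1-based inclusive by default; ``bed0=True`` accepts
    standard BED 0-based half-open coordinates and converts them.
    """
    segments = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"chrom", "start", "end", "copy_number"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(f"{path}: segment table must have columns {sorted(required)}")
        for row in reader:
            start = int(row["start"])
            end = int(row["end"])
            if bed0:
                start += 1  # half-open end becomes inclusive end unchanged
            minor = row.get("minor_cn", "")
            try:
                segments.append(
                    CNVSegment(
                        chrom=row["chrom"],
                        start=start,
                        end=end,
                        copy_number=int(row["copy_number"]),
                        minor_cn=int(minor) if minor not in ("", None, ".") else None,
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: {exc}") from exc
    return segments


def write_segments(segments: Sequence[CNVSegment], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("chrom\tstart\tend\tcopy_number\tminor_cn\n")
        for seg in segments:
            minor = "." if seg.minor_cn is None else str(seg.minor_cn)
            out.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.copy_number}\t{minor}\n")


def _data_path(filename: str) -> Path:
    from importlib.resources import files

    return Path(str(files("tumorhet").joinpath("data", filename)))


def default_catalog() -> SignatureCatalog:
    """The bundled synthetic signature catalog (see make_synthetic_catalog)."""
    return load_catalog(_data_path("signatures_synthetic.tsv"))


def default_gene_list(name: str) -> set[str]:
    """Bundled gene list: ``"drivers"`` or ``"repair"``."""
    filename = {"drivers": "driver_genes.tsv", "repair": "repair_genes.tsv"}[name]
    return load_gene_list(_data_path(filename))
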