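"""I/O round trips: VCF flat schema, FASTA, catalogs, gene lists, segments."""

import numpy as np
import pytest

from tumorhet.exceptions import SchemaError
from tumorhet.signatures import CHANNELS, SignatureCatalog
from tumorhet.types import AnnotatedVariant, CNVSegment
from tumorhet.vcfio import (
    default_catalog,
    default_gene_list,
    load_catalog,
    load_gene_list,
    read_fasta,
    read_segments,
    read_vcf,
    write_catalog,
    write_fasta,
    write_segments,
    write_vcf,
)


def _sample_variants():
    return [
        AnnotatedVariant(
            "chr1", 500, "C", "T", gene="TP53", impact="HIGH", cadd=23.5,
            qss=40.0, pop_af=0.0004, clinvar="pathogenic", pfam_domain=True,
            predictor_calls={"SIFT": "damaging", "PROVEAN": "benign"},
            per_region_support={"R1": (40, 120), "R2": (0, 95)},
        ),
        AnnotatedVariant(
            "chr1", 120, "A", "AT", impact="MODERATE", qss=17.0,
            per_region_support={"R1": (12, 100), "R2": (30, 110)},
        ),
        AnnotatedVariant(
            "chr1", 900, "G", "A",
            per_region_support={"R1": (5, 80), "R2": (60, 130)},
        ),
    ]


def test_vcf_round_trip_field_equality(tmp_path):
    variants = _sample_variants()
    path = tmp_path / "out.vcf"
    write_vcf(variants, path, ["R1", "R2"])
    back = read_vcf(path, ["R1", "R2"])
    by_key = {v.key: v for v in back}
    assert len(back) == len(variants)
    for v in variants:
        r = by_key[v.key]
        for attr in ("chrom", "pos", "ref", "alt", "gene", "impact", "clinvar",
                     "pfam_domain", "per_region_support"):
            assert getattr(r, attr) == getattr(v, attr), attr
        for attr in ("cadd", "qss", "pop_af"):
            got, want = getattr(r, attr), getattr(v, attr)
            assert (got is None) == (want is None)
            if want is not None:
                assert got == pytest.approx(want, rel=1e-6)
        assert r.predictor_calls == {
            k: c for k, c in v.predictor_calls.items() if c != "missing"
        }


def test_vcf_output_is_sorted_and_missing_fields_stay_missing(tmp_path):
    path = tmp_path / "sorted.vcf"
    write_vcf(_sample_variants(), path)
    back = read_vcf(path)
    positions = [v.pos for v in back]
    assert positions == sorted(positions)
    bare = next(v for v in back if v.pos == 900)
    assert bare.cadd is None and bare.qss is None and bare.pop_af is None
    assert bare.gene == "" and bare.clinvar == "none" and not bare.pfam_domain


def test_vcf_empty_list_writes_readable_header_only_file(tmp_path):
    path = tmp_path / "empty.vcf"
    write_vcf([], path, ["R1"])
    assert read_vcf(path) == []
    assert path.read_text().startswith("##fileformat=VCF")


def test_vcf_rejects_multiallelic_and_ad_over_dp(tmp_path):
    multi = tmp_path / "multi.vcf"
    multi.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t10\t.\tC\tA,T\t.\tPASS\t.\n"
    )
    with pytest.raises(SchemaError, match="multi-allelic"):
        read_vcf(multi)

    bad = tmp_path / "bad_ad.vcf"
    bad.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1>\n"
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tR1\n"
        "chr1\t10\t.\tC\tA\t.\tPASS\t.\tAD:DP\t10,50:40\n"
    )
    with pytest.raises(SchemaError, match="exceeds DP"):
        read_vcf(bad)


def test_fasta_round_trip_with_index(tmp_path):
    path = tmp_path / "ref.fa"
    sequences = {"chr1": "ACGTACGTAC" * 13, "chr2": "GGGCCCAATT"}
    write_fasta(sequences, path)
    assert (tmp_path / "ref.fa.fai").exists()
    assert read_fasta(path) == sequences


def test_gene_list_parsing_with_comments(tmp_path):
    path = tmp_path / "genes.tsv"
    path.write_text("# header\nTP53\nKRAS  # inline comment\n\nEGFR\n")
    assert load_gene_list(path) == {"TP53", "KRAS", "EGFR"}


def test_bundled_resources_load():
    catalog = default_catalog()
    assert catalog.matrix.shape == (6, 96)
    assert np.allclose(catalog.matrix.sum(axis=1), 1.0)
    assert "TP53" in default_gene_list("drivers")
    assert "NEIL1" in default_gene_list("repair")


def test_catalog_bad_row_sum_and_duplicate_names_rejected(tmp_path):
    bad_sum = tmp_path / "bad.tsv"
    header = "signature\t" + "\t".join(CHANNELS) + "\n"
    bad_sum.write_text(header + "s1\t" + "\t".join(["0.005208"] * 96) + "\n")
    with pytest.raises(SchemaError, match="sum"):
        load_catalog(bad_sum)

    dup = tmp_path / "dup.tsv"
    row = "\t".join([f"{1/96:.10f}"] * 96)
    dup.write_text(header + f"s1\t{row}\ns1\t{row}\n")
    with pytest.raises(SchemaError, match="duplicate"):
        load_catalog(dup)


def test_catalog_round_trip(tmp_path, catalog):
    path = tmp_path / "cat.tsv"
    write_catalog(catalog, path)
    back = load_catalog(path)
    assert back.names == catalog.names
    assert np.abs(back.matrix - catalog.matrix).max() < 1e-7


def test_segment_table_round_trip_and_bed0(tmp_path):
    segments = [
        CNVSegment("chr1", 1, 30000, 2, 1),
        CNVSegment("chr1", 30001, 60000, 0, 0),
        CNVSegment("chr1", 60001, 90000, 7, None),
    ]
    path = tmp_path / "segs.tsv"
    write_segments(segments, path)
    assert read_segments(path) == segments

    bed = tmp_path / "segs.bed.tsv"
    bed.write_text("chrom\tstart\tend\tcopy_number\nchr1\t0\t30000\t2\n")
    (seg,) = read_segments(bed, bed0=True)
    assert (seg.start, seg.end) == (1, 30000)
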