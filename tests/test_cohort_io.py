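"""Cohort input readers: caller merging, CNV categories, matrix validation."""

from __future__ import annotations

import pandas as pd
import pytest

from conftest import make_snv
from dgipredict.cohort_io import (
    CNVCategory,
    CohortIOError,
    Subtype,
    SubtypeLabel,
    categorize_copy_number,
    read_cnv_calls,
    read_expression,
    read_snv_calls,
    read_subtypes,
    subtype_map,
    write_snv_calls,
)

SNV_HEADER = "sample_id\tchrom\tpos\tref\talt\tgene\tvariant_class\timpact_rank\tdamaging\tprotein_change"


def _snv_file(tmp_path, name, rows):
    p = tmp_path / name
    p.write_text("\n".join([SNV_HEADER, *rows]) + "\n")
    return str(p)


ROW = "S1\tchr3\t100\tA\tT\tPIK3CA\tmissense\t25\ttrue\tE545K"


def test_same_locus_across_callers_merges_caller_sets(tmp_path):
    f1 = _snv_file(tmp_path, "c1.tsv", [ROW])
    f3 = _snv_file(tmp_path, "c3.tsv", [ROW])
    calls = read_snv_calls({"caller1": [f1], "caller3": [f3]})
    assert len(calls) == 1
    assert calls[0].callers == frozenset({"caller1", "caller3"})


def test_single_caller_locus_keeps_single_caller(tmp_path):
    f2 = _snv_file(tmp_path, "c2.tsv", [ROW])
    (call,) = read_snv_calls({"caller2": [f2]})
    assert call.callers == frozenset({"caller2"})


def test_different_alt_allele_stays_distinct(tmp_path):
    other = ROW.replace("A\tT", "A\tG")
    f1 = _snv_file(tmp_path, "c1.tsv", [ROW, other])
    calls = read_snv_calls({"caller1": [f1]})
    assert len(calls) == 2
    assert {c.alt for c in calls} == {"T", "G"}


def test_merge_is_order_independent(tmp_path):
    f1 = _snv_file(tmp_path, "c1.tsv", [ROW])
    f2 = _snv_file(tmp_path, "c2.tsv", [ROW, ROW.replace("100", "200")])
    a = read_snv_calls({"caller1": [f1], "caller2": [f2]})
    b = read_snv_calls({"caller2": [f2], "caller1": [f1]})
    assert a == b


def test_unknown_caller_label_is_fatal(tmp_path):
    f = _snv_file(tmp_path, "c.tsv", [ROW])
    with pytest.raises(CohortIOError, match="unknown caller"):
        read_snv_calls({"mutect": [f]})


def test_missing_annotation_column_is_fatal(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("sample_id\tchrom\tpos\tref\talt\tgene\nS1\tchr1\t5\tA\tT\tX\n")
    with pytest.raises(CohortIOError, match="missing annotation"):
        read_snv_calls({"caller1": [str(p)]})


def test_tsv_roundtrip_is_lossless(tmp_path):
    calls = [
        make_snv(pos=100, callers=("caller1",)),
        make_snv(pos=200, damaging=False, impact_rank=5, callers=("caller1",)),
    ]
    path = tmp_path / "out.tsv"
    write_snv_calls(calls, path, "caller1")
    back = read_snv_calls({"caller1": [str(path)]})
    assert back == sorted(calls, key=lambda c: c.locus_key)


def test_vcf_input_matches_tsv_dialect(tmp_path):
    vcf = tmp_path / "S1.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr3,length=200000000>\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##INFO=<ID=VARCLASS,Number=1,Type=String,Description="c">\n'
        '##INFO=<ID=IMPACT_RANK,Number=1,Type=Integer,Description="i">\n'
        '##INFO=<ID=DAMAGING,Number=1,Type=String,Description="d">\n'
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="p">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        "chr3\t100\t.\tA\tT\t.\tPASS\t"
        "GENE=PIK3CA;VARCLASS=missense;IMPACT_RANK=25;DAMAGING=true;PCHANGE=E545K"
        "\tGT\t0/1\n"
    )
    from_vcf = read_snv_calls({"caller1": [str(vcf)]})
    tsv = _snv_file(tmp_path, "c1.tsv", [ROW])
    from_tsv = read_snv_calls({"caller1": [str(tsv)]})
    assert from_vcf == from_tsv


@pytest.mark.parametrize(
    "cn,category",
    [(0, CNVCategory.DEL), (1, CNVCategory.LOSS), (2, CNVCategory.NEUTRAL),
     (3, CNVCategory.GAIN), (4, CNVCategory.GAIN), (5, CNVCategory.AMP),
     (17, CNVCategory.AMP)],
)
def test_copy_number_categories(cn, category):
    assert categorize_copy_number(cn) is category


def test_negative_copy_number_is_error():
    with pytest.raises(CohortIOError):
        categorize_copy_number(-1)


def test_cnv_reader_derives_category_and_rejects_duplicates(tmp_path):
    p = tmp_path / "cnv.tsv"
    p.write_text("sample_id\tgene\tcopy_number\nS1\tCDKN2A\t0\n")
    (call,) = read_cnv_calls(p)
    assert call.category is CNVCategory.DEL

    p.write_text("sample_id\tgene\tcopy_number\nS1\tCDKN2A\t0\nS1\tCDKN2A\t3\n")
    with pytest.raises(CohortIOError, match="duplicate"):
        read_cnv_calls(p)


def test_expression_reader_rejects_duplicate_genes(tmp_path):
    p = tmp_path / "expr.tsv"
    p.write_text("gene\tS1\tS2\nTP53\t1.0\t2.0\tp53\t0.1\t0.2\nTP53\t3.0\t4.0\n")
    p.write_text("gene\tS1\tS2\nTP53\t1.0\t2.0\nTP53\t3.0\t4.0\n")
    with pytest.raises(CohortIOError, match="duplicated gene"):
        read_expression(p)


def test_subtype_reader_and_unassigned_default(tmp_path):
    p = tmp_path / "subtypes.tsv"
    p.write_text("sample_id\tsubtype\nS1\tLumP\nS2\tNE-like\n")
    labels = read_subtypes(p)
    assert labels == [
        SubtypeLabel("S1", Subtype.LUM_P),
        SubtypeLabel("S2", Subtype.NE_LIKE),
    ]
    mapping = subtype_map(labels, ["S1", "S2", "S3"])
    assert mapping["S3"] is Subtype.UNASSIGNED
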