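"""Mutation catalog: dialects, annotation, summaries, spectrum tallies."""

import pytest

from colonyevo.catalog import (
    CatalogError,
    MutationRecord,
    ReferenceMismatchError,
    annotate_effects,
    read_catalog,
    read_gd,
    read_tsv,
    summarize_catalog,
    tally_spectrum,
    write_gd,
    write_tsv,
)
from colonyevo.codon import CodingSequence, Effect, MutationClass

GD_SAMPLE = """\
#=GENOME_DIFF\t1.0
#=TITLE\tY5
SNP\t1\t11\tctg1\t100\tT\tgene_name=cspC
MOB\t2\t12\tctg1\t200\tIS1\t1\t9\tgene_name=yobF
DEL\t3\t13\tctg1\t300\t21000\tmediated=IS5\tgene_name=gadE;hdeA
INS\t4\t14\tctg1\t400\tGG
DEL\t5\t15\tctg1\t500\t2
AMP\t6\t16\tctg1\t600\t100\t2
RA\t7\t.\tctg1\t100\t0\tA\tT
"""


def test_gd_dialect_maps_entry_types(tmp_path):
    path = tmp_path / "sample.gd"
    path.write_text(GD_SAMPLE)
    records = read_gd(path)
    assert [r.mtype for r in records] == [
        "SNS", "IS_insertion", "large_deletion", "insertion", "deletion"
    ]
    assert all(r.isolate == "Y5" for r in records)
    sns = records[0]
    assert (sns.position, sns.alt_base, sns.genes) == (100, "T", ("cspC",))
    mob = records[1]
    assert mob.is_element == "IS1 (+)"
    big_del = records[2]
    assert big_del.is_mediated and big_del.size == 21000
    assert big_del.genes == ("gadE", "hdeA")
    assert records[4].mtype == "deletion" and records[4].size == 2


def test_gd_empty_file_yields_empty_list(tmp_path, caplog):
    path = tmp_path / "empty.gd"
    path.write_text("#=GENOME_DIFF\t1.0\n")
    assert read_gd(path) == []


def test_gd_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.gd"
    path.write_text("#=GENOME_DIFF\t1.0\nSNP\t1\t.\tctg1\tnot_a_number\tT\n")
    with pytest.raises(CatalogError, match="bad.gd:2"):
        read_gd(path)


def test_unknown_dialect_rejected(tmp_path):
    path = tmp_path / "x.txt"
    path.write_text("")
    with pytest.raises(CatalogError, match="dialect"):
        read_catalog(path, dialect="vcf")


def test_tsv_round_trip_is_field_for_field(tmp_path, study_catalog):
    _, records = study_catalog
    path = tmp_path / "catalog.tsv"
    write_tsv(records, path)
    back = read_tsv(path)
    assert back == records


def test_gd_round_trip_for_gd_representable_fields(tmp_path):
    records = [
        MutationRecord(isolate="Y5", position=100, mtype="SNS",
                       ref_base="A", alt_base="T", genes=("cspC",), seqid="ctg1"),
        MutationRecord(isolate="Y5", position=200, mtype="IS_insertion",
                       is_element="IS1 (+)", genes=("yobF",), seqid="ctg1",
                       is_mediated=True),
        MutationRecord(isolate="Y5", position=300, mtype="large_deletion",
                       size=21000, is_element="IS5", is_mediated=True, seqid="ctg1"),
    ]
    path = tmp_path / "y5.gd"
    write_gd(records, path)
    back = read_gd(path)
    for orig, rt in zip(records, back):
        for field in ("isolate", "position", "mtype", "alt_base", "is_element",
                      "size", "genes", "seqid", "is_mediated", "ref_base"):
            assert getattr(rt, field) == getattr(orig, field), field


def test_gd_writer_refuses_multi_isolate_catalogs(tmp_path):
    records = [
        MutationRecord(isolate="Y1", position=1, mtype="SNS", ref_base="A", alt_base="T"),
        MutationRecord(isolate="Y2", position=2, mtype="SNS", ref_base="A", alt_base="T"),
    ]
    with pytest.raises(CatalogError, match="single isolate"):
        write_gd(records, tmp_path / "multi.gd")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _toy_cds():
    # reference: ATGGAATAA at 11..19 (+) and its mirror at 31..39 (-)
    plus = CodingSequence(id="gplus", seq="ATGGAATAA", genomic_start=11,
                          genomic_end=19, strand="+", seqid="ctg1")
    minus = CodingSequence(id="gminus", seq="ATGGAATAA", genomic_start=31,
                           genomic_end=39, strand="-", seqid="ctg1")
    return [plus, minus]


def test_annotate_plus_strand_nonsense():
    # GAA -> TAA via G>T at cds position 4 (genomic 14)
    records = [MutationRecord(isolate="Y1", position=14, mtype="SNS",
                              ref_base="G", alt_base="T", seqid="ctg1")]
    (annotated,) = annotate_effects(records, _toy_cds())
    assert annotated.effect is Effect.NONSENSE
    assert annotated.region == "coding"
    assert annotated.genes == ("gplus",)


def test_annotate_minus_strand_complements_alt():
    # coding position 4 of the minus CDS is genomic 36; genomic C>A reads
    # as coding G>T, turning GAA into the TAA stop
    records = [MutationRecord(isolate="Y1", position=36, mtype="SNS",
                              ref_base="C", alt_base="A", seqid="ctg1")]
    (annotated,) = annotate_effects(records, _toy_cds())
    assert annotated.effect is Effect.NONSENSE
    assert annotated.genes == ("gminus",)


def test_annotate_intergenic_and_non_sns():
    records = [
        MutationRecord(isolate="Y1", position=25, mtype="SNS",
                       ref_base="A", alt_base="T", seqid="ctg1"),
        MutationRecord(isolate="Y1", position=14, mtype="IS_insertion",
                       is_element="IS1", seqid="ctg1"),
    ]
    annotated = annotate_effects(records, _toy_cds())
    assert annotated[0].region == "intergenic"
    assert annotated[0].effect is Effect.NOT_APPLICABLE
    assert annotated[1].effect is Effect.NOT_APPLICABLE


def test_annotate_detects_reference_mismatch():
    records = [MutationRecord(isolate="Y1", position=14, mtype="SNS",
                              ref_base="C", alt_base="T", seqid="ctg1")]
    with pytest.raises(ReferenceMismatchError) as err:
        annotate_effects(records, _toy_cds())
    assert err.value.discordant[0][1] == "G"


def test_annotate_is_idempotent(study_catalog):
    genome, annotated = study_catalog
    again = annotate_effects(annotated, genome.cds, reference=genome)
    assert again == annotated


# ---------------------------------------------------------------------------
# summaries / spectrum
# ---------------------------------------------------------------------------

def test_summary_counts_three_simple_records():
    records = [
        MutationRecord(isolate="Y1", position=10, mtype="IS_insertion",
                       is_element="IS1", effect=Effect.NOT_APPLICABLE),
        MutationRecord(isolate="Y1", position=20, mtype="SNS", ref_base="A",
                       alt_base="G", region="coding", effect=Effect.SYNONYMOUS),
        MutationRecord(isolate="Y2", position=30, mtype="SNS", ref_base="C",
                       alt_base="T", region="intergenic",
                       effect=Effect.NOT_APPLICABLE),
    ]
    s = summarize_catalog(records)
    assert s.n_events == 3
    assert s.counts_by_mtype == {"IS_insertion": 1, "SNS": 2}
    assert s.is_counts_by_element == {"IS1": 1}
    assert s.sns_effect_counts == {"synonymous": 1, "intergenic": 1}


def test_shared_event_counts_once_but_per_isolate_separately():
    shared = dict(position=100, mtype="IS_insertion", is_element="IS1")
    records = [
        MutationRecord(isolate="Y1", **shared),
        MutationRecord(isolate="Y2", **shared),
    ]
    s = summarize_catalog(records)
    assert s.n_events == 1
    assert s.n_records == 2
    assert s.per_isolate_counts == {"Y1": 1, "Y2": 1}


def test_empty_catalog_summary_is_all_zero():
    s = summarize_catalog([])
    assert s.n_events == 0 and s.per_isolate_counts == {}


def test_spectrum_tally_counts_only_coding_sns():
    records = [
        MutationRecord(isolate="Y1", position=1, mtype="SNS", ref_base="A",
                       alt_base="C", region="coding", effect=Effect.MISSENSE),
        MutationRecord(isolate="Y1", position=2, mtype="SNS", ref_base="G",
                       alt_base="A", region="coding", effect=Effect.NONSENSE),
        MutationRecord(isolate="Y1", position=3, mtype="SNS", ref_base="T",
                       alt_base="C", region="coding", effect=Effect.SYNONYMOUS),
        MutationRecord(isolate="Y1", position=4, mtype="SNS", ref_base="A",
                       alt_base="T", region="intergenic",
                       effect=Effect.NOT_APPLICABLE),
        MutationRecord(isolate="Y1", position=5, mtype="IS_insertion",
                       is_element="IS5", effect=Effect.NOT_APPLICABLE),
    ]
    counts = tally_spectrum(records)
    assert counts.n[MutationClass.AT_CG] == 1   # missense A>C
    assert counts.n[MutationClass.CG_TA] == 1   # nonsense G>A
    assert counts.s[MutationClass.AT_GC] == 1   # synonymous T>C
    assert counts.total_n() == 2 and counts.total_s() == 1


def test_spectrum_tally_requires_annotation():
    records = [MutationRecord(isolate="Y1", position=1, mtype="SNS",
                              ref_base="A", alt_base="C")]
    with pytest.raises(CatalogError, match="annotate_effects"):
        tally_spectrum(records)


def test_is_only_catalog_gives_all_zero_spectrum():
    records = [MutationRecord(isolate="Y1", position=1, mtype="IS_insertion",
                              is_element="IS1", effect=Effect.NOT_APPLICABLE)]
    counts = tally_spectrum(records)
    assert counts.total_n() == 0 and counts.total_s() == 0


def test_partition_invariant_on_study_catalog(study_catalog):
    _, annotated = study_catalog
    counts = tally_spectrum(annotated)
    n_coding_sns = sum(
        1 for r in annotated
        if r.mtype == "SNS" and r.effect not in (None, Effect.NOT_APPLICABLE)
    )
    assert counts.total_s() + counts.total_n() == n_coding_sns
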