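"""Codon model: mutation classes, substitution effects, site counting."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyevo.codon import (
    CodingSequence,
    Effect,
    MutationClass,
    classify_spectrum_class,
    classify_substitution_effect,
    count_sites,
)

# every directed substitution and its unordered base-pair class
DIRECTED = [
    ("A", "C", MutationClass.AT_CG), ("T", "G", MutationClass.AT_CG),
    ("A", "G", MutationClass.AT_GC), ("T", "C", MutationClass.AT_GC),
    ("A", "T", MutationClass.AT_TA), ("T", "A", MutationClass.AT_TA),
    ("C", "G", MutationClass.CG_GC), ("G", "C", MutationClass.CG_GC),
    ("C", "T", MutationClass.CG_TA), ("G", "A", MutationClass.CG_TA),
    ("G", "T", MutationClass.GC_TA), ("C", "A", MutationClass.GC_TA),
]

NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def raw_cds(seq: str) -> CodingSequence:
    return CodingSequence(id="raw", seq=seq, genomic_start=1, genomic_end=len(seq))


@pytest.mark.parametrize("ref,alt,expected", DIRECTED)
def test_all_twelve_directed_substitutions_map_by_base_pair_symmetry(ref, alt, expected):
    assert classify_spectrum_class(ref, alt) is expected
    # the complementary substitution lands in the same class
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    assert classify_spectrum_class(comp[ref], comp[alt]) is expected


def test_spectrum_class_rejects_bad_input():
    with pytest.raises(ValueError):
        classify_spectrum_class("A", "A")
    with pytest.raises(ValueError):
        classify_spectrum_class("N", "A")


@pytest.mark.parametrize(
    "seq,pos,alt,effect,mclass",
    [
        ("TTT", 3, "C", Effect.SYNONYMOUS, MutationClass.AT_GC),  # TTC is still Phe
        ("TTT", 1, "A", Effect.MISSENSE, MutationClass.AT_TA),    # ATT is Ile
        ("TAC", 3, "A", Effect.NONSENSE, MutationClass.GC_TA),    # TAA is stop
        ("GAA", 1, "T", Effect.NONSENSE, MutationClass.GC_TA),    # TAA is stop
    ],
)
def test_substitution_effects_match_codon_table(seq, pos, alt, effect, mclass):
    assert classify_substitution_effect(raw_cds(seq), pos, alt) == (effect, mclass)


def test_substitution_effect_position_guard():
    with pytest.raises(ValueError):
        classify_substitution_effect(raw_cds("TTT"), 4, "A")
    with pytest.raises(ValueError):
        classify_substitution_effect(raw_cds("TTT"), 1, "T")


def test_count_sites_single_phe_codon():
    table = count_sites([raw_cds("TTT")], validate=False)
    assert table.S[MutationClass.AT_GC] == 1
    assert sum(table.S.values()) == 1
    assert table.N[MutationClass.AT_CG] == 3
    assert table.N[MutationClass.AT_GC] == 2
    assert table.N[MutationClass.AT_TA] == 3
    assert table.total_opportunities() == 9


def test_count_sites_single_met_codon_has_no_synonymous_opportunity():
    table = count_sites([raw_cds("ATG")], validate=False)
    assert all(v == 0 for v in table.S.values())
    expected_n = {
        MutationClass.AT_CG: 2, MutationClass.AT_GC: 2, MutationClass.AT_TA: 2,
        MutationClass.CG_GC: 1, MutationClass.CG_TA: 1, MutationClass.GC_TA: 1,
    }
    assert table.N == expected_n


def test_terminal_stop_codon_excluded_by_default_and_countable_on_request():
    cds = raw_cds("ATGTAA")
    default = count_sites([cds], validate=False)
    assert default.counted_length == 3
    # when included, stop->stop is synonymous: TAA->TGA and TAA->TAG (both A->G)
    included = count_sites([cds], validate=False, include_terminal_stop=True)
    assert included.counted_length == 6
    stop_s = {m: included.S[m] - default.S[m] for m in MutationClass}
    assert stop_s[MutationClass.AT_GC] == 2
    assert sum(stop_s.values()) == 2


def test_ambiguous_bases_are_skipped_and_tallied():
    table = count_sites([raw_cds("ATGNNN")], validate=False)
    assert table.skipped_positions == 3
    assert table.total_opportunities() == 9  # only the ATG codon counted


def test_count_sites_empty_set_errors():
    with pytest.raises(ValueError):
        count_sites([])


def brute_force_table(seq: str, code_table: int = 11):
    """Independent oracle: mutate every position, re-translate the whole CDS."""
    S = {m: 0 for m in MutationClass}
    N = {m: 0 for m in MutationClass}
    protein = str(Seq(seq).translate(table=code_table))
    for i, ref in enumerate(seq):
        for alt in "ACGT":
            if alt == ref:
                continue
            mutated = seq[:i] + alt + seq[i + 1 :]
            mclass = classify_spectrum_class(ref, alt)
            if str(Seq(mutated).translate(table=code_table)) == protein:
                S[mclass] += 1
            else:
                N[mclass] += 1
    return S, N


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(st.sampled_from(NON_STOP_CODONS), min_size=1, max_size=100).map("".join)
)
def test_count_sites_equals_whole_cds_retranslation_oracle(seq):
    table = count_sites([raw_cds(seq)], validate=False)
    S, N = brute_force_table(seq)
    assert table.S == S
    assert table.N == N


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(st.sampled_from(NON_STOP_CODONS), min_size=1, max_size=100).map("".join)
)
def test_opportunity_conservation(seq):
    table = count_sites([raw_cds(seq)], validate=False)
    assert table.total_opportunities() == 3 * table.counted_length
    assert table.counted_length == len(seq)


def test_conservation_on_genome_scale_fixture(sites_table):
    assert sites_table.total_opportunities() == 3 * sites_table.counted_length
    assert all(v >= 0 for v in sites_table.S.values())
    assert all(v >= 0 for v in sites_table.N.values())


def test_monotonicity_adding_a_cds_never_decreases_counts(small_genome):
    partial = count_sites(small_genome.cds[:6])
    full = count_sites(small_genome.cds)
    for m in MutationClass:
        assert full.S[m] >= partial.S[m]
        assert full.N[m] >= partial.N[m]


def test_invalid_cds_raises_or_is_skipped_per_options():
    bad = CodingSequence(id="bad", seq="ATGCCCC", genomic_start=1, genomic_end=7)
    assert "length not divisible by 3" in bad.validation_errors()
    with pytest.raises(ValueError, match="divisible"):
        count_sites([bad])
    good = raw_cds("ATGCCC")
    table = count_sites([bad, good], skip_invalid=True)
    assert table.options["n_invalid_skipped"] == 1
    assert table.cds_ids == ("raw",)


def test_site_table_tsv_json_round_trip(tmp_path, sites_table):
    from colonyevo.codon import SiteCountTable

    tsv = tmp_path / "sites.tsv"
    sites_table.to_tsv(tsv)
    back = SiteCountTable.from_tsv(tsv)
    assert back.S == sites_table.S and back.N == sites_table.N

    js = tmp_path / "sites.json"
    sites_table.to_json(js)
    back2 = SiteCountTable.from_json(js)
    assert back2.S == sites_table.S and back2.N == sites_table.N
    assert back2.options == sites_table.options
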