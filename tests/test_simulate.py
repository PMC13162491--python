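"""Synthetic-data generators: determinism, invariants, planted structure."""

import numpy as np
import pytest

from colonyevo.catalog import annotate_effects, tally_spectrum
from colonyevo.codon import Effect, MutationClass, _stop_codons, count_sites
from colonyevo.enrichment import hypergeom_overlap
from colonyevo.simulate import (
    CompetitionConfig,
    EnrichmentConfig,
    GenomeConfig,
    MutationConfig,
    synth_competition,
    synth_genesets,
    synth_genome,
    synth_mutations,
)


def test_generated_cds_satisfy_all_invariants(small_genome):
    stops = _stop_codons(11)
    for cds in small_genome.cds:
        assert cds.validation_errors() == []
        assert cds.seq.startswith("ATG")
        assert cds.seq[-3:] in stops
        assert cds.genomic_end - cds.genomic_start + 1 == len(cds.seq)
    # both strands exercised
    assert {c.strand for c in small_genome.cds} == {"+", "-"}


def test_contig_carries_reverse_complement_for_minus_strand(small_genome):
    contig = small_genome.sequences[small_genome.cds[0].seqid]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for cds in small_genome.cds:
        genomic = contig[cds.genomic_start - 1 : cds.genomic_end]
        if cds.strand == "+":
            assert genomic == cds.seq
        else:
            assert genomic == "".join(comp[b] for b in reversed(cds.seq))


def test_genome_determinism_under_fixed_seed():
    a = synth_genome(GenomeConfig(num_cds=5), seed=42)
    b = synth_genome(GenomeConfig(num_cds=5), seed=42)
    assert a.sequences == b.sequences
    assert a.cds == b.cds


def test_single_short_cds_generation():
    genome = synth_genome(GenomeConfig(num_cds=1, min_cds_length=30,
                                       max_cds_length=30), seed=0)
    assert len(genome.cds) == 1
    assert len(genome.cds[0].seq) == 30


def test_high_gc_genome_realises_requested_composition():
    genome = synth_genome(
        GenomeConfig(num_cds=100, min_cds_length=150, max_cds_length=300, gc=0.7),
        seed=3,
    )
    coding = "".join(c.seq for c in genome.cds)
    gc = sum(b in "GC" for b in coding) / len(coding)
    assert gc == pytest.approx(0.7, abs=0.03)


def test_mutation_catalog_determinism(small_genome):
    cfg = MutationConfig(n_mutations=20)
    a = synth_mutations(small_genome, cfg, seed=9)
    b = synth_mutations(small_genome, cfg, seed=9)
    assert a.records == b.records
    assert a.true_counts == b.true_counts


def test_mutations_annotate_consistently_with_true_counts(small_genome):
    """Generator-recorded truth equals what the annotation pipeline derives."""
    synth = synth_mutations(small_genome, MutationConfig(n_mutations=60), seed=4)
    annotated = annotate_effects(synth.records, small_genome.cds,
                                 reference=small_genome)
    counts = tally_spectrum(annotated)
    assert counts.s == synth.true_counts.s
    assert counts.n == synth.true_counts.n


def test_omega_zero_yields_only_synonymous_mutations(small_genome):
    synth = synth_mutations(
        small_genome, MutationConfig(omega=0.0, n_mutations=25), seed=6
    )
    assert synth.true_counts.total_n() == 0
    assert synth.true_counts.total_s() == 25
    annotated = annotate_effects(synth.records, small_genome.cds)
    assert all(r.effect is Effect.SYNONYMOUS for r in annotated)


def test_neutral_uniform_spectrum_matches_site_totals(small_genome, sites_table):
    # omega=1, uniform weights: fraction of synonymous draws ~ S/(S+N)
    synth = synth_mutations(small_genome, MutationConfig(n_mutations=2000), seed=8)
    p_syn = sum(sites_table.S.values()) / sites_table.total_opportunities()
    observed = synth.true_counts.total_s() / 2000
    # 4-sigma binomial band
    assert abs(observed - p_syn) < 4 * np.sqrt(p_syn * (1 - p_syn) / 2000)


def test_invalid_spectrum_rejected(small_genome):
    with pytest.raises(ValueError, match="non-negative"):
        synth_mutations(
            small_genome,
            MutationConfig(spectrum={m: -1.0 for m in MutationClass}),
            seed=0,
        )


def test_competition_noise_free_ratios_are_exact():
    cfg = CompetitionConfig(true_ratio=2.5, sigma_log2=0.0, n_colonies=5,
                            n_controls=3)
    data = synth_competition(cfg, seed=1)
    for m in data:
        expected = 1.0 if m.is_control else 2.5
        assert m.a_value / m.b_value == pytest.approx(expected)


def test_competition_neutral_mean_log2_obeys_clt_bound():
    cfg = CompetitionConfig(true_ratio=1.0, sigma_log2=0.5, n_colonies=2000,
                            n_controls=0)
    data = synth_competition(cfg, seed=11)
    log2_ratios = np.log2([m.a_value / m.b_value for m in data])
    assert abs(log2_ratios.mean()) < 3 * 0.5 / np.sqrt(2000)


def test_competition_determinism_and_proportion_modality():
    cfg = CompetitionConfig(modality="proportion", n_colonies=4, n_controls=2)
    a = synth_competition(cfg, seed=13)
    assert a == synth_competition(cfg, seed=13)
    for m in a:
        assert m.a_value + m.b_value == pytest.approx(1.0)


def test_genesets_feasibility_and_planted_signal():
    cfg = EnrichmentConfig(n_universe=800, n_targets=120, n_module=60, fold=3.0)
    folds = []
    for rep in range(30):
        universe, targets, module = synth_genesets(cfg, seed=100 + rep)
        assert len(universe) == 800 and len(targets) == 120 and len(module) == 60
        res = hypergeom_overlap(set(module), set(targets), set(universe))
        assert res.overlap <= min(60, 120)
        folds.append(res.fold)
    null_cfg = EnrichmentConfig(n_universe=800, n_targets=120, n_module=60, fold=1.0)
    null_folds = []
    for rep in range(30):
        _, targets, module = synth_genesets(null_cfg, seed=200 + rep)
        null_folds.append(
            hypergeom_overlap(set(module), set(targets), 800).fold
        )
    assert np.median(folds) >= 1.5 * max(np.median(null_folds), 1e-9)


def test_null_genesets_give_calibrated_p_values():
    """fold=1 modules are uniform draws, so the overlap follows the exact
    hypergeometric null: the randomised p-value (p_upper minus a uniform
    fraction of the atom P[X=k], the standard construction for discrete
    statistics) is U(0,1) (KS at alpha=0.01), and p_upper itself is
    superuniform at the 5% level."""
    from scipy import stats

    cfg = EnrichmentConfig(n_universe=4175, n_targets=713, n_module=243, fold=1.0)
    rng = np.random.default_rng(99)
    pvals, randomised = [], []
    for rep in range(200):
        _, targets, module = synth_genesets(cfg, seed=300 + rep)
        res = hypergeom_overlap(set(module), set(targets), cfg.n_universe)
        atom = stats.hypergeom.pmf(res.overlap, cfg.n_universe,
                                   cfg.n_targets, cfg.n_module)
        pvals.append(res.p_upper)
        randomised.append(res.p_upper - rng.uniform() * atom)
    d, p = stats.kstest(randomised, "uniform")
    assert p > 0.01
    reject_rate = np.mean(np.asarray(pvals) <= 0.05)
    assert reject_rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)
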