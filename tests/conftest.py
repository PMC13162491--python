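import numpy as np
import pytest

from colonyevo.catalog import annotate_effects
from colonyevo.codon import MutationClass, count_sites
from colonyevo.datasets import synthetic_study_catalog
from colonyevo.simulate import GenomeConfig, synth_genome


@pytest.fixture(scope="session")
def small_genome():
    """A dozen valid CDS on both strands of one synthetic contig."""
    return synth_genome(
        GenomeConfig(num_cds=12, min_cds_length=150, max_cds_length=450), seed=1
    )


@pytest.fixture(scope="session")
def sites_table(small_genome):
    return count_sites(small_genome.cds)


@pytest.fixture(scope="session")
def transition_biased_spectrum():
    """Transition classes weighted 10x the transversion classes."""
    transitions = (MutationClass.AT_GC, MutationClass.CG_TA)
    return {m: (10.0 if m in transitions else 1.0) for m in MutationClass}


@pytest.fixture(scope="session")
def study_catalog():
    """Annotated synthetic reconstruction of the study's mutation catalog."""
    genome, records = synthetic_study_catalog(seed=0)
    return genome, annotate_effects(records, genome.cds, reference=genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
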