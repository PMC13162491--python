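"""Synthetic-data generators with the statistical structure the analyses assume.

Every stage of the pipeline is testable without downloads: random valid
coding genomes, spectrum-biased mutation catalogs with a known selection
parameter omega, mixed-colony competition measurements with multiplicative
lognormal noise around a known fitness ratio, and gene universes with a
planted target-set enrichment.

omega is defined operationally as the acceptance probability of
non-synonymous proposals: proposals (position, alternative base) are drawn
with probability proportional to the class weight beta of the substitution,
synonymous proposals are always accepted and non-synonymous ones with
probability omega.  Under this model the expected value recovered by the
spectrum-corrected Ka/Ks estimators is exactly omega, giving a sharp
parameter-recovery contract, while the crude count ratio converges to a
spectrum-weighted N/S ratio instead.

All generators are deterministic under a fixed seed; the global seed is
expanded into fixed per-generator substreams so each component is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import MutationRecord, SpectrumCounts
from .codon import (
    COMPLEMENT,
    CodingSequence,
    Effect,
    MutationClass,
    _stop_codons,
    classify_substitution_effect,
)
from .competition import CompetitionMeasurement
from .genome_io import AnnotatedGenome

#: fixed substream keys so each generator has its own reproducible stream
_STREAMS = {"genome": 11, "mutations": 23, "competition": 37, "genesets": 53}


def substream(seed: int, name: str) -> np.random.Generator:
    """Per-generator RNG derived from the single global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass
class GenomeConfig:
    """Random coding-genome parameters (lengths in nt, divisible by 3)."""

    num_cds: int = 40
    min_cds_length: int = 150
    max_cds_length: int = 900
    gc: float = 0.51          # E. coli-like genomic GC fraction
    spacer_min: int = 20
    spacer_max: int = 120
    seqid: str = "synthchr_1"


@dataclass
class MutationConfig:
    """Mutation-catalog parameters: class weights beta, selection omega."""

    spectrum: dict | None = None   # MutationClass -> weight; None = uniform
    omega: float = 1.0
    n_mutations: int = 50
    n_isolates: int = 24


@dataclass
class CompetitionConfig:
    """Mixed-colony assay parameters (matching the 4-colony assay design)."""

    true_ratio: float = 6.2
    sigma_log2: float = 0.22
    n_colonies: int = 4
    n_controls: int = 4
    baseline: float = 20.0         # mm^2 reference-strain colony area
    baseline_sd_ln: float = 0.2
    modality: str = "area"
    strain_a: str = "mutant"
    strain_b: str = "WT-mKate"


@dataclass
class EnrichmentConfig:
    """Gene-universe parameters with a planted enrichment fold phi."""

    n_universe: int = 4175
    n_targets: int = 713
    n_module: int = 243
    fold: float = 2.1


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    mutations: MutationConfig = field(default_factory=MutationConfig)
    competition: CompetitionConfig = field(default_factory=CompetitionConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_codon(rng, gc, stops, forbid_stop=True, max_tries=200):
    for _ in range(max_tries):
        codon = "".join(
            rng.choice(("G", "C")) if rng.random() < gc else rng.choice(("A", "T"))
            for _ in range(3)
        )
        if not forbid_stop or codon not in stops:
            return codon
    raise RuntimeError("could not draw a non-stop codon; infeasible GC setting")


def synth_genome(
    config: GenomeConfig | SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    code_table: int = 11,
) -> AnnotatedGenome:
    """Generate a single-contig genome of valid CDS separated by spacers.

    Every CDS starts with ATG, ends with a stop codon, contains no internal
    stop, and satisfies the coding-sequence invariants; roughly half are
    placed on the minus strand (the contig stores their reverse complement).
    """
    if isinstance(config, SimulationConfig):
        seed = config.seed if seed is None else seed
        config = config.genome
    if rng is None:
        rng = substream(seed or 0, "genome")
    stops = _stop_codons(code_table)
    stop_list = sorted(stops)
    contig_parts: list[str] = []
    cds_list: list[CodingSequence] = []
    cursor = 0  # 0-based length so far
    lengths = [
        3 * int(rng.integers(config.min_cds_length // 3, config.max_cds_length // 3 + 1))
        for _ in range(config.num_cds)
    ]
    for idx, length in enumerate(lengths, 1):
        spacer_len = int(rng.integers(config.spacer_min, config.spacer_max + 1))
        spacer = "".join(
            rng.choice(("G", "C")) if rng.random() < config.gc else rng.choice(("A", "T"))
            for _ in range(spacer_len)
        )
        contig_parts.append(spacer)
        cursor += spacer_len
        n_codons = length // 3
        body = [_random_codon(rng, config.gc, stops) for _ in range(n_codons - 2)]
        coding = "ATG" + "".join(body) + stop_list[int(rng.integers(len(stop_list)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor + 1
        end = cursor + length
        genomic = coding if strand == "+" else _revcomp(coding)
        contig_parts.append(genomic)
        cursor += length
        cds = CodingSequence(
            id=f"sg{idx:04d}", seq=coding, genomic_start=start, genomic_end=end,
            strand=strand, seqid=config.seqid,
        )
        errors = cds.validation_errors(code_table)
        if errors:  # pragma: no cover - construction guarantees validity
            raise RuntimeError(f"generated invalid CDS {cds.id}: {errors}")
        cds_list.append(cds)
    tail = "".join(
        rng.choice(("G", "C")) if rng.random() < config.gc else rng.choice(("A", "T"))
        for _ in range(int(rng.integers(config.spacer_min, config.spacer_max + 1)))
    )
    contig_parts.append(tail)
    return AnnotatedGenome(
        sequences={config.seqid: "".join(contig_parts)}, cds=cds_list, rejected=[]
    )


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

@dataclass
class SynthCatalog:
    """Generated catalog plus the true per-class counts for oracle checks."""

    records: list
    true_counts: SpectrumCounts
    n_proposed: int = 0
    n_rejected: int = 0


def synth_mutations(
    genome: AnnotatedGenome,
    config: MutationConfig | SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    code_table: int = 11,
) -> SynthCatalog:
    """Draw a spectrum-biased mutation catalog with selection parameter omega.

    Proposals are (coding position, alternative base) pairs drawn with
    probability proportional to the class weight of the substitution;
    synonymous proposals are always accepted, non-synonymous ones with
    probability omega; accepted mutations are emitted (as raw, unannotated
    records in reference coordinates) until ``n_mutations`` are collected.
    """
    if isinstance(config, SimulationConfig):
        seed = config.seed if seed is None else seed
        config = config.mutations
    if rng is None:
        rng = substream(seed or 0, "mutations")
    spectrum = config.spectrum or {m: 1.0 for m in MutationClass}
    spectrum = {MutationClass.from_label(k) if isinstance(k, str) else k: float(v)
                for k, v in spectrum.items()}
    if any(v < 0 for v in spectrum.values()) or sum(spectrum.values()) <= 0:
        raise ValueError("spectrum weights must be non-negative with a positive sum")

    stops = _stop_codons(code_table)
    # enumerate substitution opportunities per class (terminal stop excluded,
    # consistent with the default site-counting convention)
    opportunities: dict[MutationClass, list] = {m: [] for m in MutationClass}
    from .codon import classify_spectrum_class

    for cds in genome.cds:
        seq = cds.seq.upper()
        count_len = len(seq)
        if count_len >= 3 and seq[-3:] in stops:
            count_len -= 3
        for pos0 in range(count_len):
            ref = seq[pos0]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mclass = classify_spectrum_class(ref, alt)
                opportunities[mclass].append((cds, pos0, alt))

    weights = np.array(
        [spectrum.get(m, 0.0) * len(opportunities[m]) for m in MutationClass]
    )
    if weights.sum() <= 0:
        raise ValueError("no substitution opportunities under the given spectrum")
    probs = weights / weights.sum()
    classes = list(MutationClass)

    if config.omega == 0:
        has_syn = any(
            classify_substitution_effect(cds, pos0 + 1, alt, code_table)[0]
            is Effect.SYNONYMOUS
            for m in classes if spectrum.get(m, 0.0) > 0
            for cds, pos0, alt in opportunities[m][:2000]
        )
        if not has_syn:
            raise ValueError("omega = 0 but the genome offers no synonymous opportunity")

    records: list[MutationRecord] = []
    true_counts = SpectrumCounts()
    n_proposed = 0
    n_rejected = 0
    max_proposals = max(100_000, 10_000 * config.n_mutations)
    while len(records) < config.n_mutations:
        if n_proposed >= max_proposals:
            raise RuntimeError(
                f"proposal budget exhausted after {n_proposed} draws; "
                "omega too small for this genome"
            )
        ci = int(rng.choice(len(classes), p=probs))
        mclass = classes[ci]
        cds, pos0, alt = opportunities[mclass][int(rng.integers(len(opportunities[mclass])))]
        n_proposed += 1
        effect, _ = classify_substitution_effect(cds, pos0 + 1, alt, code_table)
        if effect is not Effect.SYNONYMOUS and rng.random() >= config.omega:
            n_rejected += 1
            continue
        if cds.strand == "+":
            gpos = cds.genomic_start + pos0
            ref_g = cds.seq[pos0].upper()
            alt_g = alt
        else:
            gpos = cds.genomic_end - pos0
            ref_g = COMPLEMENT[cds.seq[pos0].upper()]
            alt_g = COMPLEMENT[alt]
        isolate = f"S{int(rng.integers(1, config.n_isolates + 1)):02d}"
        records.append(MutationRecord(
            isolate=isolate, position=gpos, mtype="SNS",
            ref_base=ref_g, alt_base=alt_g, genes=(cds.id,), seqid=cds.seqid,
        ))
        if effect is Effect.SYNONYMOUS:
            true_counts.s[mclass] += 1
        else:
            true_counts.n[mclass] += 1
    return SynthCatalog(records, true_counts, n_proposed, n_rejected)


# ---------------------------------------------------------------------------
# Competition
# ---------------------------------------------------------------------------

def synth_competition(
    config: CompetitionConfig | SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CompetitionMeasurement]:
    """Mixed-colony measurements with multiplicative lognormal noise.

    Per colony the reference measurement is a lognormal baseline and the
    focal strain's is ``true_ratio * b * 2**eps`` with
    ``eps ~ Normal(0, sigma_log2**2)``; control colonies use ratio 1.  For
    the proportion modality the two values are normalised to sum to one.
    """
    if isinstance(config, SimulationConfig):
        seed = config.seed if seed is None else seed
        config = config.competition
    if rng is None:
        rng = substream(seed or 0, "competition")
    if config.sigma_log2 < 0:
        raise ValueError("sigma_log2 must be non-negative")
    out: list[CompetitionMeasurement] = []

    def one(colony_id, ratio, strain_a, strain_b, is_control):
        b = config.baseline * float(np.exp(rng.normal(0.0, config.baseline_sd_ln)))
        eps = float(rng.normal(0.0, config.sigma_log2)) if config.sigma_log2 > 0 else 0.0
        a = ratio * b * 2.0 ** eps
        if config.modality == "proportion":
            total = a + b
            a, b = a / total, b / total
        return CompetitionMeasurement(
            colony_id=colony_id, strain_a=strain_a, strain_b=strain_b,
            a_value=a, b_value=b, modality=config.modality, is_control=is_control,
        )

    for i in range(1, config.n_colonies + 1):
        out.append(one(f"mix{i:03d}", config.true_ratio,
                       config.strain_a, config.strain_b, False))
    for i in range(1, config.n_controls + 1):
        out.append(one(f"ctrl{i:03d}", 1.0, "WT-YFP", config.strain_b, True))
    return out


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def synth_genesets(
    config: EnrichmentConfig | SimulationConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Universe, target set and module with a planted enrichment.

    With fold = 1 the module is a simple random sample of the universe (the
    exact hypergeometric null); with fold != 1 the number of target genes in
    the module is drawn so its expectation is fold * n * K / N, clipped to
    feasibility.
    """
    if isinstance(config, SimulationConfig):
        seed = config.seed if seed is None else seed
        config = config.enrichment
    if rng is None:
        rng = substream(seed or 0, "genesets")
    N, K, n = config.n_universe, config.n_targets, config.n_module
    if not (0 < K <= N and 0 < n <= N):
        raise ValueError(f"infeasible gene-set sizes N={N}, K={K}, n={n}")
    if config.fold < 0:
        raise ValueError("planted fold must be non-negative")
    width = len(str(N))
    universe = [f"g{i:0{width}d}" for i in range(1, N + 1)]
    target_idx = rng.choice(N, size=K, replace=False)
    targets = [universe[i] for i in sorted(target_idx)]
    if config.fold == 1.0:
        module_idx = rng.choice(N, size=n, replace=False)
        module = [universe[i] for i in sorted(module_idx)]
    else:
        p_hit = min(max(config.fold * K / N, 0.0), 1.0)
        k = int(rng.binomial(n, p_hit))
        k = max(k, n - (N - K))  # feasibility: not enough non-targets otherwise
        k = min(k, min(n, K))
        target_set = set(target_idx.tolist())
        non_targets = np.array(sorted(set(range(N)) - target_set))
        chosen = list(rng.choice(np.array(sorted(target_set)), size=k, replace=False))
        chosen += list(rng.choice(non_targets, size=n - k, replace=False))
        module = [universe[i] for i in sorted(chosen)]
    return universe, targets, module
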