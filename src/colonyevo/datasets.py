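"""Synthetic stand-in datasets mirroring the published study's composition.

The mutation catalog built here is a SYNTHETIC reconstruction: the study's
row-level catalog is not redistributed with this package, so a catalog with
the same marginal composition is generated over a synthetic genome — 34
distinct mutational events across 22 of 24 isolates affecting 66 genes:
11 IS insertions (7 IS1, 3 IS5, 1 IS186/IS421), 2 large IS-mediated
deletions (spanning 26 and 14 genes), 4 short indels (1 intragenic 66-bp
deletion shared by two isolates, 3 intergenic), and 17 single-nucleotide
substitutions (14 coding: 4 nonsense, 8 missense, 2 synonymous; 3
intergenic).  Positions and sequences are synthetic; every coding effect is
realised by an actual substitution in the synthetic genome so the annotation
machinery derives the effect rather than being told it.
"""

from __future__ import annotations

from .catalog import MutationRecord
from .codon import COMPLEMENT, Effect, classify_substitution_effect, _stop_codons
from .genome_io import AnnotatedGenome
from .simulate import GenomeConfig, synth_genome

#: isolates carrying at least one mutation (two of the 24 carry none)
_MUTATED_ISOLATES = [f"Y{i}" for i in range(1, 25) if i not in (20, 21)]


def _find_substitution(cds, wanted: Effect, used_positions, code_table=11):
    """First substitution in a CDS with the wanted coding effect."""
    seq = cds.seq.upper()
    count_len = len(seq)
    if count_len >= 3 and seq[-3:] in _stop_codons(code_table):
        count_len -= 3
    for pos0 in range(count_len):
        ref = seq[pos0]
        for alt in "ACGT":
            if alt == ref:
                continue
            effect, _ = classify_substitution_effect(cds, pos0 + 1, alt, code_table)
            if effect is wanted:
                if cds.strand == "+":
                    gpos = cds.genomic_start + pos0
                    return gpos, ref, alt
                gpos = cds.genomic_end - pos0
                return gpos, COMPLEMENT[ref], COMPLEMENT[alt]
    return None


def synthetic_study_catalog(seed: int = 0):
    """Synthetic genome + raw mutation catalog with the study's marginal tallies.

    Returns ``(genome, records)``; the records are unannotated (run
    ``annotate_effects`` with the returned genome), and summarising the
    annotated catalog reproduces the published marginal counts.
    """
    genome: AnnotatedGenome = synth_genome(
        GenomeConfig(num_cds=20, min_cds_length=300, max_cds_length=600), seed=seed
    )
    seqid = genome.cds[0].seqid
    contig = genome.sequences[seqid]

    # --- 14 coding SNS in 14 distinct CDS: 4 nonsense, 8 missense, 2 synonymous
    wanted_effects = (
        [Effect.NONSENSE] * 4 + [Effect.MISSENSE] * 8 + [Effect.SYNONYMOUS] * 2
    )
    coding_sns = []
    used = set()
    cds_iter = iter(genome.cds)
    for wanted in wanted_effects:
        while True:
            cds = next(cds_iter)
            hit = _find_substitution(cds, wanted, used)
            if hit is not None and hit[0] not in used:
                used.add(hit[0])
                coding_sns.append((hit[0], hit[1], hit[2]))
                break

    # --- intergenic positions (spacers between CDS)
    covered = []
    for cds in genome.cds:
        covered.append((cds.genomic_start, cds.genomic_end))
    covered.sort()

    def intergenic_positions(count):
        out = []
        pos = 5
        for (start, _end) in covered:
            while pos < start and len(out) < count:
                if contig[pos - 1] in COMPLEMENT:
                    out.append(pos)
                pos += 3
            pos = _end + 3
            if len(out) >= count:
                break
        if len(out) < count:
            raise RuntimeError("not enough intergenic positions")
        return out

    inter = intergenic_positions(20)
    events = []

    for gpos, ref, alt in coding_sns:
        events.append(dict(position=gpos, mtype="SNS", ref_base=ref, alt_base=alt))
    for gpos in inter[:3]:  # 3 intergenic SNS
        ref = contig[gpos - 1]
        alt = "A" if ref != "A" else "G"
        events.append(dict(position=gpos, mtype="SNS", ref_base=ref, alt_base=alt))

    # --- 11 IS insertions: 7 IS1, 3 IS5, 1 IS186/IS421
    is_labels = ["IS1"] * 7 + ["IS5"] * 3 + ["IS186/IS421"]
    for i, (gpos, label) in enumerate(zip(inter[3:14], is_labels)):
        # ten IS events hit fresh genes; the eleventh re-hits a mutated CDS
        gene = f"isg_{i + 1:02d}" if i < 10 else genome.cds[0].id
        events.append(dict(position=gpos, mtype="IS_insertion",
                           is_element=f"{label} (+)", genes=(gene,)))

    # --- 2 large IS-mediated deletions spanning 26 and 14 genes
    events.append(dict(position=inter[14], mtype="large_deletion", size=21000,
                       is_element="IS5", is_mediated=True,
                       genes=tuple(f"ld1_{j:02d}" for j in range(1, 27))))
    events.append(dict(position=inter[15], mtype="large_deletion", size=14000,
                       is_element="IS5", is_mediated=True,
                       genes=tuple(f"ld2_{j:02d}" for j in range(1, 15))))

    # --- 4 short indels: one intragenic 66-bp deletion (shared by 2 isolates),
    #     three intergenic (one annotated with its flanking gene)
    events.append(dict(position=inter[16], mtype="deletion", size=66,
                       genes=("ind_01",)))
    events.append(dict(position=inter[17], mtype="deletion", size=1))
    events.append(dict(position=inter[18], mtype="insertion", alt_base="G", size=1))
    events.append(dict(position=inter[19], mtype="insertion", alt_base="TA", size=2,
                       genes=("flank_01",)))

    assert len(events) == 34

    # --- distribute over 22 isolates (1-2 records each); the 66-bp deletion
    #     appears in two isolates (35 records, 34 distinct events)
    records = []
    shared = events[30]  # the intragenic 66-bp deletion
    assert shared["mtype"] == "deletion" and shared["size"] == 66
    assignments = events + [shared]
    for i, ev in enumerate(assignments):
        isolate = _MUTATED_ISOLATES[i % len(_MUTATED_ISOLATES)]
        records.append(MutationRecord(
            isolate=isolate, seqid=seqid,
            **{k: v for k, v in ev.items()},
        ))
    return genome, records
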