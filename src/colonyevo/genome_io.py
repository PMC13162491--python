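"""Readers and writers for annotated genomes (GenBank, FASTA + GFF3).

CDS are extracted on the coding strand (minus-strand features are
reverse-complemented).  Features that violate the coding-sequence invariants
are returned in a separate rejected list together with the reasons — never
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gffutils
from Bio import SeqIO

from .codon import CodingSequence, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class RejectedCds:
    cds: CodingSequence
    reasons: list[str]


@dataclass
class AnnotatedGenome:
    """Contig sequences plus the CDS extracted from the annotation."""

    sequences: dict[str, str]
    cds: list[CodingSequence]
    rejected: list[RejectedCds]

    def reference_base(self, seqid: str, position: int) -> str:
        """1-based reference base lookup."""
        seq = self.sequences[seqid]
        if not (1 <= position <= len(seq)):
            raise ValueError(f"position {position} outside contig {seqid}")
        return seq[position - 1].upper()


def _build_cds(seqid, contig_seq, start, end, strand, cds_id, code_table, accepted, rejected):
    if start < 1 or end > len(contig_seq):
        raise ValueError(
            f"CDS {cds_id} coordinates {start}..{end} out of range for contig "
            f"{seqid} (length {len(contig_seq)})"
        )
    raw = contig_seq[start - 1 : end].upper()
    seq = reverse_complement(raw) if strand == "-" else raw
    cds = CodingSequence(
        id=cds_id, seq=seq, genomic_start=start, genomic_end=end,
        strand=strand, seqid=seqid,
    )
    errors = cds.validation_errors(code_table)
    if errors:
        rejected.append(RejectedCds(cds, errors))
    else:
        accepted.append(cds)


def read_genbank(path, code_table: int = 11) -> AnnotatedGenome:
    """Read sequence and CDS features from a GenBank flat file."""
    sequences: dict[str, str] = {}
    accepted: list[CodingSequence] = []
    rejected: list[RejectedCds] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        contig_seq = str(record.seq).upper()
        if not contig_seq or set(contig_seq) == {"N"}:
            raise ValueError(f"missing sequence for contig {record.id} in {path}")
        sequences[record.id] = contig_seq
        counter = 0
        for feature in record.features:
            if feature.type != "CDS":
                continue
            counter += 1
            quals = feature.qualifiers
            cds_id = (
                quals.get("locus_tag", quals.get("gene", [f"CDS_{counter}"]))[0]
            )
            loc = feature.location
            if len(loc.parts) > 1:
                # compound (joined) locations: record as rejected, not dropped
                seq = str(feature.extract(record.seq)).upper()
                cds = CodingSequence(
                    id=cds_id, seq=seq,
                    genomic_start=int(loc.start) + 1, genomic_end=int(loc.end),
                    strand="-" if loc.strand == -1 else "+", seqid=record.id,
                )
                rejected.append(RejectedCds(cds, ["compound (join) location unsupported"]))
                continue
            strand = "-" if loc.strand == -1 else "+"
            _build_cds(
                record.id, contig_seq, int(loc.start) + 1, int(loc.end),
                strand, cds_id, code_table, accepted, rejected,
            )
    if n_records == 0:
        raise ValueError(f"no GenBank records found in {path}")
    return AnnotatedGenome(sequences, accepted, rejected)


def read_fasta_gff3(fasta_path, gff3_path, code_table: int = 11) -> AnnotatedGenome:
    """Read contigs from FASTA and CDS features from a GFF3 annotation."""
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not sequences:
        raise ValueError(f"no sequences found in {fasta_path}")
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    accepted: list[CodingSequence] = []
    rejected: list[RejectedCds] = []
    counter = 0
    for feature in db.features_of_type("CDS", order_by=("seqid", "start")):
        counter += 1
        if feature.seqid not in sequences:
            raise ValueError(
                f"missing sequence for annotated contig {feature.seqid!r}"
            )
        attrs = feature.attributes
        cds_id = (
            attrs.get("locus_tag", attrs.get("ID", attrs.get("Parent", [f"CDS_{counter}"])))[0]
        )
        strand = "-" if feature.strand == "-" else "+"
        _build_cds(
            feature.seqid, sequences[feature.seqid], feature.start, feature.end,
            strand, cds_id, code_table, accepted, rejected,
        )
    return AnnotatedGenome(sequences, accepted, rejected)


def read_annotated_genome(
    genbank=None, fasta=None, gff3=None, code_table: int = 11
) -> AnnotatedGenome:
    """Dispatch to the GenBank or FASTA+GFF3 reader.

    Exactly one of ``genbank`` or the ``fasta``/``gff3`` pair must be given.
    """
    if genbank is not None:
        if fasta is not None or gff3 is not None:
            raise ValueError("give either a GenBank file or a FASTA+GFF3 pair, not both")
        return read_genbank(genbank, code_table)
    if fasta is None or gff3 is None:
        raise ValueError("FASTA and GFF3 paths are both required")
    return read_fasta_gff3(fasta, gff3, code_table)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seqid, seq in sequences.items():
            fh.write(f">{seqid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(cds_list, path, source: str = "colonyevo") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cds in cds_list:
            attrs = f"ID={cds.id};locus_tag={cds.id}"
            fh.write(
                "\t".join(
                    [
                        cds.seqid or "contig_1",
                        source,
                        "CDS",
                        str(cds.genomic_start),
                        str(cds.genomic_end),
                        ".",
                        cds.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
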