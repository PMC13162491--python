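"""Codon-level substitution model: mutation classes, coding effects, site counts.

The mutational spectrum is summarised by six unordered base-pair substitution
classes (AT>CG, AT>GC, AT>TA, CG>GC, CG>TA, GC>TA): every directed
single-base change maps to exactly one class via base-pair symmetry, e.g.
A>C and T>G are both AT>CG, and C>T and G>A are both CG>TA (the transition
on a C:G pair).

Site counting enumerates, for every nucleotide of a coding-sequence set and
each of its three alternative bases, whether the substitution is synonymous
or non-synonymous (nonsense included), and accumulates the opportunity into
the class-specific totals ``S_i`` / ``N_i``.  These per-class totals are what
the spectrum-corrected Ka/Ks estimators consume.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

from Bio.Data import CodonTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_REVCOMP_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP_TABLE)[::-1]


class MutationClass(enum.Enum):
    """One of the six unordered base-pair substitution classes."""

    AT_CG = "AT>CG"
    AT_GC = "AT>GC"
    AT_TA = "AT>TA"
    CG_GC = "CG>GC"
    CG_TA = "CG>TA"
    GC_TA = "GC>TA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "MutationClass":
        label = label.strip().replace("→", ">").replace("->", ">")
        for m in cls:
            if m.value == label:
                return m
        raise ValueError(f"unknown mutation class label: {label!r}")


#: Directed substitution (ref, alt) -> unordered base-pair class.
_CLASS_OF_SUBSTITUTION = {
    ("A", "C"): MutationClass.AT_CG,
    ("T", "G"): MutationClass.AT_CG,
    ("A", "G"): MutationClass.AT_GC,
    ("T", "C"): MutationClass.AT_GC,
    ("A", "T"): MutationClass.AT_TA,
    ("T", "A"): MutationClass.AT_TA,
    ("C", "G"): MutationClass.CG_GC,
    ("G", "C"): MutationClass.CG_GC,
    ("C", "T"): MutationClass.CG_TA,
    ("G", "A"): MutationClass.CG_TA,
    ("G", "T"): MutationClass.GC_TA,
    ("C", "A"): MutationClass.GC_TA,
}


def classify_spectrum_class(ref_base: str, alt_base: str) -> MutationClass:
    """Map a directed single-base substitution to its base-pair class.

    Parameters
    ----------
    ref_base, alt_base
        Single nucleotides in ``{A, C, G, T}`` (case-insensitive); must differ.
    """
    ref = ref_base.upper()
    alt = alt_base.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"non-ACGT base in substitution {ref_base}>{alt_base}")
    if ref == alt:
        raise ValueError(f"ref and alt bases are identical: {ref_base}")
    return _CLASS_OF_SUBSTITUTION[(ref, alt)]


class Effect(enum.Enum):
    """Coding effect of a single-nucleotide substitution."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    NOT_APPLICABLE = "not_applicable"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CodingSequence:
    """A coding sequence on the coding strand, with reference coordinates.

    ``genomic_start``/``genomic_end`` are 1-based inclusive positions on the
    reference; for minus-strand CDS the sequence stored here is the reverse
    complement of the reference slice.
    """

    id: str
    seq: str
    genomic_start: int
    genomic_end: int
    strand: str = "+"
    seqid: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def validation_errors(self, code_table: int = 11) -> list[str]:
        """Invariant violations; empty list means the CDS is valid."""
        errors = []
        if len(self.seq) % 3 != 0:
            errors.append("length not divisible by 3")
        span = self.genomic_end - self.genomic_start + 1
        if span != len(self.seq):
            errors.append(
                f"coordinate span {span} does not equal sequence length {len(self.seq)}"
            )
        stops = _stop_codons(code_table)
        # internal stops only: terminal codon may legitimately be a stop
        for i in range(0, max(len(self.seq) - 3, 0) - 2, 3):
            codon = self.seq[i : i + 3].upper()
            if codon in stops:
                errors.append(f"internal stop codon {codon} at codon {i // 3 + 1}")
                break
        return errors

    def genomic_to_cds(self, genomic_pos: int) -> int:
        """1-based genomic coordinate -> 1-based offset within the CDS."""
        if not (self.genomic_start <= genomic_pos <= self.genomic_end):
            raise ValueError(
                f"position {genomic_pos} outside CDS {self.id} "
                f"({self.genomic_start}..{self.genomic_end})"
            )
        if self.strand == "+":
            return genomic_pos - self.genomic_start + 1
        return self.genomic_end - genomic_pos + 1


def _codon_tables(code_table: int):
    try:
        table = CodonTable.unambiguous_dna_by_id[code_table]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code table id {code_table}") from exc
    return table.forward_table, frozenset(table.stop_codons)


_TABLE_CACHE: dict[int, tuple[dict, frozenset]] = {}


def _stop_codons(code_table: int) -> frozenset:
    if code_table not in _TABLE_CACHE:
        _TABLE_CACHE[code_table] = _codon_tables(code_table)
    return _TABLE_CACHE[code_table][1]


def translate_codon(codon: str, code_table: int = 11) -> str:
    """Single-codon translation; stop codons translate to ``*``."""
    if code_table not in _TABLE_CACHE:
        _TABLE_CACHE[code_table] = _codon_tables(code_table)
    forward, stops = _TABLE_CACHE[code_table]
    codon = codon.upper()
    if codon in stops:
        return "*"
    try:
        return forward[codon]
    except KeyError as exc:
        raise ValueError(f"cannot translate codon {codon!r}") from exc


def classify_substitution_effect(
    cds: CodingSequence,
    cds_position: int,
    alt_base: str,
    code_table: int = 11,
) -> tuple[Effect, MutationClass]:
    """Coding effect and mutation class of one substitution within a CDS.

    ``cds_position`` is the 1-based offset on the coding strand.  The affected
    codon is translated before and after the change: sense->stop is nonsense,
    stop->stop is synonymous, any amino-acid change is missense (stop->sense
    included), and an identical amino acid is synonymous.
    """
    if not (1 <= cds_position <= len(cds.seq)):
        raise ValueError(
            f"cds_position {cds_position} out of range 1..{len(cds.seq)} for {cds.id}"
        )
    ref = cds.seq[cds_position - 1].upper()
    alt = alt_base.upper()
    mclass = classify_spectrum_class(ref, alt)

    codon_index = (cds_position - 1) // 3
    within = (cds_position - 1) % 3
    codon = cds.seq[codon_index * 3 : codon_index * 3 + 3].upper()
    mutated = codon[:within] + alt + codon[within + 1 :]

    aa_before = translate_codon(codon, code_table)
    aa_after = translate_codon(mutated, code_table)
    if aa_before == aa_after:
        effect = Effect.SYNONYMOUS
    elif aa_after == "*":
        effect = Effect.NONSENSE
    else:
        effect = Effect.MISSENSE
    return effect, mclass


@dataclass
class SiteCountTable:
    """Per-class totals of synonymous (S_i) / non-synonymous (N_i) opportunities."""

    S: dict[MutationClass, float] = field(
        default_factory=lambda: {m: 0.0 for m in MutationClass}
    )
    N: dict[MutationClass, float] = field(
        default_factory=lambda: {m: 0.0 for m in MutationClass}
    )
    cds_ids: tuple[str, ...] = ()
    options: dict = field(default_factory=dict)
    skipped_positions: int = 0
    counted_length: int = 0

    def total_opportunities(self) -> float:
        return sum(self.S.values()) + sum(self.N.values())

    def scaled(self, factor: float) -> "SiteCountTable":
        return SiteCountTable(
            S={m: v * factor for m, v in self.S.items()},
            N={m: v * factor for m, v in self.N.items()},
            cds_ids=self.cds_ids,
            options=dict(self.options),
            skipped_positions=self.skipped_positions,
            counted_length=self.counted_length,
        )

    # -- serialisation -----------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class\tS\tN\n")
            for m in MutationClass:
                fh.write(f"{m.value}\t{self.S[m]:.10g}\t{self.N[m]:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "SiteCountTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:3] != ["class", "S", "N"]:
                raise ValueError(f"unexpected site-table header in {path}: {header}")
            for line in fh:
                if not line.strip():
                    continue
                label, s, n = line.rstrip("\n").split("\t")[:3]
                m = MutationClass.from_label(label)
                table.S[m] = float(s)
                table.N[m] = float(n)
        return table

    def to_json(self, path=None):
        payload = {
            "S": {m.value: self.S[m] for m in MutationClass},
            "N": {m.value: self.N[m] for m in MutationClass},
            "cds_ids": list(self.cds_ids),
            "options": self.options,
            "skipped_positions": self.skipped_positions,
            "counted_length": self.counted_length,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    @classmethod
    def from_json(cls, path) -> "SiteCountTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            S={MutationClass.from_label(k): v for k, v in payload["S"].items()},
            N={MutationClass.from_label(k): v for k, v in payload["N"].items()},
            cds_ids=tuple(payload.get("cds_ids", ())),
            options=payload.get("options", {}),
            skipped_positions=payload.get("skipped_positions", 0),
            counted_length=payload.get("counted_length", 0),
        )


def count_sites(
    cds_set,
    code_table: int = 11,
    include_terminal_stop: bool = False,
    skip_invalid: bool = False,
    validate: bool = True,
) -> SiteCountTable:
    """Enumerate substitution opportunities over a CDS set.

    Every position of every CDS (terminal stop codon excluded unless
    ``include_terminal_stop``) contributes its three alternative bases to the
    class totals: synonymous changes to ``S_i``, amino-acid-changing or
    nonsense changes to ``N_i``.  Positions with ambiguous bases (N etc.) are
    skipped and tallied in ``skipped_positions``.

    With ``validate`` set (default), CDS violating the coding-sequence
    invariants raise unless ``skip_invalid`` is set, in which case they are
    skipped with a tally in ``options['n_invalid_skipped']``.
    """
    cds_list = list(cds_set)
    if not cds_list:
        raise ValueError("empty CDS set")
    table = SiteCountTable(
        options={
            "code_table": code_table,
            "include_terminal_stop": include_terminal_stop,
            "skip_invalid": skip_invalid,
            "validate": validate,
            "n_invalid_skipped": 0,
        }
    )
    stops = _stop_codons(code_table)
    ids = []
    for cds in cds_list:
        if validate:
            errors = cds.validation_errors(code_table)
            if errors:
                if skip_invalid:
                    table.options["n_invalid_skipped"] += 1
                    continue
                raise ValueError(f"invalid CDS {cds.id}: {'; '.join(errors)}")
        seq = cds.seq.upper()
        count_len = len(seq)
        if not include_terminal_stop and count_len >= 3 and seq[-3:] in stops:
            count_len -= 3
        for pos0 in range(count_len):
            ref = seq[pos0]
            if ref not in COMPLEMENT:
                table.skipped_positions += 1
                continue
            codon_start = (pos0 // 3) * 3
            codon = seq[codon_start : codon_start + 3]
            if any(b not in COMPLEMENT for b in codon):
                table.skipped_positions += 1
                continue
            for alt in "ACGT":
                if alt == ref:
                    continue
                effect, mclass = classify_substitution_effect(
                    cds, pos0 + 1, alt, code_table
                )
                if effect is Effect.SYNONYMOUS:
                    table.S[mclass] += 1
                else:
                    table.N[mclass] += 1
            table.counted_length += 1
        ids.append(cds.id)
    table.cds_ids = tuple(ids)
    return table
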