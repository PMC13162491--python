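"""Mutation catalogs of evolved isolates: parsing, annotation, tallies.

Supports two on-disk dialects: a minimal subset of the breseq Genome Diff
(GD) format (mutational entries SNP/INS/DEL/MOB; evidence lines ignored) and
a flat TSV with the documented header.  Coding effects are filled in by
``annotate_effects`` using the codon model, strand-aware; the per-class
observed counts that the Ka/Ks estimators consume come from
``tally_spectrum``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from .codon import (
    COMPLEMENT,
    CodingSequence,
    Effect,
    MutationClass,
    classify_spectrum_class,
    classify_substitution_effect,
)

logger = logging.getLogger(__name__)

MUTATION_TYPES = ("SNS", "insertion", "deletion", "IS_insertion", "large_deletion")

#: deletions at least this long are typed large_deletion when read from GD
LARGE_DELETION_MIN_BP = 100

TSV_COLUMNS = [
    "isolate", "position", "type", "ref", "alt", "element", "size",
    "genes", "region", "effect", "seqid",
]


class CatalogError(ValueError):
    pass


class ReferenceMismatchError(CatalogError):
    """Catalog ref bases disagree with the reference genome."""

    def __init__(self, discordant):
        self.discordant = discordant
        lines = ", ".join(
            f"{r.isolate}:{r.position} {r.ref_base}->{expected}"
            for r, expected in discordant
        )
        super().__init__(f"catalog/reference mismatch at {lines}")


@dataclass(frozen=True)
class MutationRecord:
    """One genomic mutational event in one isolate."""

    isolate: str
    position: int
    mtype: str
    ref_base: str | None = None
    alt_base: str | None = None
    is_element: str | None = None
    size: int | None = None
    genes: tuple[str, ...] = ()
    region: str | None = None
    effect: Effect | None = None
    is_mediated: bool = False
    seqid: str = ""

    def __post_init__(self):
        if self.mtype not in MUTATION_TYPES:
            raise CatalogError(f"unknown mutation type {self.mtype!r}")
        if self.mtype == "SNS":
            if self.ref_base is not None and self.alt_base is not None:
                if self.ref_base.upper() == self.alt_base.upper():
                    raise CatalogError(
                        f"SNS at {self.position} has identical ref and alt bases"
                    )
        if self.mtype == "IS_insertion" and not self.is_element:
            raise CatalogError(f"IS insertion at {self.position} lacks an element label")

    @property
    def change(self) -> str:
        """Canonical description of the sequence change (distinct-event key part)."""
        if self.mtype == "SNS":
            return f"{self.ref_base or '?'}>{self.alt_base}"
        if self.mtype == "IS_insertion":
            return f"+{self.is_element}"
        if self.mtype in ("deletion", "large_deletion"):
            return f"del{self.size or '?'}"
        return f"ins{self.alt_base or self.size or '?'}"

    def event_key(self) -> tuple:
        return (self.seqid, self.position, self.mtype, self.change)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _parse_gd_kv(fields):
    kv = {}
    for item in fields:
        if "=" in item:
            key, _, value = item.partition("=")
            kv[key] = value
    return kv


def read_gd(path, isolate: str | None = None) -> list[MutationRecord]:
    """Parse the mutational-entry subset of a breseq Genome Diff file.

    SNP -> SNS, INS -> insertion, DEL -> deletion (``large_deletion`` when at
    least ``LARGE_DELETION_MIN_BP``), MOB -> IS_insertion.  AMP and unknown
    entry types are skipped with a warning; evidence lines (RA/JC/MC/UN) are
    ignored.  The isolate defaults to the ``#=TITLE`` header.
    """
    records: list[MutationRecord] = []
    title = None
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#=TITLE"):
                    title = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else None
                continue
            fields = line.split("\t")
            etype = fields[0]
            if etype in ("RA", "JC", "MC", "UN"):
                continue
            try:
                if etype == "SNP":
                    seqid, position, new_base = fields[3], int(fields[4]), fields[5]
                    kv = _parse_gd_kv(fields[6:])
                    records.append(MutationRecord(
                        isolate=isolate or title or "unknown",
                        position=position, mtype="SNS",
                        ref_base=kv.get("ref_base"), alt_base=new_base,
                        genes=_split_genes(kv.get("gene_name")),
                        seqid=seqid,
                    ))
                elif etype == "INS":
                    seqid, position, new_seq = fields[3], int(fields[4]), fields[5]
                    kv = _parse_gd_kv(fields[6:])
                    records.append(MutationRecord(
                        isolate=isolate or title or "unknown",
                        position=position, mtype="insertion",
                        alt_base=new_seq, size=len(new_seq),
                        genes=_split_genes(kv.get("gene_name")),
                        seqid=seqid,
                    ))
                elif etype == "DEL":
                    seqid, position, size = fields[3], int(fields[4]), int(fields[5])
                    kv = _parse_gd_kv(fields[6:])
                    mediated = "mediated" in kv or "repeat_name" in kv
                    mtype = (
                        "large_deletion" if size >= LARGE_DELETION_MIN_BP else "deletion"
                    )
                    records.append(MutationRecord(
                        isolate=isolate or title or "unknown",
                        position=position, mtype=mtype, size=size,
                        genes=_split_genes(kv.get("gene_name")),
                        is_mediated=mediated,
                        is_element=kv.get("mediated") or kv.get("repeat_name"),
                        seqid=seqid,
                    ))
                elif etype == "MOB":
                    seqid, position, repeat_name = fields[3], int(fields[4]), fields[5]
                    raw_strand = fields[6] if len(fields) > 6 else "?"
                    strand = {"1": "+", "-1": "-", "+": "+", "-": "-"}.get(raw_strand)
                    kv = _parse_gd_kv(fields[7:])
                    records.append(MutationRecord(
                        isolate=isolate or title or "unknown",
                        position=position, mtype="IS_insertion",
                        is_element=f"{repeat_name} ({strand})" if strand else repeat_name,
                        genes=_split_genes(kv.get("gene_name")),
                        is_mediated=True,
                        seqid=seqid,
                    ))
                else:
                    n_skipped += 1
                    logger.warning("%s:%d: skipping unsupported GD entry type %s",
                                   path, lineno, etype)
            except (IndexError, ValueError) as exc:
                raise CatalogError(f"{path}:{lineno}: malformed GD line: {exc}") from exc
    if not records:
        logger.warning("%s: no mutational entries parsed", path)
    if n_skipped:
        logger.warning("%s: %d unsupported entries skipped", path, n_skipped)
    return records


def _split_genes(value) -> tuple[str, ...]:
    if not value:
        return ()
    for sep in (";", ",", "|", "/"):
        value = value.replace(sep, ";")
    return tuple(g.strip() for g in value.split(";") if g.strip())


def read_tsv(path) -> list[MutationRecord]:
    """Read the flat TSV catalog dialect (documented header)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in TSV_COLUMNS[:3] if c not in header]
        if missing:
            raise CatalogError(f"{path}: TSV header missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")

            def get(col, default=""):
                i = idx.get(col)
                return fields[i] if i is not None and i < len(fields) else default

            try:
                effect_str = get("effect")
                records.append(MutationRecord(
                    isolate=get("isolate"),
                    position=int(get("position")),
                    mtype=get("type"),
                    ref_base=get("ref") or None,
                    alt_base=get("alt") or None,
                    is_element=get("element") or None,
                    size=int(get("size")) if get("size") else None,
                    genes=_split_genes(get("genes")),
                    region=get("region") or None,
                    effect=Effect(effect_str) if effect_str else None,
                    is_mediated=get("is_mediated", "").lower() in ("1", "true", "yes"),
                    seqid=get("seqid"),
                ))
            except (ValueError, CatalogError) as exc:
                raise CatalogError(f"{path}:{lineno}: malformed TSV line: {exc}") from exc
    if not records:
        logger.warning("%s: empty catalog", path)
    return records


def read_catalog(path, dialect: str = "flat_tsv", isolate: str | None = None):
    if dialect == "gd":
        return read_gd(path, isolate=isolate)
    if dialect == "flat_tsv":
        return read_tsv(path)
    raise CatalogError(f"unknown catalog dialect {dialect!r}")


def write_tsv(records, path) -> None:
    cols = TSV_COLUMNS + ["is_mediated"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.isolate,
                str(r.position),
                r.mtype,
                r.ref_base or "",
                r.alt_base or "",
                r.is_element or "",
                "" if r.size is None else str(r.size),
                ";".join(r.genes),
                r.region or "",
                r.effect.value if r.effect else "",
                r.seqid,
                "true" if r.is_mediated else "false",
            ]) + "\n")


def write_gd(records, path, title: str | None = None) -> None:
    """Write records for one isolate in the GD mutational-entry subset."""
    isolates = {r.isolate for r in records}
    if len(isolates) > 1:
        raise CatalogError("GD files hold a single isolate; split the catalog first")
    with open(path, "w") as fh:
        fh.write("#=GENOME_DIFF\t1.0\n")
        fh.write(f"#=TITLE\t{title or (next(iter(isolates)) if isolates else 'empty')}\n")
        for i, r in enumerate(records, 1):
            seqid = r.seqid or "reference"
            extras = []
            if r.genes:
                extras.append(f"gene_name={';'.join(r.genes)}")
            if r.mtype == "SNS":
                if r.ref_base:
                    extras.append(f"ref_base={r.ref_base}")
                fh.write("\t".join(["SNP", str(i), ".", seqid, str(r.position),
                                    r.alt_base or "?"] + extras) + "\n")
            elif r.mtype == "insertion":
                fh.write("\t".join(["INS", str(i), ".", seqid, str(r.position),
                                    r.alt_base or "N" * (r.size or 1)] + extras) + "\n")
            elif r.mtype in ("deletion", "large_deletion"):
                if r.is_mediated and r.is_element:
                    extras.append(f"mediated={r.is_element}")
                fh.write("\t".join(["DEL", str(i), ".", seqid, str(r.position),
                                    str(r.size or 1)] + extras) + "\n")
            elif r.mtype == "IS_insertion":
                element = r.is_element or "IS"
                strand = "1"
                if "(" in element:
                    element, _, rest = element.partition(" (")
                    strand = {"+": "1", "-": "-1"}.get(rest.rstrip(")"), "1")
                fh.write("\t".join(["MOB", str(i), ".", seqid, str(r.position),
                                    element, strand] + extras) + "\n")
            else:  # pragma: no cover - MUTATION_TYPES is closed
                raise CatalogError(f"cannot write mutation type {r.mtype}")


def write_catalog(records, path, dialect: str = "flat_tsv") -> None:
    if dialect == "gd":
        write_gd(records, path)
    elif dialect == "flat_tsv":
        write_tsv(records, path)
    else:
        raise CatalogError(f"unknown catalog dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_effects(
    records,
    cds_set,
    reference=None,
    code_table: int = 11,
) -> list[MutationRecord]:
    """Fill coding effects for SNS records, strand-aware.

    Each SNS falling inside a CDS is classified with the codon model; for
    minus-strand CDS the alt base is complemented before codon substitution.
    SNS covered by no CDS get ``region='intergenic'``; non-SNS records get
    ``effect=not_applicable``.  ``reference`` (an AnnotatedGenome or a
    ``{seqid: sequence}`` mapping) fills missing ref bases for intergenic SNS.

    Raises ``ReferenceMismatchError`` listing every SNS whose recorded ref
    base disagrees with the reference, which signals a catalog/reference
    mismatch that would corrupt downstream Ka/Ks.
    """
    trees: dict[str, IntervalTree] = {}
    for cds in cds_set:
        trees.setdefault(cds.seqid, IntervalTree()).addi(
            cds.genomic_start, cds.genomic_end + 1, cds
        )
    ref_seqs = None
    if reference is not None:
        ref_seqs = getattr(reference, "sequences", reference)

    annotated: list[MutationRecord] = []
    discordant: list[tuple[MutationRecord, str]] = []
    for r in records:
        if r.mtype != "SNS":
            annotated.append(replace(r, effect=Effect.NOT_APPLICABLE))
            continue
        tree = trees.get(r.seqid) or (trees.get("") if len(trees) == 1 else None)
        if tree is None and len(trees) == 1:
            tree = next(iter(trees.values()))
        hits = sorted(tree[r.position], key=lambda iv: iv.begin) if tree is not None else []
        if not hits:
            ref_base = r.ref_base
            if ref_base is None and ref_seqs is not None and r.seqid in ref_seqs:
                ref_base = ref_seqs[r.seqid][r.position - 1].upper()
            annotated.append(replace(
                r, region="intergenic", effect=Effect.NOT_APPLICABLE, ref_base=ref_base,
            ))
            continue
        cds: CodingSequence = hits[0].data
        cds_pos = cds.genomic_to_cds(r.position)
        coding_ref = cds.seq[cds_pos - 1].upper()
        expected_genomic_ref = (
            coding_ref if cds.strand == "+" else COMPLEMENT[coding_ref]
        )
        if r.ref_base is not None and r.ref_base.upper() != expected_genomic_ref:
            discordant.append((r, expected_genomic_ref))
            continue
        alt = r.alt_base.upper()
        coding_alt = alt if cds.strand == "+" else COMPLEMENT[alt]
        effect, _ = classify_substitution_effect(cds, cds_pos, coding_alt, code_table)
        genes = r.genes if r.genes else (cds.id,)
        annotated.append(replace(
            r, region="coding", effect=effect, ref_base=expected_genomic_ref, genes=genes,
        ))
    if discordant:
        raise ReferenceMismatchError(discordant)
    return annotated


# ---------------------------------------------------------------------------
# Summaries and spectrum tallies
# ---------------------------------------------------------------------------

@dataclass
class CatalogSummary:
    """Deterministic tallies over a mutation catalog."""

    n_events: int = 0
    n_records: int = 0
    n_isolates_with_mutations: int = 0
    n_genes_affected: int = 0
    counts_by_mtype: dict = field(default_factory=dict)
    is_counts_by_element: dict = field(default_factory=dict)
    n_is_mediated: int = 0
    sns_effect_counts: dict = field(default_factory=dict)
    per_isolate_counts: dict = field(default_factory=dict)
    effects_available: bool = True

    def to_json(self, path=None):
        payload = {k: getattr(self, k) for k in (
            "n_events", "n_records", "n_isolates_with_mutations", "n_genes_affected",
            "counts_by_mtype", "is_counts_by_element", "n_is_mediated",
            "sns_effect_counts", "per_isolate_counts", "effects_available",
        )}
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload

    def to_text(self) -> str:
        lines = [
            f"distinct mutational events : {self.n_events}",
            f"records (isolate x event)  : {self.n_records}",
            f"isolates with mutations    : {self.n_isolates_with_mutations}",
            f"genes affected             : {self.n_genes_affected}",
            f"IS-mediated events         : {self.n_is_mediated}",
            "events by type:",
        ]
        for k, v in sorted(self.counts_by_mtype.items()):
            lines.append(f"  {k:<15} {v}")
        if self.is_counts_by_element:
            lines.append("IS events by element family:")
            for k, v in sorted(self.is_counts_by_element.items()):
                lines.append(f"  {k:<15} {v}")
        if self.effects_available and self.sns_effect_counts:
            lines.append("SNS by effect:")
            for k, v in sorted(self.sns_effect_counts.items()):
                lines.append(f"  {k:<15} {v}")
        return "\n".join(lines)


def _element_family(label: str) -> str:
    """'IS1 (+)' -> 'IS1'."""
    return label.split()[0].split("(")[0] if label else "IS"


def summarize_catalog(records) -> CatalogSummary:
    """Tally a catalog; distinct events are unique (position, type, change) tuples."""
    summary = CatalogSummary()
    summary.n_records = len(records)
    events: dict[tuple, MutationRecord] = {}
    for r in records:
        events.setdefault(r.event_key(), r)
    summary.n_events = len(events)
    summary.n_isolates_with_mutations = len({r.isolate for r in records})
    genes = set()
    for r in records:
        genes.update(r.genes)
    summary.n_genes_affected = len(genes)
    for r in events.values():
        summary.counts_by_mtype[r.mtype] = summary.counts_by_mtype.get(r.mtype, 0) + 1
        if r.mtype == "IS_insertion":
            fam = _element_family(r.is_element)
            summary.is_counts_by_element[fam] = summary.is_counts_by_element.get(fam, 0) + 1
        if r.is_mediated or r.mtype == "IS_insertion":
            summary.n_is_mediated += 1
    sns_events = [r for r in events.values() if r.mtype == "SNS"]
    if any(r.effect is None for r in sns_events):
        summary.effects_available = False
    else:
        for r in sns_events:
            key = (
                "intergenic" if r.region == "intergenic" else r.effect.value
            )
            summary.sns_effect_counts[key] = summary.sns_effect_counts.get(key, 0) + 1
    for r in records:
        summary.per_isolate_counts[r.isolate] = summary.per_isolate_counts.get(r.isolate, 0) + 1
    return summary


@dataclass
class SpectrumCounts:
    """Observed per-class synonymous (s_i) / non-synonymous (n_i) SNS counts."""

    s: dict[MutationClass, int] = field(
        default_factory=lambda: {m: 0 for m in MutationClass}
    )
    n: dict[MutationClass, int] = field(
        default_factory=lambda: {m: 0 for m in MutationClass}
    )

    def total_s(self) -> int:
        return sum(self.s.values())

    def total_n(self) -> int:
        return sum(self.n.values())

    def to_json(self, path=None):
        payload = {
            "s": {m.value: self.s[m] for m in MutationClass},
            "n": {m.value: self.n[m] for m in MutationClass},
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def tally_spectrum(records) -> SpectrumCounts:
    """Per-class observed counts from coding SNS; everything else excluded.

    Missense and nonsense both increment ``n_i`` (stop-gain counted
    non-synonymous); synonymous increments ``s_i``.  Unannotated coding SNS
    raise, forcing ``annotate_effects`` first.
    """
    counts = SpectrumCounts()
    for r in records:
        if r.mtype != "SNS":
            continue
        if r.region == "intergenic":
            continue
        if r.effect is None:
            raise CatalogError(
                f"SNS at {r.position} ({r.isolate}) lacks effect annotation; "
                "run annotate_effects first"
            )
        if r.effect is Effect.NOT_APPLICABLE:
            continue
        mclass = classify_spectrum_class(r.ref_base, r.alt_base)
        if r.effect is Effect.SYNONYMOUS:
            counts.s[mclass] += 1
        else:
            counts.n[mclass] += 1
    return counts
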