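"""The annotation object hierarchy and its integrity rules.

The user-facing data model mirrors what a geneticist manipulates: genomes,
chromosomes, genes, transcripts, exons and proteins, each a stored record
kind.  Records are served by the store as lazy minimal views
(:mod:`genovault.store`); this module owns the *schema* — which fields each
kind has, which of them are heavy (deferred until first access) — and the
containment/ordering invariants that a well-formed genome satisfies.

Coordinate convention: all internal coordinates are 0-based, half-open
``[start, end)``.  GTF (1-based inclusive) and VCF (1-based) are converted
at parse time and back-converted on export, so ``end - start`` is always a
length.  Strand lives on the gene and is inherited by its transcripts and
exons; mixed-strand transcripts are rejected at import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import NotFoundError


@dataclass(frozen=True)
class KindSchema:
    """Storage schema for one record kind."""

    kind: str
    table: str
    fields: tuple[str, ...]            # all persisted fields, incl. "id"
    heavy: frozenset[str] = frozenset()  # deferred until first access
    json_fields: frozenset[str] = frozenset()  # TEXT columns holding JSON

    @property
    def light(self) -> tuple[str, ...]:
        return tuple(f for f in self.fields if f not in self.heavy)


KINDS: dict[str, KindSchema] = {
    s.kind: s
    for s in (
        KindSchema(
            "Genome", "genomes",
            ("id", "species", "description", "version", "maintainer",
             "chromosome_names"),
            json_fields=frozenset({"chromosome_names"}),
        ),
        KindSchema(
            "Chromosome", "chromosomes",
            ("id", "genome", "name", "length", "sequence"),
            heavy=frozenset({"sequence"}),
        ),
        KindSchema(
            "Gene", "genes",
            ("id", "genome", "name", "chromosome", "start", "end", "strand"),
        ),
        KindSchema(
            "Transcript", "transcripts",
            ("id", "genome", "gene", "chromosome", "start", "end", "strand",
             "exon_ids", "cds_intervals", "cds_frame", "protein_id",
             "sequence", "cds_sequence"),
            heavy=frozenset({"sequence", "cds_sequence"}),
            json_fields=frozenset({"exon_ids", "cds_intervals"}),
        ),
        KindSchema(
            "Exon", "exons",
            ("id", "genome", "gene", "transcript", "chromosome",
             "start", "end", "strand", "rank"),
        ),
        KindSchema(
            "Protein", "proteins",
            ("id", "genome", "transcript", "sequence"),
            heavy=frozenset({"sequence"}),
        ),
        KindSchema(
            "Polymorphism", "polymorphisms",
            ("id", "set_name", "chromosome", "position", "ref_allele",
             "alt_allele", "variant_kind", "quality", "metadata"),
            json_fields=frozenset({"metadata"}),
        ),
        KindSchema(
            "SnpSet", "snp_sets",
            ("id", "species", "description", "version", "maintainer"),
        ),
    )
}

_INT_FIELDS = {"length", "start", "end", "rank", "position", "cds_frame"}
_REAL_FIELDS = {"quality"}


def sql_type(field_name: str) -> str:
    if field_name in _INT_FIELDS:
        return "INTEGER"
    if field_name in _REAL_FIELDS:
        return "REAL"
    return "TEXT"


def encode_value(schema: KindSchema, field_name: str, value):
    if field_name in schema.json_fields and value is not None:
        return json.dumps(value)
    return value


def decode_value(schema: KindSchema, field_name: str, value):
    if field_name in schema.json_fields and value is not None:
        return json.loads(value)
    return value


@dataclass(frozen=True)
class Violation:
    """One broken integrity rule, naming the offending record."""

    kind: str
    record_id: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = f"{self.kind} {self.record_id}: {self.rule}"
        return f"{s} ({self.detail})" if self.detail else s


def validate_hierarchy(store, genome_name: str) -> list[Violation]:
    """Check every containment/ordering invariant of an imported genome.

    Returns an empty list iff the genome is well-formed.  Each violation
    names the record kind, the record id and the broken rule.  Unknown
    genome names raise :class:`NotFoundError`.
    """
    genomes = list(store.get("Genome", {"id": genome_name}))
    if not genomes:
        raise NotFoundError(f"genome {genome_name!r} not found")

    out: list[Violation] = []
    chroms = {c.name: c for c in store.get("Chromosome", {"genome": genome_name})}
    genes = {g.id: g for g in store.get("Gene", {"genome": genome_name})}

    # Chromosome: stored sequence length must equal the declared length.
    # Checked in SQL so validation does not inflate (and cache) sequences.
    for c in chroms.values():
        if c.length < 0:
            out.append(Violation("Chromosome", c.id, "length must be >= 0"))
        (seq_len,) = store.connection.execute(
            "SELECT length(sequence) FROM chromosomes WHERE id = ?", (c.id,)
        ).fetchone()
        if seq_len != c.length:
            out.append(Violation(
                "Chromosome", c.id, "sequence length != declared length",
                f"sequence {seq_len}, declared {c.length}"))

    for g in genes.values():
        chrom = chroms.get(g.chromosome)
        if chrom is None:
            out.append(Violation("Gene", g.id, "unknown chromosome", g.chromosome))
            continue
        if not (0 <= g.start < g.end <= chrom.length):
            out.append(Violation(
                "Gene", g.id, "interval outside chromosome",
                f"[{g.start},{g.end}) vs length {chrom.length}"))
        if g.strand not in ("+", "-"):
            out.append(Violation("Gene", g.id, "invalid strand", g.strand))

    exons_by_tx: dict[str, list] = {}
    for e in store.get("Exon", {"genome": genome_name}):
        exons_by_tx.setdefault(e.transcript, []).append(e)
        gene = genes.get(e.gene)
        if gene is None:
            out.append(Violation("Exon", e.id, "unknown gene", e.gene))
        elif not (gene.start <= e.start < e.end <= gene.end):
            out.append(Violation(
                "Exon", e.id, "interval outside gene",
                f"[{e.start},{e.end}) vs gene [{gene.start},{gene.end})"))

    transcripts = list(store.get("Transcript", {"genome": genome_name}))
    for t in transcripts:
        exons = sorted(exons_by_tx.get(t.id, []), key=lambda e: e.start)
        if {e.id for e in exons} != set(t.exon_ids):
            out.append(Violation(
                "Transcript", t.id, "exon list mismatch",
                f"store has {len(exons)}, record lists {len(t.exon_ids)}"))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                out.append(Violation(
                    "Transcript", t.id, "overlapping exons", f"{a.id}/{b.id}"))
        for e in exons:
            if e.strand != t.strand:
                out.append(Violation(
                    "Exon", e.id, "strand differs from transcript", e.strand))
        # rank must follow transcription direction
        ranked = sorted(exons, key=lambda e: e.rank)
        genomic = exons if t.strand == "+" else exons[::-1]
        if [e.id for e in ranked] != [e.id for e in genomic]:
            out.append(Violation(
                "Transcript", t.id, "exon rank order violates strand"))
        # every CDS interval inside the exon union
        for (cs, ce) in t.cds_intervals:
            if not any(e.start <= cs and ce <= e.end for e in exons):
                out.append(Violation(
                    "Transcript", t.id, "CDS interval outside exons",
                    f"[{cs},{ce})"))

    tx_by_id = {t.id: t for t in transcripts}
    for p in store.get("Protein", {"genome": genome_name}):
        t = tx_by_id.get(p.transcript)
        if t is None:
            out.append(Violation("Protein", p.id, "unknown transcript", p.transcript))
        elif not t.cds_intervals:
            out.append(Violation("Protein", p.id, "transcript has no CDS"))
    return out
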