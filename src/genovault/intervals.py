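"""Interval indexing over genomic annotations and polymorphisms.

Maps positions/ranges to the annotation records (genes, transcripts,
exons) and variants overlapping them.  The contract is half-open overlap:
an entry ``[s, e)`` matches a query ``[qs, qe)`` iff ``s < qe and qs < e``
— so a point lookup must be phrased as ``[p, p+1)``, and a degenerate
``start == end`` query matches nothing.  Zero-length loci (insertion
anchors) are indexed as ``[pos, pos+1)`` so range queries over exons find
them.

The balanced structure is an interval tree; results are returned sorted
by ``(start, end, id)`` so queries are deterministic.  Duplicated entries
are preserved (multiset semantics).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import CoordinateError, IntervalError, NotFoundError


class IntervalIndex:
    """Queryable set of (start, end, payload-id) intervals."""

    def __init__(self, entries: Iterable[tuple[int, int, object]] = ()):
        self._tree = IntervalTree()
        self._n = 0
        for start, end, payload in entries:
            self.add(start, end, payload)

    def add(self, start: int, end: int, payload) -> None:
        if start < 0:
            raise IntervalError(f"negative interval start {start}")
        if start >= end:
            raise IntervalError(f"empty or inverted interval [{start}, {end})")
        # payload wrapped with an insertion ordinal so duplicates survive
        # the tree's set semantics
        self._tree.addi(start, end, (self._n, payload))
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, start: int, end: int) -> list:
        """Payload ids of entries overlapping [start, end), sorted by
        (start, end, id)."""
        if start < 0 or end < 0:
            raise IntervalError(f"negative query coordinates [{start}, {end})")
        if end < start:
            raise IntervalError(f"inverted query [{start}, {end})")
        if start == end:
            return []
        hits = self._tree.overlap(start, end)
        ordered = sorted(
            hits, key=lambda iv: (iv.begin, iv.end, _sort_key(iv.data[1]))
        )
        return [iv.data[1] for iv in ordered]


def _sort_key(payload):
    return str(payload)


def build_interval_index(
    entries: Sequence[tuple[int, int, object]]
) -> IntervalIndex:
    """Build an index over (start, end, id) entries; duplicates preserved."""
    return IntervalIndex(entries)


def query_overlaps(index: IntervalIndex, start: int, end: int) -> list:
    return index.query(start, end)


def annotation_index(store, genome_name: str, chromosome: str) -> IntervalIndex:
    """Index of (kind, id) payloads for one chromosome's annotations."""
    entries: list[tuple[int, int, object]] = []
    for kind in ("Gene", "Transcript", "Exon"):
        for rec in store.get(kind, {"genome": genome_name, "chromosome": chromosome}):
            entries.append((rec.start, rec.end, (kind, rec.id)))
    return build_interval_index(entries)


def polymorphism_index(store, set_name: str, chromosome: str) -> IntervalIndex:
    """Index of polymorphism record ids for one set on one chromosome.

    Substitutions span ``[pos, pos+1)``, deletions ``[pos, pos+len)``;
    insertion anchors are zero-length loci indexed as ``[pos, pos+1)``.
    """
    entries = []
    for p in store.get(
        "Polymorphism", {"set_name": set_name, "chromosome": chromosome}
    ):
        if p.variant_kind == "deletion":
            span = (p.position, p.position + len(p.ref_allele))
        else:
            span = (p.position, p.position + 1)
        entries.append((*span, p.id))
    return build_interval_index(entries)


def annotate_position(store, genome_name: str, chromosome: str, pos: int):
    """(kind, id) of every gene/transcript/exon whose interval contains pos."""
    chrom = None
    for c in store.get("Chromosome", {"genome": genome_name, "name": chromosome}):
        chrom = c
    if chrom is None:
        raise NotFoundError(
            f"chromosome {chromosome!r} not in genome {genome_name!r}"
        )
    if not 0 <= pos < chrom.length:
        raise CoordinateError(
            f"position {pos} outside chromosome {chromosome!r} "
            f"[0, {chrom.length})"
        )
    return annotation_index(store, genome_name, chromosome).query(pos, pos + 1)
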