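"""Personalized genomes: filter -> insert -> assemble -> translate.

A :class:`PersonalizedGenome` binds a stored reference genome to an
ordered list of polymorphism sets and an *allele filter* — a user-supplied
decision procedure that, for every locus carrying variants, says what to
put there (keep the reference, substitute one base, insert, or delete).
Sequences are produced lazily: constructing the handle loads nothing; the
first access to a personalized protein sequence pulls the transcript, its
exons and the overlapping polymorphisms, applies the filter, splices the
exons and translates.  Several personalized genomes over one reference
share the reference records through the store's singleton cache, so the
chromosome sequence is loaded at most once per session.

Edits are applied in descending genomic position so that coordinate
shifts from indels stay local and earlier coordinates never move; this is
equivalent to editing a position-tagged character list.

The default filter is heterozygosity-preserving: at a substitution locus
it encodes the reference plus all observed alternate alleles as the
minimal IUPAC ambiguity code, so downstream translation yields ``X``
where the haplotypes disagree at the protein level.  Indels are applied
only when marked validated/high-quality (VCF FILTER ``PASS`` or a truthy
``validated`` metadata entry), since an unvalidated frameshift destroys
the whole downstream protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .errors import ConflictError, ConsistencyError, CoordinateError, NotFoundError
from .intervals import polymorphism_index
from .sequence import iupac_code, reverse_complement, translate

logger = logging.getLogger(__name__)

Locus = tuple[str, int]  # (chromosome name, 0-based position)


@dataclass(frozen=True)
class AlleleDecision:
    """What to do at one locus.

    ``substitute``: *sequence* is the single (possibly IUPAC) base to put
    at the position; ``insert``: *sequence* goes immediately after the
    position; ``delete``: *length* reference bases starting at the
    position are removed.  *ref* (when set) is the expected reference
    allele, checked against the genome before applying.
    """

    action: str                       # keep_reference|substitute|insert|delete
    sequence: str = ""
    length: int = 0
    ref: str = ""

    def __post_init__(self):
        if self.action not in ("keep_reference", "substitute", "insert", "delete"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "substitute" and len(self.sequence) != 1:
            raise ValueError("substitute decisions carry exactly one base")
        if self.action == "insert" and len(self.sequence) < 1:
            raise ValueError("insert decisions need a non-empty sequence")
        if self.action == "delete" and self.length < 1:
            raise ValueError("delete decisions need length >= 1")


KEEP_REFERENCE = AlleleDecision("keep_reference")

AlleleFilter = Callable[[Locus, Sequence], AlleleDecision]


def _is_validated(polymorphism) -> bool:
    meta = polymorphism.metadata or {}
    return bool(meta.get("validated")) or meta.get("filter") == "PASS"


def _indel_decision(candidates) -> AlleleDecision | None:
    indels = sorted(
        (c for c in candidates if c.variant_kind in ("insertion", "deletion")),
        key=lambda c: (c.variant_kind, c.id),
    )
    for c in indels:
        if _is_validated(c):
            if c.variant_kind == "insertion":
                return AlleleDecision("insert", sequence=c.alt_allele)
            return AlleleDecision(
                "delete", length=len(c.ref_allele), ref=c.ref_allele
            )
    return None


def het_iupac(locus: Locus, candidates: Sequence) -> AlleleDecision:
    """Default filter: IUPAC-encode substitutions; validated indels only."""
    indel = _indel_decision(candidates)
    if indel is not None:
        return indel
    subs = [c for c in candidates if c.variant_kind == "substitution"]
    if not subs:
        return KEEP_REFERENCE
    ref = subs[0].ref_allele
    bases = {ref} | {c.alt_allele for c in subs}
    code = iupac_code(bases)
    if code == ref:
        return KEEP_REFERENCE
    return AlleleDecision("substitute", sequence=code, ref=ref)


def ref_only(locus: Locus, candidates: Sequence) -> AlleleDecision:
    """Keep the reference everywhere (personalization identity)."""
    return KEEP_REFERENCE


def qual_ge(threshold: float) -> AlleleFilter:
    """Filter factory: consider only variants with quality >= threshold."""

    def _filter(locus: Locus, candidates: Sequence) -> AlleleDecision:
        passing = [
            c for c in candidates
            if c.quality is not None and c.quality >= threshold
        ]
        if not passing:
            return KEEP_REFERENCE
        indel = _first_indel(passing)
        if indel is not None:
            return indel
        subs = [c for c in passing if c.variant_kind == "substitution"]
        if not subs:
            return KEEP_REFERENCE
        ref = subs[0].ref_allele
        code = iupac_code({ref} | {c.alt_allele for c in subs})
        if code == ref:
            return KEEP_REFERENCE
        return AlleleDecision("substitute", sequence=code, ref=ref)

    _filter.__name__ = f"qual_ge_{threshold:g}"
    return _filter


def _first_indel(candidates) -> AlleleDecision | None:
    for c in sorted(
        (c for c in candidates if c.variant_kind in ("insertion", "deletion")),
        key=lambda c: (c.variant_kind, c.id),
    ):
        if c.variant_kind == "insertion":
            return AlleleDecision("insert", sequence=c.alt_allele)
        return AlleleDecision("delete", length=len(c.ref_allele), ref=c.ref_allele)
    return None


def validated_only(locus: Locus, candidates: Sequence) -> AlleleDecision:
    """Apply only variants marked validated (dbSNP-style) or FILTER PASS."""
    passing = [c for c in candidates if _is_validated(c)]
    if not passing:
        return KEEP_REFERENCE
    return het_iupac(locus, passing)


#: Named filters selectable from the CLI; "qual-ge:<N>" is parsed separately.
NAMED_FILTERS: dict[str, AlleleFilter] = {
    "het-iupac": het_iupac,
    "ref-only": ref_only,
    "validated-only": validated_only,
}


def resolve_filter(name: str) -> AlleleFilter:
    if name in NAMED_FILTERS:
        return NAMED_FILTERS[name]
    if name.startswith("qual-ge:"):
        return qual_ge(float(name.split(":", 1)[1]))
    raise NotFoundError(
        f"unknown filter {name!r}; available: "
        f"{sorted(NAMED_FILTERS) + ['qual-ge:<N>']}"
    )


# ---------------------------------------------------------------------------
# the edit engine


def _edit_span(position: int, decision: AlleleDecision):
    """Numeric edited span; insertions are zero-width at position + 1."""
    if decision.action == "substitute":
        return (position, position + 1)
    if decision.action == "delete":
        return (position, position + decision.length)
    return (position + 1, position + 1)


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    if a[0] == a[1]:  # zero-width insertion point
        return b[0] < a[0] < b[1]
    if b[0] == b[1]:
        return a[0] < b[0] < a[1]
    return a[0] < b[1] and b[0] < a[1]


def check_non_overlapping(decisions: Sequence[tuple[int, AlleleDecision]],
                          context: str = "") -> None:
    spans = sorted(
        (( _edit_span(p, d), p) for p, d in decisions), key=lambda x: x[0]
    )
    bad = [
        (pa, pb)
        for ((sa, pa), (sb, pb)) in zip(spans, spans[1:])
        if _spans_overlap(sa, sb)
    ]
    if bad:
        raise ConflictError([p for pair in bad for p in pair], context)


def personalize_region(
    ref_seq: str,
    region_start: int,
    decisions: Sequence[tuple[int, AlleleDecision]],
    clip_policy: str = "clip",
    context: str = "",
) -> str:
    """Apply sorted, non-overlapping decisions to one reference slice.

    Positions are genomic; *region_start* anchors the slice.  Edits are
    applied highest-position first so indel length changes never shift
    pending coordinates.  A deletion running past the region end is
    clipped with a warning (``clip_policy="clip"``) or raises
    (``"strict"``).
    """
    n = len(ref_seq)
    for pos, dec in decisions:
        if not region_start <= pos < region_start + n:
            raise CoordinateError(
                f"decision position {pos} outside region "
                f"[{region_start}, {region_start + n}) {context}"
            )
    check_non_overlapping(decisions, context)
    s = ref_seq
    for pos, dec in sorted(decisions, key=lambda x: x[0], reverse=True):
        rel = pos - region_start
        if dec.action == "keep_reference":
            continue
        if dec.action == "substitute":
            if dec.ref and s[rel] != dec.ref:
                raise ConsistencyError(pos, dec.ref, s[rel], context)
            s = s[:rel] + dec.sequence + s[rel + 1 :]
        elif dec.action == "insert":
            s = s[: rel + 1] + dec.sequence + s[rel + 1 :]
        elif dec.action == "delete":
            end = rel + dec.length
            if end > n:
                if clip_policy == "strict":
                    raise CoordinateError(
                        f"deletion at {pos} (length {dec.length}) runs past "
                        f"region end {region_start + n} {context}"
                    )
                logger.warning(
                    "clipping deletion at %d to region end (%s)", pos, context
                )
                end = n
            if dec.ref:
                expected = dec.ref[: end - rel]
                found = ref_seq[rel:end]
                if found != expected:
                    raise ConsistencyError(pos, expected, found, context)
            s = s[:rel] + s[end:]
    return s


# ---------------------------------------------------------------------------
# the personalized genome


class PersonalizedSequenceView:
    """Fig-1-style handle on one protein: ``.sequence`` computes lazily."""

    __slots__ = ("_pg", "record")

    def __init__(self, pg: "PersonalizedGenome", record):
        self._pg = pg
        self.record = record

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self._pg.protein_sequence(self.record.id)


class PersonalizedGenome:
    """A reference genome overlaid with polymorphism sets and a filter.

    Construction only validates names; no sequence is loaded until a
    personalized sequence is actually requested.  Results are cached per
    handle, keyed by transcript id.
    """

    def __init__(
        self,
        store,
        reference: str,
        polymorphism_sets: Sequence[str] = (),
        allele_filter: AlleleFilter = het_iupac,
        clip_policy: str = "clip",
    ):
        self.store = store
        self.reference = store.get_one("Genome", reference).id
        for name in polymorphism_sets:
            store.get_one("SnpSet", name)
        self.polymorphism_sets = list(polymorphism_sets)
        self.allele_filter = allele_filter
        self.clip_policy = clip_policy
        self._seq_cache: dict[tuple[str, str], str] = {}
        self._protein_cache: dict[str, str] = {}
        self._poly_indexes: dict[tuple[str, str], object] = {}
        #: times the allele filter was invoked (one call per locus)
        self.filter_calls = 0

    # -- store passthrough -------------------------------------------------

    def get(self, kind: str, filters=None, **kw):
        """Query the underlying store, scoped to this genome where the
        kind carries a ``genome`` field."""
        from .model import KINDS

        spec = dict(filters or {})
        spec.update(kw)
        if "genome" in KINDS[kind].fields:
            spec.setdefault("genome", self.reference)
        return self.store.get(kind, spec)

    def protein(self, protein_id: str) -> PersonalizedSequenceView:
        return PersonalizedSequenceView(
            self, self.store.get_one("Protein", protein_id)
        )

    # -- variant collection ------------------------------------------------

    def _index_for(self, set_name: str, chromosome: str):
        key = (set_name, chromosome)
        if key not in self._poly_indexes:
            self._poly_indexes[key] = polymorphism_index(
                self.store, set_name, chromosome
            )
        return self._poly_indexes[key]

    def collect_locus_decisions(
        self, chromosome: str, interval: tuple[int, int]
    ) -> list[tuple[int, AlleleDecision]]:
        """Filter decisions for every variant locus in [start, end).

        Polymorphisms from all sets are grouped by locus and offered to
        the filter once per locus, in set order.  ``keep_reference``
        decisions are dropped; retained decisions are clipped to the
        interval, sorted by position and checked for overlap conflicts.
        An insertion anchored on the interval's half-open end coordinate
        belongs downstream and is excluded.
        """
        start, end = interval
        by_locus: dict[int, list] = {}
        for set_name in self.polymorphism_sets:
            index = self._index_for(set_name, chromosome)
            for pid in index.query(start, end):
                p = self.store.get_one("Polymorphism", pid)
                if p.variant_kind == "insertion" and p.position >= end - 1:
                    continue  # boundary rule: belongs to the next interval
                by_locus.setdefault(p.position, []).append(p)

        decisions: list[tuple[int, AlleleDecision]] = []
        for pos in sorted(by_locus):
            candidates = by_locus[pos]
            self.filter_calls += 1
            decision = self.allele_filter((chromosome, pos), candidates)
            if decision.action == "keep_reference":
                continue
            pos2, decision = self._clip(pos, decision, start, end)
            if decision is not None:
                decisions.append((pos2, decision))
        check_non_overlapping(decisions, f"chromosome {chromosome}")
        return decisions

    def _clip(self, pos: int, decision: AlleleDecision, start: int, end: int):
        """Clip a decision to [start, end) per clip_policy."""
        if decision.action == "delete":
            dstart, dend = pos, pos + decision.length
            cstart, cend = max(dstart, start), min(dend, end)
            if (cstart, cend) != (dstart, dend):
                if self.clip_policy == "strict":
                    raise CoordinateError(
                        f"deletion at {pos} crosses interval [{start}, {end})"
                    )
                logger.warning(
                    "clipping deletion at %d to interval [%d, %d)", pos, start, end
                )
                if cstart >= cend:
                    return pos, None
                offset = cstart - dstart
                return cstart, AlleleDecision(
                    "delete",
                    length=cend - cstart,
                    ref=decision.ref[offset : offset + cend - cstart]
                    if decision.ref
                    else "",
                )
        return pos, decision

    # -- sequence assembly ---------------------------------------------------

    def _chromosome_sequence(self, chromosome: str) -> str:
        chrom = None
        for c in self.store.get(
            "Chromosome", {"genome": self.reference, "name": chromosome}
        ):
            chrom = c
        if chrom is None:
            raise NotFoundError(
                f"chromosome {chromosome!r} not in genome {self.reference!r}"
            )
        return chrom.sequence  # heavy field; singleton cache makes this shared

    def transcript_sequence(self, transcript_id: str, which: str = "full") -> str:
        """Personalized spliced sequence of one transcript.

        ``which="full"`` assembles the exons, ``"cds"`` the coding
        intervals (with the annotated frame offset trimmed).  Intervals
        are personalized independently, concatenated in genomic order and
        reverse-complemented for minus-strand genes.
        """
        if which not in ("full", "cds"):
            raise ValueError(f"unknown sequence kind {which!r}")
        key = (transcript_id, which)
        if key in self._seq_cache:
            return self._seq_cache[key]

        t = self.store.get_one("Transcript", transcript_id)
        if which == "full":
            exons = sorted(
                self.store.get("Exon", {"transcript": transcript_id}),
                key=lambda e: e.start,
            )
            intervals = [(e.start, e.end) for e in exons]
        else:
            intervals = [tuple(iv) for iv in t.cds_intervals]

        chrom_seq = self._chromosome_sequence(t.chromosome)
        parts = []
        try:
            for (s, e) in intervals:
                decisions = self.collect_locus_decisions(t.chromosome, (s, e))
                parts.append(
                    personalize_region(
                        chrom_seq[s:e], s, decisions,
                        clip_policy=self.clip_policy,
                        context=f"transcript {transcript_id}",
                    )
                )
        except (ConflictError, ConsistencyError) as e:
            e.args = (f"{e.args[0]} [transcript {transcript_id}]",) + e.args[1:]
            raise
        seq = "".join(parts)
        if t.strand == "-":
            seq = reverse_complement(seq)
        if which == "cds" and t.cds_frame:
            seq = seq[t.cds_frame :]
        self._seq_cache[key] = seq
        return seq

    def protein_sequence(self, protein_id: str) -> str:
        """Personalized protein: translate the personalized CDS."""
        if protein_id in self._protein_cache:
            return self._protein_cache[protein_id]
        p = self.store.get_one("Protein", protein_id)
        t = self.store.get_one("Transcript", p.transcript)
        if not t.cds_intervals:
            logger.warning(
                "transcript %s has no CDS; empty protein %s", t.id, protein_id
            )
            seq = ""
        else:
            seq = translate(
                self.transcript_sequence(t.id, "cds"), "truncate_at_stop"
            )
        self._protein_cache[protein_id] = seq
        return seq

    # -- export -------------------------------------------------------------

    def export_fasta(self, ids: Iterable[str], kind: str = "protein") -> str:
        """FASTA text of personalized sequences, records sorted by id.

        Header: ``<id>|<genome>|<comma-joined set names>``.
        """
        from .parsers import write_fasta

        sets = ",".join(self.polymorphism_sets)
        records = []
        for rid in sorted(set(ids)):
            if kind == "protein":
                seq = self.protein_sequence(rid)
            elif kind in ("transcript", "cds"):
                seq = self.transcript_sequence(
                    rid, "full" if kind == "transcript" else "cds"
                )
            else:
                raise ValueError(f"unknown export kind {kind!r}")
            records.append((f"{rid}|{self.reference}|{sets}", seq))
        return write_fasta(records)
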