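"""Deterministic synthetic datawraps with planted, known-answer truth.

Generates toy reference-genome datawraps (FASTA + GTF + manifest.ini) and
polymorphism-set datawraps (VCF + manifest.ini) whose every planted fact
— gene/transcript/exon coordinates, reference sequences, and the
personalized cDNA/protein expected under the default allele filter — is
recorded in a *ledger* computed by a naive oracle that shares no code
with the import/personalization pipeline: sequence arithmetic goes
through Biopython (``Bio.Seq``, ``Bio.Data.IUPACData``) and variant
application through a position-tagged character list.  Comparing pipeline
output against the ledger is therefore an independent end-to-end check,
not a tautology.

Same seed, same spec -> byte-identical files.  The toy genomes emulate
Ensembl-style nuclear gene annotation (multi-exon, both strands,
contiguous CDS blocks, frame 0); they do not emulate realistic base
composition, intron length distributions, UTR structure beyond simple
flanks, or population allele frequencies.
"""

from __future__ import annotations

import itertools
import random
import tarfile
from dataclasses import dataclass
from pathlib import Path

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import FixtureSpecError

# ---------------------------------------------------------------------------
# independent oracle primitives (Biopython-backed; no package sequence code)

_IUPAC_FOR_SET = {
    frozenset(bases): code
    for code, bases in ambiguous_dna_values.items()
    if code != "X"
}


def oracle_revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def oracle_iupac(bases) -> str:
    return _IUPAC_FOR_SET[frozenset(bases)]


def oracle_translate(cds: str) -> str:
    """Codon-wise translation, expansions-agree rule, truncate at stop."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        expansions = itertools.product(*(ambiguous_dna_values[c] for c in codon))
        aas = {str(Seq("".join(e)).translate()) for e in expansions}
        aa = aas.pop() if len(aas) == 1 else "X"
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def tagged_list_edit(ref_seq: str, region_start: int, edits) -> str:
    """Brute-force editor on a position-tagged character list.

    *edits* is a list of ``(pos, action, payload)`` where action is
    ``substitute`` (payload: one base), ``insert`` (payload: string,
    goes after pos) or ``delete`` (payload: length).  Order of the edit
    list is irrelevant: tags, not offsets, locate the edits.
    """
    tagged: list[list] = [
        [region_start + i, c] for i, c in enumerate(ref_seq)
    ]
    for pos, action, payload in edits:
        if action == "substitute":
            for cell in tagged:
                if cell[0] == pos:
                    cell[1] = payload
                    break
            else:
                raise ValueError(f"substitute position {pos} not in region")
        elif action == "delete":
            doomed = set(range(pos, pos + payload))
            tagged = [cell for cell in tagged if cell[0] not in doomed]
        elif action == "insert":
            for i, cell in enumerate(tagged):
                if cell[0] == pos:
                    tagged[i + 1 : i + 1] = [[None, c] for c in payload]
                    break
            else:
                raise ValueError(f"insert anchor {pos} not in region")
        else:
            raise ValueError(f"unknown action {action!r}")
    return "".join(cell[1] for cell in tagged)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a toy genome datawrap.

    ``transcripts_per_gene`` and ``exons_per_transcript`` are cycled over
    genes/transcripts in order, so record counts are fixed by the spec,
    not sampled; the seed randomizes sequence content and coordinates
    only.  Defaults: one 10 kb chromosome, 2 genes (one per strand),
    3 transcripts, 7 exons.
    """

    seed: int = 42
    name: str = "toy-genome"
    species: str = "toyus exemplaris"
    n_chromosomes: int = 1
    chromosome_length: int = 10_000
    n_genes: int = 2
    transcripts_per_gene: tuple[int, ...] = (2, 1)
    exons_per_transcript: tuple[int, ...] = (2, 3, 2)
    strands: tuple[str, ...] = ("+", "-")
    exon_length: tuple[int, int] = (60, 150)
    intron_length: tuple[int, int] = (30, 80)


@dataclass(frozen=True)
class VariantSpec:
    """Shape of a toy polymorphism-set datawrap.

    Defaults plant 5 VCF lines — 2 simple substitutions (one of them
    low-quality), 1 multi-allelic substitution with two alternates, 1
    insertion and 1 deletion — all inside coding sequence, away from
    interval boundaries, with pairwise non-overlapping edit spans.
    """

    seed: int = 7
    name: str = "toy-snps"
    n_substitutions: int = 2
    n_multi_allelic: int = 1
    n_insertions: int = 1
    n_deletions: int = 1
    insertion_length: int = 2
    deletion_length: int = 3
    n_low_quality: int = 1
    low_quality: float = 10.0
    quality_range: tuple[float, float] = (30.0, 60.0)
    cds_fraction: float = 1.0


@dataclass
class TranscriptTruth:
    gene: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein_id: str
    sequence: str = ""
    cds_sequence: str = ""
    protein: str = ""


@dataclass
class GenomeLedger:
    """Planted ground truth for one generated genome datawrap."""

    spec: FixtureSpec
    name: str
    chromosomes: dict[str, str]
    genes: dict[str, dict]
    transcripts: dict[str, TranscriptTruth]
    path: Path

    def intergenic_position(self) -> int:
        """A position on the first chromosome covered by no gene."""
        chrom = sorted(self.chromosomes)[0]
        covered = sorted(
            (g["start"], g["end"]) for g in self.genes.values()
            if g["chromosome"] == chrom
        )
        pos = 0
        for (s, e) in covered:
            if pos < s:
                return pos
            pos = max(pos, e)
        if pos < len(self.chromosomes[chrom]):
            return pos
        raise FixtureSpecError("no intergenic gap on first chromosome")


@dataclass
class PlantedVariant:
    chromosome: str
    position: int                  # internal 0-based (insertion: anchor base)
    kind: str                      # substitution | insertion | deletion
    ref: str
    alts: list[str]
    quality: float
    filter: str

    @property
    def span(self) -> tuple[int, int]:
        if self.kind == "deletion":
            return (self.position, self.position + len(self.ref))
        if self.kind == "insertion":
            return (self.position + 1, self.position + 1)
        return (self.position, self.position + 1)


@dataclass
class VariantLedger:
    """Planted variants plus expected personalized sequences.

    ``expected`` maps transcript id -> dict with keys ``cdna``, ``cds``
    and ``protein``: the sequences the default (heterozygosity-
    preserving) filter must produce, computed with the tagged-list
    editor and Biopython translation.
    """

    spec: VariantSpec
    name: str
    variants: list[PlantedVariant]
    expected: dict[str, dict]
    path: Path


# ---------------------------------------------------------------------------
# genome generation


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def generate_genome_datawrap(
    spec: FixtureSpec, out_path: str | Path
) -> tuple[Path, GenomeLedger]:
    """Write a genome datawrap directory; return its path and ledger."""
    rng = random.Random(spec.seed)
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)

    margin = 200
    slot = (spec.chromosome_length - 2 * margin) // max(spec.n_genes, 1)
    max_exons = max(spec.exons_per_transcript)
    worst = (
        max_exons * spec.exon_length[1]
        + (max_exons - 1) * spec.intron_length[1]
        + 60  # transcript-start jitter and CDS margins
    )
    if worst > slot:
        raise FixtureSpecError(
            f"genes do not fit: a transcript may need {worst} bp but each "
            f"gene slot is {slot} bp; shrink exons_per_transcript or grow "
            f"the chromosome"
        )

    chromosomes = {
        str(i + 1): _rand_seq(rng, spec.chromosome_length)
        for i in range(spec.n_chromosomes)
    }

    genes: dict[str, dict] = {}
    transcripts: dict[str, TranscriptTruth] = {}
    tpg = itertools.cycle(spec.transcripts_per_gene)
    ept = itertools.cycle(spec.exons_per_transcript)
    chrom_cycle = itertools.cycle(sorted(chromosomes))

    for gi in range(spec.n_genes):
        chrom = next(chrom_cycle)
        gid = f"GENE{gi + 1:03d}"
        strand = spec.strands[gi % len(spec.strands)]
        slot_start = margin + (gi // spec.n_chromosomes) * slot
        n_tx = next(tpg)
        tx_ids = []
        for ti in range(n_tx):
            tid = f"TX{gi + 1:03d}.{ti + 1}"
            n_ex = next(ept)
            start = slot_start + rng.randint(0, 40)
            exons = []
            pos = start
            for _ in range(n_ex):
                length = rng.randint(*spec.exon_length)
                exons.append((pos, pos + length))
                pos += length + rng.randint(*spec.intron_length)
            cds = _choose_cds(rng, exons)
            transcripts[tid] = TranscriptTruth(
                gene=gid, chromosome=chrom, strand=strand,
                exons=exons, cds=cds, protein_id=f"{tid}_prot",
            )
            tx_ids.append(tid)
        g_start = min(transcripts[t].exons[0][0] for t in tx_ids)
        g_end = max(transcripts[t].exons[-1][1] for t in tx_ids)
        genes[gid] = {
            "id": gid, "name": f"Toy{gi + 1}", "chromosome": chrom,
            "start": g_start, "end": g_end, "strand": strand,
        }

    _purge_internal_stops(chromosomes, transcripts)

    # reference sequences via the oracle
    for tid, t in transcripts.items():
        t.sequence = _oracle_assemble(chromosomes[t.chromosome], t.exons, t.strand)
        t.cds_sequence = _oracle_assemble(chromosomes[t.chromosome], t.cds, t.strand)
        t.protein = oracle_translate(t.cds_sequence)

    _write_genome_files(spec, out, chromosomes, genes, transcripts)
    ledger = GenomeLedger(
        spec=spec, name=spec.name, chromosomes=chromosomes,
        genes=genes, transcripts=transcripts, path=out,
    )
    return out, ledger


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}


def _purge_internal_stops(chromosomes: dict[str, str], transcripts) -> None:
    """Rewrite chromosome bases so no CDS contains an in-frame stop codon.

    Real coding sequences are stop-free until their terminator; random
    sequence is not, and an early stop would hide every downstream
    planted variant from the protein.  Whenever a stop codon appears in
    any transcript's reading frame, its wobble position is set to C
    (complement G on the minus strand) — no stop codon contains a C, so
    the rewrite converges even for transcripts sharing sequence in
    different frames.
    """
    seqs = {c: list(s) for c, s in chromosomes.items()}
    for _ in range(10):
        dirty = False
        for t in transcripts.values():
            seq = seqs[t.chromosome]
            pos = [p for (s, e) in sorted(t.cds) for p in range(s, e)]
            if t.strand == "-":
                pos.reverse()
            for i in range(0, len(pos) - len(pos) % 3, 3):
                triple = pos[i : i + 3]
                codon = "".join(seq[p] for p in triple)
                if t.strand == "-":
                    codon = codon.translate(_COMPLEMENT)
                if codon in _STOPS:
                    seq[triple[2]] = "C" if t.strand == "+" else "G"
                    dirty = True
        if not dirty:
            break
    else:  # pragma: no cover - C-rewrite converges by construction
        raise FixtureSpecError("could not purge internal stop codons")
    for c in chromosomes:
        chromosomes[c] = "".join(seqs[c])


def _choose_cds(rng: random.Random, exons) -> list[tuple[int, int]]:
    """Contiguous CDS block: first-exon offset to last-exon offset, length
    trimmed to a codon multiple."""
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    cds_start = first_s + rng.randint(6, min(20, first_e - first_s - 10))
    cds_end = last_e - rng.randint(6, min(20, last_e - last_s - 10))
    intervals = []
    for (s, e) in exons:
        cs, ce = max(s, cds_start), min(e, cds_end)
        if cs < ce:
            intervals.append((cs, ce))
    total = sum(e - s for (s, e) in intervals)
    trim = total % 3
    if trim:
        s, e = intervals[-1]
        intervals[-1] = (s, e - trim)
    return intervals


def _oracle_assemble(chrom_seq: str, intervals, strand: str) -> str:
    seq = "".join(chrom_seq[s:e] for (s, e) in sorted(intervals))
    return oracle_revcomp(seq) if strand == "-" else seq


def _write_genome_files(spec, out: Path, chromosomes, genes, transcripts):
    fasta_lines = []
    for cname in sorted(chromosomes):
        fasta_lines.append(f">chr{cname}")
        seq = chromosomes[cname]
        fasta_lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    (out / "genome.fa").write_text("\n".join(fasta_lines) + "\n")

    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        rows.append(_gtf_row(g["chromosome"], "gene", g["start"], g["end"],
                             g["strand"], f'gene_id "{gid}"; gene_name "{g["name"]}";'))
        for tid in sorted(t for t, tt in transcripts.items() if tt.gene == gid):
            t = transcripts[tid]
            rows.append(_gtf_row(
                t.chromosome, "transcript", t.exons[0][0], t.exons[-1][1],
                t.strand,
                f'gene_id "{gid}"; transcript_id "{tid}"; '
                f'protein_id "{t.protein_id}";'))
            ordered = t.exons if t.strand == "+" else t.exons[::-1]
            for rank, (s, e) in enumerate(ordered, 1):
                rows.append(_gtf_row(
                    t.chromosome, "exon", s, e, t.strand,
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'exon_number "{rank}"; exon_id "{tid}.e{rank}";'))
            for (s, e) in t.cds:
                rows.append(_gtf_row(
                    t.chromosome, "CDS", s, e, t.strand,
                    f'gene_id "{gid}"; transcript_id "{tid}";'))
    (out / "annotation.gtf").write_text(
        "#!genome-build toy\n" + "\n".join(rows) + "\n"
    )

    (out / "manifest.ini").write_text(
        "[package]\n"
        f"description = synthetic toy genome (seed {spec.seed})\n"
        "version = 1.0\n"
        "maintainer = fixtures\n"
        "\n[genome]\n"
        f"name = {spec.name}\n"
        f"species = {spec.species}\n"
        "\n[files]\n"
        "fasta = genome.fa\n"
        "gtf = annotation.gtf\n"
    )


def _gtf_row(chrom, feature, start, end, strand, attrs) -> str:
    # internal half-open -> 1-based inclusive; frame always 0 for CDS
    frame = "0" if feature == "CDS" else "."
    return "\t".join(
        (f"chr{chrom}", "fixtures", feature, str(start + 1), str(end), ".",
         strand, frame, attrs)
    )


# ---------------------------------------------------------------------------
# variant generation


def generate_variant_datawrap(
    spec: VariantSpec, genome_ledger: GenomeLedger, out_path: str | Path
) -> tuple[Path, VariantLedger]:
    """Write a VCF datawrap with planted in-CDS variants plus the expected
    personalized sequences of every transcript under the default filter."""
    rng = random.Random(spec.seed)
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)

    sites = _pick_sites(rng, spec, genome_ledger)
    variants = _plant_variants(rng, spec, genome_ledger, sites)
    expected = {
        tid: _expected_sequences(genome_ledger, tid, variants)
        for tid in genome_ledger.transcripts
    }
    _write_variant_files(spec, out, variants, genome_ledger.chromosomes)
    ledger = VariantLedger(
        spec=spec, name=spec.name, variants=variants,
        expected=expected, path=out,
    )
    return out, ledger


def _pick_sites(rng, spec: VariantSpec, gl: GenomeLedger) -> list[tuple[str, int]]:
    """Non-overlapping in-CDS anchor positions with boundary margins.

    Sites are allocated round-robin over the transcripts so every
    transcript — in particular the minus-strand one — receives planted
    variants whenever there are at least as many sites as transcripts.
    """
    n_needed = (
        spec.n_substitutions + spec.n_multi_allelic + spec.n_insertions
        + spec.n_deletions
    )
    margin = 5
    pad = max(spec.deletion_length, spec.insertion_length) + 2
    per_tx: list[list[tuple[str, int, int]]] = []
    for _, t in sorted(gl.transcripts.items()):
        windows = [
            (t.chromosome, s + margin, e - margin - pad)
            for (s, e) in t.cds
            if e - s > 2 * margin + pad
        ]
        if windows:
            per_tx.append(windows)
    if not per_tx:
        raise FixtureSpecError("no CDS interval is wide enough for variants")
    taken: list[tuple[str, int, int]] = []
    sites: list[tuple[str, int]] = []
    attempts = 0
    k = 0
    while len(sites) < n_needed:
        attempts += 1
        if attempts > 10_000:
            raise FixtureSpecError(
                f"could not place {n_needed} non-overlapping in-CDS variants"
            )
        windows = per_tx[k % len(per_tx)]
        chrom, lo, hi = windows[rng.randrange(len(windows))]
        pos = rng.randint(lo, hi)
        span = (pos - pad, pos + pad)
        if any(c == chrom and span[0] < e and s < span[1] for (c, s, e) in taken):
            continue
        taken.append((chrom, *span))
        sites.append((chrom, pos))
        k += 1
    return sites


def _plant_variants(rng, spec: VariantSpec, gl: GenomeLedger, sites):
    variants: list[PlantedVariant] = []
    queue = list(sites)

    def qual() -> float:
        return round(rng.uniform(*spec.quality_range), 1)

    def other_bases(ref: str, k: int) -> list[str]:
        return rng.sample([b for b in "ACGT" if b != ref], k)

    n_plain = spec.n_substitutions
    for i in range(n_plain):
        chrom, pos = queue.pop(0)
        ref = gl.chromosomes[chrom][pos]
        low = i < spec.n_low_quality
        variants.append(PlantedVariant(
            chromosome=chrom, position=pos, kind="substitution",
            ref=ref, alts=other_bases(ref, 1),
            quality=spec.low_quality if low else qual(),
            filter="q10" if low else "PASS",
        ))
    for _ in range(spec.n_multi_allelic):
        chrom, pos = queue.pop(0)
        ref = gl.chromosomes[chrom][pos]
        variants.append(PlantedVariant(
            chromosome=chrom, position=pos, kind="substitution",
            ref=ref, alts=sorted(other_bases(ref, 2)),
            quality=qual(), filter="PASS",
        ))
    for _ in range(spec.n_insertions):
        chrom, pos = queue.pop(0)
        variants.append(PlantedVariant(
            chromosome=chrom, position=pos, kind="insertion",
            ref="", alts=[_rand_seq(rng, spec.insertion_length)],
            quality=qual(), filter="PASS",
        ))
    for _ in range(spec.n_deletions):
        chrom, pos = queue.pop(0)
        ref = gl.chromosomes[chrom][pos : pos + spec.deletion_length]
        variants.append(PlantedVariant(
            chromosome=chrom, position=pos, kind="deletion",
            ref=ref, alts=[], quality=qual(), filter="PASS",
        ))
    variants.sort(key=lambda v: (v.chromosome, v.position, v.kind))
    return variants


# the default-filter rule, restated independently for the ledger:
# substitutions -> IUPAC over ref+alts; indels -> applied iff FILTER PASS


def _expected_sequences(gl: GenomeLedger, tid: str, variants) -> dict:
    t = gl.transcripts[tid]
    chrom_seq = gl.chromosomes[t.chromosome]

    def personalize(intervals) -> str:
        parts = []
        for (s, e) in sorted(intervals):
            edits = []
            for v in variants:
                if v.chromosome != t.chromosome:
                    continue
                if v.kind == "substitution" and s <= v.position < e:
                    code = oracle_iupac({v.ref, *v.alts})
                    if code != v.ref:
                        edits.append((v.position, "substitute", code))
                elif v.kind == "insertion" and s <= v.position < e - 1:
                    if v.filter == "PASS":
                        edits.append((v.position, "insert", v.alts[0]))
                elif v.kind == "deletion":
                    ds, de = v.position, v.position + len(v.ref)
                    cs, ce = max(ds, s), min(de, e)
                    if cs < ce and v.filter == "PASS":
                        edits.append((cs, "delete", ce - cs))
            parts.append(tagged_list_edit(chrom_seq[s:e], s, edits))
        seq = "".join(parts)
        return oracle_revcomp(seq) if t.strand == "-" else seq

    cdna = personalize(t.exons)
    cds = personalize(t.cds)
    return {"cdna": cdna, "cds": cds, "protein": oracle_translate(cds)}


def _write_variant_files(
    spec: VariantSpec, out: Path, variants, chromosomes
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, v in enumerate(variants, 1):
        lines.append(_vcf_line(i, v, chromosomes))
    (out / "variants.vcf").write_text("\n".join(lines) + "\n")

    (out / "manifest.ini").write_text(
        "[package]\n"
        f"description = synthetic toy polymorphisms (seed {spec.seed})\n"
        "version = 1.0\n"
        "maintainer = fixtures\n"
        "\n[snps]\n"
        f"name = {spec.name}\n"
        "species = toyus exemplaris\n"
        "\n[files]\n"
        "snp = variants.vcf\n"
    )


def _vcf_line(i: int, v: PlantedVariant, chromosomes) -> str:
    # back-convert to 1-based VCF, restoring anchor bases for indels
    chrom_seq = chromosomes[v.chromosome]
    if v.kind == "substitution":
        pos1, ref, alts = v.position + 1, v.ref, v.alts
    elif v.kind == "insertion":
        # inserted after internal position p: the anchor base is at p
        anchor = chrom_seq[v.position]
        pos1, ref, alts = v.position + 1, anchor, [anchor + v.alts[0]]
    else:  # deletion: the anchor base precedes the deleted run
        anchor = chrom_seq[v.position - 1]
        pos1, ref, alts = v.position, anchor + v.ref, [anchor]
    return "\t".join(
        (f"chr{v.chromosome}", str(pos1), f"var{i:03d}", ref,
         ",".join(alts), f"{v.quality:g}", v.filter, f"KIND={v.kind}")
    )


# ---------------------------------------------------------------------------
# archiving + bundled registry


def make_archive(datawrap_dir: str | Path, tar_path: str | Path) -> Path:
    """Pack a datawrap directory into a tar.gz archive."""
    datawrap_dir = Path(datawrap_dir)
    tar_path = Path(tar_path)
    with tarfile.open(tar_path, "w:gz") as tar:
        for p in sorted(datawrap_dir.iterdir()):
            tar.add(p, arcname=p.name)
    return tar_path


BUNDLED: dict[str, FixtureSpec | VariantSpec] = {
    "toy-genome": FixtureSpec(),
    "toy-snps": VariantSpec(),
}
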