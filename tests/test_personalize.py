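"""The personalization engine: filters, edits, assembly, translation."""

import random
import shutil

import pytest

from genovault.errors import (
    ConflictError,
    ConsistencyError,
    CoordinateError,
    NotFoundError,
)
from genovault.fixtures import tagged_list_edit
from genovault.importers import import_genome, import_polymorphisms
from genovault.personalize import (
    AlleleDecision,
    PersonalizedGenome,
    personalize_region,
    qual_ge,
    ref_only,
    resolve_filter,
)
from genovault.sequence import reverse_complement
from genovault.store import Store


def sub(base, ref=""):
    return AlleleDecision("substitute", sequence=base, ref=ref)


def ins(seq):
    return AlleleDecision("insert", sequence=seq)


def dele(n, ref=""):
    return AlleleDecision("delete", length=n, ref=ref)


class TestAlleleDecision:
    def test_action_validation(self):
        with pytest.raises(ValueError):
            AlleleDecision("transmogrify")
        with pytest.raises(ValueError):
            AlleleDecision("substitute", sequence="AC")
        with pytest.raises(ValueError):
            AlleleDecision("insert", sequence="")
        with pytest.raises(ValueError):
            AlleleDecision("delete", length=0)


class TestPersonalizeRegion:
    def test_single_substitution(self):
        assert personalize_region("ATGCCC", 0, [(3, sub("G"))]) == "ATGGCC"

    def test_insertion_after_anchor(self):
        got = personalize_region("ATGCCC", 0, [(2, ins("TT"))])
        assert got == "ATGTTCCC"
        assert got == tagged_list_edit("ATGCCC", 0, [(2, "insert", "TT")])

    def test_deletion_plus_substitution(self):
        decisions = [(1, dele(2)), (4, sub("A"))]
        got = personalize_region("ATGCCC", 0, decisions)
        oracle = tagged_list_edit(
            "ATGCCC", 0, [(1, "delete", 2), (4, "substitute", "A")]
        )
        assert got == oracle == "ACAC"

    def test_region_start_offsets_positions(self):
        assert personalize_region("ATGCCC", 100, [(103, sub("G"))]) == "ATGGCC"

    def test_reference_mismatch_is_reported(self):
        with pytest.raises(ConsistencyError, match="expected 'G', found 'C'"):
            personalize_region("ATGCCC", 0, [(3, sub("A", ref="G"))])

    def test_position_outside_region(self):
        with pytest.raises(CoordinateError):
            personalize_region("ATGCCC", 0, [(6, sub("A"))])

    def test_overlapping_edits_conflict(self):
        with pytest.raises(ConflictError):
            personalize_region("ATGCCC", 0, [(1, dele(3)), (2, sub("A"))])

    def test_insertion_inside_deletion_conflicts(self):
        with pytest.raises(ConflictError):
            personalize_region("ATGCCC", 0, [(1, dele(3)), (1, ins("GG"))])

    def test_deletion_past_region_end_clips_or_raises(self, caplog):
        with caplog.at_level("WARNING"):
            got = personalize_region("ATGCCC", 0, [(4, dele(5))])
        assert got == "ATGC"
        assert any("clipping" in r.message for r in caplog.records)
        with pytest.raises(CoordinateError):
            personalize_region("ATGCCC", 0, [(4, dele(5))], clip_policy="strict")

    @pytest.mark.parametrize("seed", range(3))
    def test_random_edit_sets_match_tagged_list_oracle(self, seed):
        rng = random.Random(seed)
        for _ in range(200):
            n = rng.randint(50, 300)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            start = rng.randint(0, 1000)
            decisions, oracle_edits = _random_edits(rng, seq, start)
            assert personalize_region(seq, start, decisions) == \
                tagged_list_edit(seq, start, oracle_edits)

    def test_length_conservation(self):
        rng = random.Random(9)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        decisions, _ = _random_edits(rng, seq, 0)
        got = personalize_region(seq, 0, decisions)
        delta = sum(
            len(d.sequence) if d.action == "insert"
            else -d.length if d.action == "delete" else 0
            for _, d in decisions
        )
        assert len(got) - len(seq) == delta


def _random_edits(rng, seq, start):
    """Non-overlapping random edits, in both engine and oracle form."""
    n = len(seq)
    decisions, oracle = [], []
    pos = 0
    while pos < n - 6:
        pos += rng.randint(1, 25)
        if pos >= n - 6:
            break
        kind = rng.choice(["substitute", "insert", "delete", "none"])
        gpos = start + pos
        if kind == "substitute":
            base = rng.choice("ACGT")
            decisions.append((gpos, sub(base, ref=seq[pos])))
            oracle.append((gpos, "substitute", base))
        elif kind == "insert":
            piece = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            decisions.append((gpos, ins(piece)))
            oracle.append((gpos, "insert", piece))
        elif kind == "delete":
            length = rng.randint(1, 4)
            decisions.append((gpos, dele(length, ref=seq[pos : pos + length])))
            oracle.append((gpos, "delete", length))
            pos += length
        pos += 1  # keep a gap so spans never touch
    return decisions, oracle


def test_substitution_commutes_with_reverse_complement():
    """Editing then reverse-complementing equals mirror-editing the
    reverse complement."""
    rng = random.Random(5)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for _ in range(50):
        n = rng.randint(20, 80)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        pos, base = rng.randrange(n), rng.choice("ACGT")
        a = reverse_complement(personalize_region(seq, 0, [(pos, sub(base))]))
        b = personalize_region(
            reverse_complement(seq), 0, [(n - 1 - pos, sub(comp[base]))]
        )
        assert a == b


class TestPersonalizedGenome:
    def test_unknown_reference_or_set(self, populated_store):
        with pytest.raises(NotFoundError):
            PersonalizedGenome(populated_store, "nope", [])
        with pytest.raises(NotFoundError):
            PersonalizedGenome(populated_store, "toy-genome", ["nope"])

    def test_empty_sets_reproduce_reference(self, populated_store, genome_fixture):
        _, ledger = genome_fixture
        pg = PersonalizedGenome(populated_store, "toy-genome", [])
        for tid, t in ledger.transcripts.items():
            assert pg.transcript_sequence(tid, "full") == t.sequence
            assert pg.transcript_sequence(tid, "cds") == t.cds_sequence
            assert pg.protein_sequence(t.protein_id) == t.protein

    def test_ref_only_filter_reproduces_reference(
        self, populated_store, genome_fixture
    ):
        _, ledger = genome_fixture
        pg = PersonalizedGenome(
            populated_store, "toy-genome", ["toy-snps"], ref_only
        )
        for tid, t in ledger.transcripts.items():
            assert pg.protein_sequence(t.protein_id) == t.protein

    def test_quality_filter_drops_low_quality_snp(
        self, populated_store, variant_fixture
    ):
        _, vledger = variant_fixture
        low = next(v for v in vledger.variants if v.quality < 20)
        passing = next(
            v for v in vledger.variants
            if v.quality >= 20 and v.kind == "substitution"
        )
        pg = PersonalizedGenome(
            populated_store, "toy-genome", ["toy-snps"], qual_ge(20)
        )
        assert pg.collect_locus_decisions(
            low.chromosome, (low.position - 1, low.position + 2)
        ) == []
        assert len(pg.collect_locus_decisions(
            passing.chromosome, (passing.position - 1, passing.position + 2)
        )) == 1

    def test_locus_in_two_sets_filtered_once_with_both(
        self, populated_store, variant_fixture, tmp_path
    ):
        wrap = tmp_path / "again"
        shutil.copytree(variant_fixture[0], wrap)
        manifest = (wrap / "manifest.ini").read_text()
        (wrap / "manifest.ini").write_text(
            manifest.replace("name = toy-snps", "name = toy-snps-2")
        )
        import_polymorphisms(populated_store, wrap)

        seen = []

        def spy(locus, candidates):
            seen.append((locus, len(candidates)))
            return ref_only(locus, candidates)

        _, vledger = variant_fixture
        v = next(x for x in vledger.variants if x.kind == "substitution"
                 and len(x.alts) == 1 and x.quality >= 20)
        pg = PersonalizedGenome(
            populated_store, "toy-genome", ["toy-snps", "toy-snps-2"], spy
        )
        pg.collect_locus_decisions(v.chromosome, (v.position, v.position + 1))
        assert seen == [((v.chromosome, v.position), 2)]
        assert pg.filter_calls == 1

    def test_retained_overlapping_decisions_conflict(self, populated_store):
        exon = next(iter(populated_store.get("Exon", {})))
        p = exon.start + 10
        populated_store.insert("SnpSet", {"id": "clash", "species": "t"})
        populated_store.insert_many("Polymorphism", [
            {"id": "clash:1", "set_name": "clash", "chromosome": exon.chromosome,
             "position": p, "ref_allele": "AAA", "alt_allele": "",
             "variant_kind": "deletion", "quality": 50.0,
             "metadata": {"filter": "PASS"}},
            {"id": "clash:2", "set_name": "clash", "chromosome": exon.chromosome,
             "position": p + 1, "ref_allele": "A", "alt_allele": "C",
             "variant_kind": "substitution", "quality": 50.0,
             "metadata": {"filter": "PASS"}},
        ])
        populated_store.commit()
        pg = PersonalizedGenome(populated_store, "toy-genome", ["clash"])
        with pytest.raises(ConflictError):
            pg.collect_locus_decisions(exon.chromosome, (exon.start, exon.end))


HANDMADE_FASTA = ">chr1\nGGGATGAAATTTTAGGGG\n"
HANDMADE_GTF = "\n".join([
    "\t".join(["chr1", "t", "gene", "4", "15", ".", "+", ".",
               'gene_id "G1"; gene_name "G1";']),
    "\t".join(["chr1", "t", "transcript", "4", "15", ".", "+", ".",
               'gene_id "G1"; transcript_id "T1"; protein_id "P1";']),
    "\t".join(["chr1", "t", "exon", "4", "15", ".", "+", ".",
               'gene_id "G1"; transcript_id "T1"; exon_number "1";'
               ' exon_id "T1.e1";']),
    "\t".join(["chr1", "t", "CDS", "4", "15", ".", "+", "0",
               'gene_id "G1"; transcript_id "T1";']),
]) + "\n"
HANDMADE_VCF = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    "chr1\t8\trs1\tA\tG\t55\tPASS\t.\n"     # middle base of codon 2 (AAA)
)


@pytest.fixture
def handmade_store(tmp_path):
    """One-exon gene with CDS ATG AAA TTT TAG and a SNP in codon 2."""
    for name, text in [("genome.fa", HANDMADE_FASTA),
                       ("annotation.gtf", HANDMADE_GTF)]:
        (tmp_path / "g").mkdir(exist_ok=True)
        (tmp_path / "g" / name).write_text(text)
    (tmp_path / "g" / "manifest.ini").write_text(
        "[package]\ndescription = h\nversion = 1\nmaintainer = m\n"
        "[genome]\nname = hand\nspecies = s\n"
        "[files]\nfasta = genome.fa\ngtf = annotation.gtf\n"
    )
    (tmp_path / "v").mkdir()
    (tmp_path / "v" / "variants.vcf").write_text(HANDMADE_VCF)
    (tmp_path / "v" / "manifest.ini").write_text(
        "[package]\ndescription = h\nversion = 1\nmaintainer = m\n"
        "[snps]\nname = hand-snps\nspecies = s\n"
        "[files]\nsnp = variants.vcf\n"
    )
    s = Store(tmp_path / "hand.db")
    import_genome(s, tmp_path / "g")
    import_polymorphisms(s, tmp_path / "v")
    yield s
    s.close()


class TestHandmadeMissense:
    def test_reference_protein(self, handmade_store):
        assert handmade_store.get_one("Protein", "P1").sequence == "MKF"

    def test_homozygous_alt_filter_gives_missense(self, handmade_store):
        def take_alt(locus, candidates):
            c = candidates[0]
            return AlleleDecision(
                "substitute", sequence=c.alt_allele, ref=c.ref_allele
            )

        pg = PersonalizedGenome(handmade_store, "hand", ["hand-snps"], take_alt)
        assert pg.protein_sequence("P1") == "MRF"  # K -> R at residue 2

    def test_default_heterozygous_filter_gives_iupac_then_x(self, handmade_store):
        pg = PersonalizedGenome(handmade_store, "hand", ["hand-snps"])
        assert pg.transcript_sequence("T1", "cds") == "ATGARATTTTAG"
        assert pg.protein_sequence("P1") == "MXF"  # AAA/AGA disagree

    def test_named_filter_resolution(self, handmade_store):
        pg = PersonalizedGenome(
            handmade_store, "hand", ["hand-snps"], resolve_filter("qual-ge:60")
        )
        assert pg.protein_sequence("P1") == "MKF"  # SNP below threshold
        with pytest.raises(NotFoundError):
            resolve_filter("frobnicate")


class TestLazyChain:
    def test_construction_loads_nothing(self, populated_store):
        PersonalizedGenome(populated_store, "toy-genome", ["toy-snps"])
        assert populated_store.load_count() == 0

    def test_first_protein_access_loads_chain_once(
        self, populated_store, genome_fixture
    ):
        _, ledger = genome_fixture
        pid = sorted(t.protein_id for t in ledger.transcripts.values())[0]
        pg = PersonalizedGenome(populated_store, "toy-genome", ["toy-snps"])
        view = pg.protein(pid)
        assert populated_store.load_count() == 0  # still lazy
        seq1 = view.sequence
        assert populated_store.load_count("Chromosome", "sequence") == 1
        total_after_first = populated_store.load_count()
        assert view.sequence == seq1  # cached: no further loads
        assert populated_store.load_count() == total_after_first

        pg2 = PersonalizedGenome(populated_store, "toy-genome", ["toy-snps"])
        assert pg2.protein(pid).sequence == seq1
        assert populated_store.load_count("Chromosome", "sequence") == 1

    def test_minus_strand_equals_revcomp_of_plus_assembly(
        self, populated_store, genome_fixture, variant_fixture
    ):
        """Personalizing a minus-strand transcript commutes with reverse
        complement: the pipeline output equals the reverse complement of
        the plus-strand genomic assembly edited by the tagged-list oracle."""
        from Bio.Seq import Seq

        _, ledger = genome_fixture
        _, vledger = variant_fixture
        pg = PersonalizedGenome(populated_store, "toy-genome", ["toy-snps"])
        minus = {
            tid: t for tid, t in ledger.transcripts.items() if t.strand == "-"
        }
        assert minus, "fixture must contain a minus-strand transcript"
        for tid, t in minus.items():
            plus = vledger.expected[tid]["cdna"]  # oracle, revcomp applied
            assert pg.transcript_sequence(tid, "full") == plus
            # and the un-revcomped assemblies agree too
            assert str(Seq(plus).reverse_complement()) == \
                reverse_complement(pg.transcript_sequence(tid, "full"))


class TestClipPolicy:
    def _plant_boundary_deletion(self, store, ledger):
        tid, t = next(
            (i, tt) for i, tt in sorted(ledger.transcripts.items())
            if tt.strand == "+"
        )
        cs, ce = t.cds[-1]
        chrom_seq = ledger.chromosomes[t.chromosome]
        store.insert("SnpSet", {"id": "edge", "species": "t"})
        store.insert(
            "Polymorphism",
            {"id": "edge:1", "set_name": "edge", "chromosome": t.chromosome,
             "position": ce - 1, "ref_allele": chrom_seq[ce - 1 : ce + 2],
             "alt_allele": "", "variant_kind": "deletion", "quality": 50.0,
             "metadata": {"filter": "PASS"}},
        )
        store.commit()
        return tid, t

    def test_deletion_across_cds_boundary_is_clipped(
        self, populated_store, genome_fixture, caplog
    ):
        _, ledger = genome_fixture
        tid, t = self._plant_boundary_deletion(populated_store, ledger)
        pg = PersonalizedGenome(populated_store, "toy-genome", ["edge"])
        with caplog.at_level("WARNING"):
            got = pg.transcript_sequence(tid, "cds")
        # only the single in-CDS base of the 3 bp deletion is removed
        assert len(got) == len(t.cds_sequence) - 1
        assert any("clipping" in r.message for r in caplog.records)

    def test_strict_mode_raises(self, populated_store, genome_fixture):
        _, ledger = genome_fixture
        tid, _ = self._plant_boundary_deletion(populated_store, ledger)
        pg = PersonalizedGenome(
            populated_store, "toy-genome", ["edge"], clip_policy="strict"
        )
        with pytest.raises(CoordinateError):
            pg.transcript_sequence(tid, "cds")


def test_export_fasta_headers_and_determinism(populated_store, genome_fixture):
    _, ledger = genome_fixture
    pg = PersonalizedGenome(populated_store, "toy-genome", ["toy-snps"])
    pids = [t.protein_id for t in ledger.transcripts.values()]
    text = pg.export_fasta(pids, kind="protein")
    assert text == pg.export_fasta(reversed(pids), kind="protein")
    headers = [l for l in text.splitlines() if l.startswith(">")]
    assert headers == [f">{p}|toy-genome|toy-snps" for p in sorted(pids)]
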