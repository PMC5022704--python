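"""Lazy minimal views, singleton identity, get() and global indexes."""

import random
import shutil

import pytest

from genovault.errors import FieldError, SchemaError
from genovault.parsers import parse_gtf
from genovault.store import Store


def test_get_planted_gene_by_id(populated_store, genome_fixture):
    _, ledger = genome_fixture
    gid = sorted(ledger.genes)[0]
    assert [g.id for g in populated_store.get("Gene", {"id": gid})] == [gid]


def test_get_absent_id_yields_nothing(populated_store):
    assert list(populated_store.get("Gene", {"id": "no_such_id"})) == []


def test_empty_filter_counts_match_fixture_gtf(populated_store, genome_fixture):
    path, _ = genome_fixture
    features = parse_gtf((path / "annotation.gtf").read_text())
    for kind, feature in (("Gene", "gene"), ("Transcript", "transcript"),
                          ("Exon", "exon")):
        expected = sum(1 for f in features if f.feature == feature)
        assert populated_store.count(kind) == expected


def test_unknown_kind_and_field_raise(populated_store):
    with pytest.raises(SchemaError):
        list(populated_store.get("Plasmid", {}))
    with pytest.raises(FieldError):
        list(populated_store.get("Gene", {"flavour": "salty"}))


def test_filter_comparators_match_python_semantics(populated_store):
    genes = list(populated_store.get("Gene", {}))
    cut = genes[0].start + 1
    lt = {g.id for g in populated_store.get("Gene", {"start__lt": cut})}
    assert lt == {g.id for g in genes if g.start < cut}
    gt = {g.id for g in populated_store.get("Gene", {"end__gt": cut})}
    assert gt == {g.id for g in genes if g.end > cut}
    pre = {t.id for t in populated_store.get("Transcript", {"id__prefix": "TX001"})}
    assert pre == {
        t.id for t in populated_store.get("Transcript", {})
        if t.id.startswith("TX001")
    }


class TestLazyLoading:
    def test_heavy_access_loads_exactly_once(self, populated_store):
        chrom = next(iter(populated_store.get("Chromosome", {})))
        assert "sequence" not in chrom.loaded_fields  # minimal view
        before = populated_store.load_count()
        seq = chrom.sequence
        assert len(seq) == chrom.length
        assert populated_store.load_count() == before + 1
        assert chrom.sequence is seq  # cached, no second fetch
        assert populated_store.load_count() == before + 1

    def test_light_access_never_counts_as_load(self, populated_store):
        gene = next(iter(populated_store.get("Gene", {})))
        before = populated_store.load_count()
        _ = gene.id, gene.start, gene.strand
        assert populated_store.load_count() == before

    def test_loaded_fields_only_grow(self, populated_store):
        t = next(iter(populated_store.get("Transcript", {})))
        snapshots = [set(t.loaded_fields)]
        _ = t.sequence
        snapshots.append(set(t.loaded_fields))
        _ = t.cds_sequence
        snapshots.append(set(t.loaded_fields))
        for a, b in zip(snapshots, snapshots[1:]):
            assert a <= b

    def test_unknown_field_access_raises(self, populated_store):
        g = next(iter(populated_store.get("Gene", {})))
        with pytest.raises(FieldError):
            _ = g.barcode


class TestSingletonIdentity:
    def test_same_id_same_object(self, populated_store):
        g1 = next(iter(populated_store.get("Gene", {})))
        g2 = populated_store.get_one("Gene", g1.id)
        assert g1 is g2

    def test_inflation_shared_between_handles(self, populated_store):
        c1 = next(iter(populated_store.get("Chromosome", {})))
        c2 = populated_store.get_one("Chromosome", c1.id)
        _ = c1.sequence
        before = populated_store.load_count()
        _ = c2.sequence  # already inflated through the other handle
        assert populated_store.load_count() == before

    def test_different_ids_distinct_objects(self, populated_store):
        genes = list(populated_store.get("Gene", {}))
        assert genes[0] is not genes[1]


class TestGlobalIndexes:
    def test_ensure_is_idempotent(self, populated_store):
        h1 = populated_store.ensure_global_index("Transcript", "id")
        h2 = populated_store.ensure_global_index("Transcript", "id")
        assert h1 == h2
        names = [h.name for h in populated_store.list_global_indexes()]
        assert names.count("Transcript.id") == 1

    def test_results_invariant_under_index(self, populated_store):
        tid = next(iter(populated_store.get("Transcript", {}))).id
        before = {t.id for t in populated_store.get("Transcript", {"id": tid})}
        populated_store.ensure_global_index("Transcript", "id")
        after = {t.id for t in populated_store.get("Transcript", {"id": tid})}
        assert before == after

    def test_drop_twice_is_noop(self, populated_store):
        populated_store.ensure_global_index("Gene", "chromosome")
        populated_store.drop_global_index("Gene", "chromosome")
        populated_store.drop_global_index("Gene", "chromosome")  # no error

    def test_unknown_kind_or_field(self, populated_store):
        with pytest.raises(SchemaError):
            populated_store.ensure_global_index("Nope", "id")
        with pytest.raises(FieldError):
            populated_store.ensure_global_index("Gene", "nope")

    def test_random_filterspecs_invariant(self, populated_store):
        rng = random.Random(3)
        genes = list(populated_store.get("Gene", {}))
        specs = []
        for _ in range(25):
            g = rng.choice(genes)
            specs.append(rng.choice([
                {"chromosome": g.chromosome},
                {"start__lt": rng.randint(0, 10_000)},
                {"end__gt": rng.randint(0, 10_000)},
                {"id__prefix": g.id[: rng.randint(1, 4)]},
            ]))
        before = [
            {x.id for x in populated_store.get("Gene", s)} for s in specs
        ]
        for field in ("chromosome", "start", "end", "id"):
            populated_store.ensure_global_index("Gene", field)
        after = [
            {x.id for x in populated_store.get("Gene", s)} for s in specs
        ]
        assert before == after


def test_store_roundtrip_and_file_copy(tmp_path, genome_fixture, variant_fixture):
    """The store file is the complete state: reopening it, or a copy of
    it, reproduces every result set."""
    from genovault.importers import import_genome, import_polymorphisms

    p = tmp_path / "round.db"
    s = Store(p)
    import_genome(s, genome_fixture[0])
    import_polymorphisms(s, variant_fixture[0])
    kinds = ["Genome", "Chromosome", "Gene", "Transcript", "Exon",
             "Protein", "Polymorphism", "SnpSet"]
    baseline = {k: sorted(r.id for r in s.get(k, {})) for k in kinds}
    s.close()

    s2 = Store(p)
    assert {k: sorted(r.id for r in s2.get(k, {})) for k in kinds} == baseline
    s2.close()

    copy = tmp_path / "backup.db"
    shutil.copyfile(p, copy)
    s3 = Store(copy)
    assert {k: sorted(r.id for r in s3.get(k, {})) for k in kinds} == baseline
    s3.close()
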