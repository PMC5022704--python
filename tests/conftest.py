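import pytest

from genovault.fixtures import (
    FixtureSpec,
    VariantSpec,
    generate_genome_datawrap,
    generate_variant_datawrap,
)
from genovault.importers import import_genome, import_polymorphisms
from genovault.store import Store


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    """Toy genome datawrap (seed 42: 1x10 kb, 2 genes, 3 tx, 7 exons)."""
    out = tmp_path_factory.mktemp("wraps") / "toy-genome"
    path, ledger = generate_genome_datawrap(FixtureSpec(), out)
    return path, ledger


@pytest.fixture(scope="session")
def variant_fixture(genome_fixture, tmp_path_factory):
    """Toy variant datawrap planted inside the toy genome's CDS."""
    _, ledger = genome_fixture
    out = tmp_path_factory.mktemp("wraps") / "toy-snps"
    path, vledger = generate_variant_datawrap(VariantSpec(), ledger, out)
    return path, vledger


@pytest.fixture
def store(tmp_path):
    s = Store(tmp_path / "store.db")
    yield s
    s.close()


@pytest.fixture
def populated_store(tmp_path, genome_fixture, variant_fixture):
    """Fresh store per test with the toy genome and variant set imported."""
    s = Store(tmp_path / "store.db")
    import_genome(s, genome_fixture[0])
    import_polymorphisms(s, variant_fixture[0])
    yield s
    s.close()
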