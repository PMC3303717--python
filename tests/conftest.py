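import pytest

from ontoload import db as dbmod
from ontoload import fixtures, parser
from ontoload.ontology import OntologySnapshot, load_obo
from ontoload.rules import process_entry


@pytest.fixture(scope="session")
def mini_so():
    """(obo text, manifest) of the bundled mini ontology fragment."""
    return fixtures.generate_mini_so(0)


@pytest.fixture(scope="session")
def snapshot(mini_so):
    return OntologySnapshot.build(load_obo(mini_so[0]))


@pytest.fixture(scope="session")
def nested_fixture(tmp_path_factory):
    """20 nested gene-model entries with manifest, written to disk."""
    text, manifest = fixtures.generate_entries(20, 42, "nested_gene_models")
    path = tmp_path_factory.mktemp("fixtures") / "nested.gbff"
    path.write_text(text)
    return str(path), manifest


@pytest.fixture()
def loaded_db(snapshot, nested_fixture):
    """In-memory database with the nested fixture fully loaded."""
    path, manifest = nested_fixture
    conn = dbmod.connect(":memory:")
    dbmod.create_schema(conn)
    dbmod.install_ontology(snapshot.closure, snapshot.graph.terms.values(), conn)
    for entry_text in parser.iter_entry_texts(path):
        entry = parser.parse_entry(entry_text)
        result = process_entry(entry, snapshot)
        load = dbmod.execute_statements(result.statements, conn)
        assert load.status == "loaded", load.reason
    yield conn, manifest
    conn.close()


def parse_all(path):
    return [parser.parse_entry(t) for t in parser.iter_entry_texts(path)]
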