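"""Rule engine: facts, relationship/evidence/intron inference, routing,
statement generation."""
import pytest

from ontoload.errors import StatementError
from ontoload.facts import StatementFact, entry_to_facts, validate_statements
from ontoload.model import Entry, Feature, Header, LocationPortion, Qualifier, Reference
from ontoload import fixtures, parser
from ontoload.rules import (
    assign_reference_evidence,
    infer_introns,
    infer_relationships,
    process_entry,
    route_qualifiers,
)


def _entry(features, references=(), length=1000):
    header = Header(
        locus_name="TST1", sequence_length=length, molecule_type="DNA",
        topology="linear", division_code="PLN", modification_date="01-JAN-2010",
        accession="TST1", version="TST1.1", gi=999, organism_name="Synthetica exempli",
    )
    return Entry(header=header, references=list(references), features=list(features))


def _feat(key, portions, quals=(), rank=0):
    return Feature(
        key=key,
        portions=[LocationPortion(start=s, end=e, strand=st, rank=i)
                  for i, (s, e, st) in enumerate(portions)],
        qualifiers=[Qualifier(name=n, value=v) for n, v in quals],
        rank=rank,
    )


# ---------------------------------------------------------------------------
# facts


def test_fact_count_by_construction(snapshot):
    features = [
        _feat("gene", [(1, 500, "forward")], [("gene", "a"), ("locus_tag", "t")], 0),
        _feat("mRNA", [(1, 500, "forward")], [("gene", "a"), ("product", "p")], 1),
    ]
    refs = [Reference(ordinal=1, cited_ranges=[(1, 800)])]
    facts = entry_to_facts(_entry(features, refs), snapshot.mapping)
    # 1 header + 1 sequence + 2 key + 2 portion + 4 qualifier + 1 ref + 1 range
    assert len(facts) == 12
    assert sum(f.template == "header" for f in facts) == 1
    assert sum(f.template == "sequence" for f in facts) == 1


def test_no_references_no_reference_facts(snapshot):
    facts = entry_to_facts(_entry([_feat("gene", [(1, 10, "forward")])]), snapshot.mapping)
    assert not [f for f in facts if f.template.startswith("reference")]


def test_fact_counts_match_fixture_manifest(snapshot, nested_fixture):
    path, manifest = nested_fixture
    for text, m in zip(parser.iter_entry_texts(path), manifest["entries"]):
        facts = entry_to_facts(parser.parse_entry(text), snapshot.mapping)
        assert len(facts) == m["fact_count"]


def test_residues_never_become_facts(snapshot):
    entry = _entry([_feat("gene", [(1, 10, "forward")])])
    entry.sequence = "acgt" * 100
    facts = entry_to_facts(entry, snapshot.mapping)
    seq_fact = next(f for f in facts if f.template == "sequence")
    assert "acgt" not in str(seq_fact.slots)
    assert seq_fact["present"] is True


def test_organelle_refines_gene_type(snapshot):
    features = [
        _feat("source", [(1, 1000, "forward")],
              [("organism", "X"), ("organelle", "mitochondrion")], 0),
        _feat("gene", [(10, 500, "forward")], [("gene", "a")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    gene_key = next(f for f in facts if f.template == "key" and f["key"] == "gene")
    assert gene_key["term"] == "SO:0000088"


# ---------------------------------------------------------------------------
# relationship inference


def test_gene_mrna_cds_tree_resolves_to_minimal_parents(snapshot):
    """mRNA attaches to its gene, CDS to the mRNA (smallest containing
    span), never directly to the gene."""
    features = [
        _feat("gene", [(1, 500, "forward")], [("gene", "abcA")], 0),
        _feat("mRNA", [(1, 100, "forward"), (201, 500, "forward")],
              [("gene", "abcA")], 1),
        _feat("CDS", [(10, 100, "forward"), (201, 450, "forward")],
              [("gene", "abcA")], 2),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    rels = {(r.subject, r.relationship, r.object)
            for r in infer_relationships(facts, snapshot)}
    assert rels == {(1, "part_of", 0), (2, "part_of", 1)}


def test_disjoint_genes_stay_unrelated(snapshot):
    features = [
        _feat("gene", [(1, 200, "forward")], [("gene", "a")], 0),
        _feat("gene", [(300, 500, "forward")], [("gene", "b")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    assert infer_relationships(facts, snapshot) == []


def test_qualifier_mismatch_blocks_relationship(snapshot):
    features = [
        _feat("gene", [(1, 500, "forward")], [("gene", "a")], 0),
        _feat("mRNA", [(10, 400, "forward")], [("gene", "OTHER")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    assert infer_relationships(facts, snapshot) == []


def test_strand_mismatch_blocks_relationship(snapshot):
    features = [
        _feat("gene", [(1, 500, "forward")], [("gene", "a")], 0),
        _feat("mRNA", [(10, 400, "reverse")], [("gene", "a")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    assert infer_relationships(facts, snapshot) == []


def test_protein_id_supports_derives_from(snapshot):
    features = [
        _feat("CDS", [(10, 400, "forward")], [("protein_id", "AAA1.1")], 0),
        _feat("mat_peptide", [(20, 100, "forward")], [("protein_id", "AAA1.1")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    rels = infer_relationships(facts, snapshot)
    assert [(r.subject, r.relationship, r.object) for r in rels] == [(1, "derives_from", 0)]
    assert "protein_id" in rels[0].provenance


def test_relationship_types_always_admissible(snapshot, nested_fixture):
    path, _ = nested_fixture
    for text in parser.iter_entry_texts(path):
        entry = parser.parse_entry(text)
        facts = entry_to_facts(entry, snapshot.mapping)
        terms = {f["feature_id"]: f["term"] for f in facts if f.template == "key"}
        for r in infer_relationships(facts, snapshot):
            assert snapshot.is_admissible(terms[r.subject], r.relationship,
                                          terms[r.object])


# ---------------------------------------------------------------------------
# reference evidence


@pytest.mark.parametrize(
    "span,linked", [((100, 400), True), ((700, 900), False)]
)
def test_reference_evidence_requires_containment(snapshot, span, linked):
    features = [_feat("gene", [(*span, "forward")], [("gene", "a")], 0)]
    refs = [Reference(ordinal=1, cited_ranges=[(1, 800)])]
    facts = entry_to_facts(_entry(features, refs), snapshot.mapping)
    assert (assign_reference_evidence(facts) == [(0, 1)]) is linked


def test_whole_entry_reference_links_every_feature(snapshot):
    features = [
        _feat("gene", [(10, 100, "forward")], rank=0),
        _feat("mRNA", [(500, 900, "forward")], rank=1),
    ]
    refs = [Reference(ordinal=1, cited_ranges=[(1, 1000)])]
    facts = entry_to_facts(_entry(features, refs), snapshot.mapping)
    assert assign_reference_evidence(facts) == [(0, 1), (1, 1)]


# ---------------------------------------------------------------------------
# implicit introns


def test_intron_from_two_exon_mrna(snapshot):
    features = [_feat("mRNA", [(1, 100, "forward"), (201, 300, "forward")],
                      [("gene", "a")], 0)]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    introns = infer_introns(facts, snapshot)
    assert [(i.start, i.end, i.strand, i.donors) for i in introns] == \
        [(101, 200, "forward", [0])]


def test_single_portion_feature_yields_no_intron(snapshot):
    facts = entry_to_facts(_entry([_feat("mRNA", [(1, 300, "forward")])]),
                           snapshot.mapping)
    assert infer_introns(facts, snapshot) == []


def test_intron_strand_carries_over_from_complement(snapshot):
    features = [_feat("mRNA", [(1, 100, "reverse"), (201, 300, "reverse")], rank=0)]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    introns = infer_introns(facts, snapshot)
    assert [(i.start, i.end, i.strand) for i in introns] == [(101, 200, "reverse")]


def test_explicit_intron_suppresses_inferred_duplicate(snapshot):
    features = [
        _feat("mRNA", [(1, 100, "forward"), (201, 300, "forward")], [("gene", "a")], 0),
        _feat("intron", [(101, 200, "forward")], [("gene", "a")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    assert infer_introns(facts, snapshot) == []


def test_shared_gap_merges_donors(snapshot):
    features = [
        _feat("mRNA", [(1, 100, "forward"), (201, 300, "forward")], [("gene", "a")], 0),
        _feat("CDS", [(10, 100, "forward"), (201, 290, "forward")], [("gene", "a")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    introns = infer_introns(facts, snapshot)
    assert [(i.start, i.end, i.donors) for i in introns] == [(101, 200, [0, 1])]


def test_introns_tile_gaps_exactly_on_fixtures(snapshot, nested_fixture):
    """Union of portions and inferred introns equals the donor's span,
    pairwise disjoint."""
    path, _ = nested_fixture
    checked = 0
    for text in parser.iter_entry_texts(path):
        entry = parser.parse_entry(text)
        facts = entry_to_facts(entry, snapshot.mapping)
        introns = infer_introns(facts, snapshot)
        for feat in entry.features:
            ports = sorted((p.start, p.end) for p in feat.portions
                           if p.remote_accession is None)
            if len(ports) < 2 or feat.key not in ("mRNA", "CDS"):
                continue
            mine = [i for i in introns if feat.rank in i.donors
                    and ports[0][0] <= i.start <= ports[-1][1]]
            segments = sorted(ports + [(i.start, i.end) for i in mine])
            # disjoint and contiguous from span start to span end
            for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
                assert e1 + 1 == s2
            assert segments[0][0] == ports[0][0]
            assert segments[-1][1] == ports[-1][1]
            checked += 1
    assert checked > 10


# ---------------------------------------------------------------------------
# qualifier routing


def test_qualifier_routing_destinations(snapshot):
    features = [
        _feat("source", [(1, 1000, "forward")],
              [("organism", "Synthetica exempli"), ("country", "Italy"),
               ("db_xref", "taxon:32644")], 0),
        _feat("CDS", [(10, 400, "forward")],
              [("product", "VP35"), ("frobnicate", "x")], 1),
    ]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    routed = route_qualifiers(facts, snapshot)
    assert ("country", "Italy") in routed.collection
    assert ("organism_name", "Synthetica exempli") in routed.taxonomy
    assert ("taxon_db_xref", "taxon:32644") in routed.taxonomy
    annots = {(name, value) for _, _, name, value in routed.annotations}
    assert ("product", "VP35") in annots
    terms = {name: term for _, term, name, _ in routed.annotations}
    assert terms["frobnicate"] == "local:frobnicate"


def test_non_taxon_db_xref_stays_an_annotation(snapshot):
    features = [_feat("CDS", [(1, 10, "forward")], [("db_xref", "GOA:P123")], 0)]
    facts = entry_to_facts(_entry(features), snapshot.mapping)
    routed = route_qualifiers(facts, snapshot)
    assert routed.taxonomy == []
    assert any(n == "db_xref" for _, _, n, _ in routed.annotations)


# ---------------------------------------------------------------------------
# statement generation


def test_statement_list_contract_on_fixture(snapshot, nested_fixture):
    path, _ = nested_fixture
    text = next(parser.iter_entry_texts(path))
    result = process_entry(parser.parse_entry(text), snapshot)
    statements = result.statements
    validate_statements(statements)  # strictly increasing + ordered citations
    counts = [s.count for s in statements]
    assert counts == sorted(counts)
    # every fact lands somewhere: entry, sequence, features, portions...
    tables = {s.table_name for s in statements}
    assert {"entry", "sequence", "sequence_feature", "feature_portion",
            "feature_annotation", "feature_relationship", "taxonomy",
            "individual", "reference", "reference_evidence"} <= tables


def test_minimal_entry_statements(snapshot):
    result = process_entry(_entry([]), snapshot)
    tables = [s.table_name for s in result.statements]
    assert "entry" in tables and "sequence" in tables and "taxonomy" in tables
    assert "sequence_feature" not in tables


def test_annotation_insert_cites_feature_insert(snapshot):
    features = [_feat("CDS", [(1, 90, "forward")], [("product", "VP35")], 0)]
    result = process_entry(_entry(features), snapshot)
    feat_stmt = next(s for s in result.statements if s.table_name == "sequence_feature")
    annot = next(s for s in result.statements if s.table_name == "feature_annotation")
    assert annot.count > feat_stmt.count
    assert feat_stmt.count in annot.foreign_counts


def test_statement_generation_is_deterministic(snapshot, nested_fixture):
    path, _ = nested_fixture
    text = next(parser.iter_entry_texts(path))
    entry = parser.parse_entry(text)
    a = process_entry(entry, snapshot).statements
    b = process_entry(entry, snapshot).statements
    assert [(s.kind, s.count, s.table_name, s.column_values, s.foreign_counts)
            for s in a] == \
        [(s.kind, s.count, s.table_name, s.column_values, s.foreign_counts)
         for s in b]


def test_dangling_foreign_count_rejected():
    st = [
        StatementFact("insert", 1, "individual", ["label"], ["x"]),
        StatementFact("insert", 2, "collection_event",
                      ["individual_id"], [None], [7], ["individual_id"]),
    ]
    with pytest.raises(StatementError, match="cites count 7"):
        validate_statements(st)
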