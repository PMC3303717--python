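"""Flat-file parser: location grammar, sections, headers, round-trips."""
import pytest

from ontoload.errors import IndexingError, LocationParseError, ParseError
from ontoload import fixtures, parser
from ontoload.model import FORWARD, REVERSE


# ---------------------------------------------------------------------------
# location grammar


@pytest.mark.parametrize(
    "text,expected",
    [
        ("340..565", [(340, 565, FORWARD, False, False, False, None)]),
        ("467", [(467, 467, FORWARD, False, False, False, None)]),
        ("<1..206", [(1, 206, FORWARD, True, False, False, None)]),
        ("3..>206", [(3, 206, FORWARD, False, True, False, None)]),
        ("123^124", [(123, 124, FORWARD, False, False, True, None)]),
        (
            "complement(join(2691..4571,4918..5163))",
            [
                (2691, 4571, REVERSE, False, False, False, None),
                (4918, 5163, REVERSE, False, False, False, None),
            ],
        ),
        (
            "join(1..100,REM1234.1:50..80,201..300)",
            [
                (1, 100, FORWARD, False, False, False, None),
                (50, 80, FORWARD, False, False, False, "REM1234.1"),
                (201, 300, FORWARD, False, False, False, None),
            ],
        ),
        ("complement(77..154)", [(77, 154, REVERSE, False, False, False, None)]),
    ],
)
def test_location_grammar(text, expected):
    portions = parser.parse_location(text)
    got = [
        (p.start, p.end, p.strand, p.partial5, p.partial3, p.between_bases,
         p.remote_accession)
        for p in portions
    ]
    assert got == expected
    assert [p.rank for p in portions] == list(range(len(portions)))


def test_order_operator_is_annotated_not_lost():
    portions, op = parser.parse_location_full("order(1..50,100..150)")
    assert op == "order"
    assert [(p.start, p.end) for p in portions] == [(1, 50), (100, 150)]


@pytest.mark.parametrize(
    "bad",
    [
        "join(1..100,201..300",          # unbalanced
        "complement(complement(1..10))",  # nested complement rejected
        "shuffle(1..10)",                 # unknown operator
        "",                               # empty
        "10..5",                          # inverted range
        "123^300",                        # non-adjacent between-bases
    ],
)
def test_malformed_locations_raise(bad):
    with pytest.raises((LocationParseError, ValueError)):
        parser.parse_location(bad)


# ---------------------------------------------------------------------------
# section split


def _one_entry_text():
    text, _ = fixtures.generate_entries(1, 5, "nested_gene_models")
    return text


def test_split_entry_partitions_input():
    text = _one_entry_text()
    sections = parser.split_entry(text)
    recombined = (
        sections.header_text + sections.references_text
        + sections.features_text + sections.sequence_text
    )
    assert recombined == text
    assert sections.header_text.startswith("LOCUS")
    assert sections.references_text.startswith("REFERENCE")
    assert sections.features_text.startswith("FEATURES")
    assert sections.sequence_text.startswith("ORIGIN")


def test_split_entry_without_references():
    text, _ = fixtures.generate_entries(6, 3, "adversarial")
    entries = text.split("//\n")
    no_ref = next(e + "//\n" for e in entries if "REFERENCE" not in e)
    sections = parser.split_entry(no_ref)
    assert sections.references_text == ""
    assert sections.features_text.startswith("FEATURES")


def test_split_entry_groups_all_reference_blocks():
    text, _ = fixtures.generate_entries(1, 3, "reference_rich")
    sections = parser.split_entry(text)
    assert sections.references_text.count("REFERENCE") == 3
    assert "REFERENCE" not in sections.features_text


@pytest.mark.parametrize("drop,section", [("ORIGIN", "sequence"), ("//", "sequence")])
def test_split_entry_missing_terminator_errors(drop, section):
    text = _one_entry_text()
    broken = "\n".join(l for l in text.splitlines() if not l.startswith(drop))
    with pytest.raises(ParseError, match=section):
        parser.split_entry(broken + "\n")


# ---------------------------------------------------------------------------
# header


def test_parse_header_fields_match_manifest():
    text, manifest = fixtures.generate_entries(1, 9, "minimal")
    entry = manifest["entries"][0]
    header = parser.parse_header(parser.split_entry(text).header_text)
    assert header.locus_name == entry["locus_name"]
    assert header.sequence_length == entry["sequence_length"]
    assert header.topology == entry["topology"]
    assert header.division_code == entry["division"]
    assert header.gi == entry["gi"]
    assert header.version == entry["version"]
    assert header.organism_name == entry["organism"]
    assert header.lineage == entry["lineage"]
    assert header.keywords == []


def test_parse_header_version_gi_style():
    header = parser.parse_header(
        "LOCUS       X00001                   300 bp    DNA     linear   PLN 01-JAN-1999\n"
        "DEFINITION  test entry.\n"
        "ACCESSION   X00001\n"
        "VERSION     X00001.1  GI:12345\n"
    )
    assert header.version == "X00001.1"
    assert header.gi == 12345
    assert header.sequence_length == 300
    assert header.keywords == []


def test_parse_header_unparseable_locus_cites_line():
    with pytest.raises(ParseError, match="LOCUS"):
        parser.parse_header("LOCUS   garbled line without length\n")


# ---------------------------------------------------------------------------
# references


def test_parse_reference_base_clause():
    refs = parser.parse_references("REFERENCE   1  (bases 1 to 800)\n  AUTHORS   A.\n")
    assert refs[0].ordinal == 1
    assert refs[0].cited_ranges == [(1, 800)]


def test_parse_reference_multiple_ranges():
    refs = parser.parse_references("REFERENCE   2  (bases 1 to 100; 200 to 300)\n")
    assert refs[0].cited_ranges == [(1, 100), (200, 300)]


def test_parse_references_empty_text():
    assert parser.parse_references("") == []


def test_parse_reference_without_clause_covers_whole_entry():
    refs = parser.parse_references("REFERENCE   1\n  TITLE     Direct Submission\n", 512)
    assert refs[0].cited_ranges == [(1, 512)]


def test_parse_reference_pubmed():
    refs = parser.parse_references(
        "REFERENCE   1  (bases 1 to 10)\n  PUBMED    987654\n"
    )
    assert refs[0].pubmed_id == 987654


# ---------------------------------------------------------------------------
# feature table


FEATURES_TEXT = """FEATURES             Location/Qualifiers
     source          1..900
                     /organism="Synthetica exempli"
     gene            10..800
                     /gene="abcA"
     mRNA            join(10..100,201..800)
                     /gene="abcA"
                     /product="alpha
                     beta"
     CDS             20..700
                     /germline
                     /translation="MKVLITTS
                     WAARD"
"""


def test_parse_feature_table_order_and_values():
    feats = parser.parse_feature_table(FEATURES_TEXT)
    assert [f.key for f in feats] == ["source", "gene", "mRNA", "CDS"]
    assert [f.rank for f in feats] == [0, 1, 2, 3]
    mrna = feats[2]
    # wrapped quoted value joins with a single space
    assert mrna.qualifiers[1].value == "alpha beta"
    cds = feats[3]
    # flag qualifier has no value; translation joins with no separator
    assert cds.qualifiers[0].name == "germline"
    assert cds.qualifiers[0].value is None
    assert cds.qualifiers[1].value == "MKVLITTSWAARD"


def test_qualifier_before_any_feature_key_errors():
    bad = 'FEATURES             Location/Qualifiers\n                     /gene="x"\n'
    with pytest.raises(ParseError):
        parser.parse_feature_table(bad)


# ---------------------------------------------------------------------------
# whole entries, indexing, streaming


def test_parse_entry_sequence_extraction():
    text, manifest = fixtures.generate_entries(1, 4, "minimal")
    entry = parser.parse_entry(text)
    m = manifest["entries"][0]
    assert entry.sequence == m["sequence"]
    assert len(entry.sequence) == entry.header.sequence_length


def test_parse_entry_truncated_errors():
    text = _one_entry_text()
    truncated = text[: text.rindex("//")]
    with pytest.raises((ParseError, IndexingError)):
        parser.parse_entry(truncated)


@pytest.mark.parametrize(
    "profile,n", [("minimal", 3), ("nested_gene_models", 6), ("reference_rich", 3),
                  ("adversarial", 12), ("key_coverage", 4), ("qualifier_coverage", 4)]
)
def test_round_trip_against_manifest(tmp_path, profile, n):
    """Every parsed entry equals the generator's planted ground truth."""
    text, manifest = fixtures.generate_entries(n, 17, profile)
    path = tmp_path / f"{profile}.gbff"
    path.write_text(text)
    entries = [parser.parse_entry(t) for t in parser.iter_entry_texts(str(path))]
    assert len(entries) == manifest["n_entries"]
    for entry, m in zip(entries, manifest["entries"]):
        assert entry.header.gi == m["gi"]
        assert entry.header.sequence_length == m["sequence_length"]
        assert entry.sequence == m["sequence"]
        assert len(entry.features) == len(m["features"])
        for feat, mf in zip(entry.features, m["features"]):
            assert feat.key == mf["key"]
            assert feat.location_operator == mf["operator"]
            got_portions = [
                [p.start, p.end, p.strand, p.partial5, p.partial3, p.between_bases,
                 p.remote_accession]
                for p in feat.portions
            ]
            assert got_portions == mf["portions"]
            assert [[q.name, q.value] for q in feat.qualifiers] == mf["qualifiers"]
        assert [r.ordinal for r in entry.references] == \
            [r["ordinal"] for r in m["references"]]
        assert [r.cited_ranges for r in entry.references] == \
            [[tuple(x) for x in r["ranges"]] for r in m["references"]]


def test_index_entries_offsets_address_locus_lines(tmp_path, nested_fixture):
    path, manifest = nested_fixture
    records = parser.index_entries(path)
    assert len(records) == manifest["n_entries"]
    with open(path, "rb") as fh:
        for (header_off, seq_off, gi), m in zip(records, manifest["entries"]):
            assert (header_off, seq_off, gi) == (
                m["header_offset"], m["sequence_offset"], m["gi"])
            fh.seek(header_off)
            assert fh.readline().startswith(b"LOCUS")


def test_index_empty_file(tmp_path):
    empty = tmp_path / "empty.gbff"
    empty.write_text("")
    assert parser.index_entries(str(empty)) == []


def test_index_terminator_without_locus_errors(tmp_path):
    bad = tmp_path / "bad.gbff"
    bad.write_text("DEFINITION  orphan\n//\n")
    with pytest.raises(IndexingError, match="byte"):
        parser.index_entries(str(bad))


def test_streaming_reader_yields_each_entry(nested_fixture):
    path, manifest = nested_fixture
    texts = list(parser.iter_entry_texts(path))
    assert len(texts) == manifest["n_entries"]
    for text in texts:
        assert text.startswith("LOCUS")
        assert text.rstrip().endswith("//")


def test_read_entry_at_seeks_correctly(nested_fixture):
    path, manifest = nested_fixture
    m = manifest["entries"][3]
    text = parser.read_entry_at(path, m["header_offset"])
    entry = parser.parse_entry(text)
    assert entry.header.gi == m["gi"]


# ---------------------------------------------------------------------------
# independent reference-parser agreement (cross-validation harness)


@pytest.mark.parametrize("profile,n", [("nested_gene_models", 5), ("key_coverage", 4)])
def test_agreement_with_reference_parser(tmp_path, profile, n):
    """Feature counts, keys and qualifier counts agree with Biopython."""
    SeqIO = pytest.importorskip("Bio.SeqIO")
    text, _ = fixtures.generate_entries(n, 23, profile)
    path = tmp_path / "xval.gbff"
    path.write_text(text)
    ours = [parser.parse_entry(t) for t in parser.iter_entry_texts(str(path))]
    theirs = list(SeqIO.parse(str(path), "genbank"))
    assert len(ours) == len(theirs)
    for mine, ref in zip(ours, theirs):
        assert [f.key for f in mine.features] == [f.type for f in ref.features]
        for mf, rf in zip(mine.features, ref.features):
            assert len(mf.qualifiers) == sum(len(v) for v in rf.qualifiers.values())
        assert str(ref.seq).lower() == mine.sequence
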