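"""Forward-chaining inference over entry facts.

The engine is a deterministic, stratified forward-chaining evaluator.  The
strata run in a fixed order — facts, relationships, reference evidence,
implicit introns, qualifier routing, statement generation — so no general
conflict-resolution strategy is needed and the statement list is
reproducible bit-for-bit for a given entry and ontology snapshot.

Relationship inference combines three tests:

* admissibility — the (subject type, relationship, object type) pair must
  be entailed by the ontology (the object type may satisfy a triple through
  any of its is_a ancestors);
* qualifier consistency — the features must share an identical value for
  ``locus_tag`` or ``gene`` (``protein_id`` also counts for derives_from);
  when neither feature carries any of those qualifiers, location alone
  decides;
* location coherence — the subject's span must lie within the object's
  span on the same strand (strand ignored when either side is strandless).

When several admissible parents qualify for the same relationship, the one
with the smallest containing span wins; remaining ties go to the earlier
feature in entry order.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .facts import Fact, RelationshipFact, StatementFact
from .ontology import OntologySnapshot

log = logging.getLogger(__name__)

CONSISTENCY_QUALIFIERS = ("locus_tag", "gene")
DERIVES_QUALIFIER = "protein_id"
DEFAULT_INTRON_DONOR_TERMS = ("SO:0000673", "SO:0000316")  # transcript, CDS
INTRON_TERM = "SO:0000188"


@dataclass
class _FeatureView:
    """Per-feature aggregation of key/portion/qualifier facts."""

    fid: int
    key: str
    term: str
    rank: int
    portions: list[tuple[int, int, str, bool]] = field(default_factory=list)
    # (start, end, strand, between_bases) — local portions only
    qualifiers: dict[str, list[Optional[str]]] = field(default_factory=dict)
    strandless_key: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, *_ in self.portions), max(e for _, e, *_ in self.portions))

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s + 1

    @property
    def covered_length(self) -> int:
        """Sum of portion lengths — the tie-break size measure.  A spliced
        parent (mRNA) is smaller than an unspliced one (gene) even when
        their outer spans coincide."""
        return sum(e - s + 1 for s, e, _st, _b in self.portions)

    @property
    def strand(self) -> Optional[str]:
        strands = {st for _s, _e, st, _b in self.portions}
        return next(iter(strands)) if len(strands) == 1 else None

    def values(self, name: str) -> set[str]:
        return {v for v in self.qualifiers.get(name, []) if v is not None}


def feature_views(facts: list[Fact]) -> dict[int, _FeatureView]:
    views: dict[int, _FeatureView] = {}
    for f in facts:
        if f.template == "key":
            views[f["feature_id"]] = _FeatureView(
                fid=f["feature_id"],
                key=f["key"],
                term=f["term"],
                rank=f["rank"],
                strandless_key=f["key"] == "source",
            )
    for f in facts:
        if f.template == "portion":
            if f["remote_accession"] is not None:
                continue  # remote portions never join inference
            views[f["feature_id"]].portions.append(
                (f["start"], f["end"], f["strand"], f["between_bases"])
            )
        elif f.template == "qualifier":
            views[f["feature_id"]].qualifiers.setdefault(f["name"], []).append(f["value"])
    return {fid: v for fid, v in views.items() if v.portions}


def _qualifier_consistent(f: _FeatureView, g: _FeatureView, relationship: str) -> tuple[bool, str]:
    keys = CONSISTENCY_QUALIFIERS + ((DERIVES_QUALIFIER,) if relationship == "derives_from" else ())
    f_has = any(f.values(k) for k in keys)
    g_has = any(g.values(k) for k in keys)
    if not f_has and not g_has:
        return True, "no identity qualifiers; location decides"
    for k in keys:
        shared = f.values(k) & g.values(k)
        if shared:
            return True, f"shared /{k}={sorted(shared)[0]!r}"
    return False, ""


def _location_coherent(f: _FeatureView, g: _FeatureView) -> bool:
    fs, fe = f.span
    gs, ge = g.span
    if not (gs <= fs and fe <= ge):
        return False
    if f.strandless_key or g.strandless_key:
        return True
    sf, sg = f.strand, g.strand
    return sf is None or sg is None or sf == sg


def infer_relationships(
    facts: list[Fact], snapshot: OntologySnapshot
) -> list[RelationshipFact]:
    """Reconstruct member_of/part_of/derives_from edges among an entry's features."""
    views = feature_views(facts)
    out: list[RelationshipFact] = []
    for f in sorted(views.values(), key=lambda v: v.rank):
        for rel in ("part_of", "member_of", "derives_from"):
            candidates = []
            for g in sorted(views.values(), key=lambda v: v.rank):
                if g.fid == f.fid:
                    continue
                if not snapshot.is_admissible(f.term, rel, g.term):
                    continue
                ok, why = _qualifier_consistent(f, g, rel)
                if not ok:
                    continue
                if not _location_coherent(f, g):
                    continue
                candidates.append(((g.covered_length, g.span_length, g.rank), g, why))
            if candidates:
                candidates.sort(key=lambda c: c[0])
                _, g, why = candidates[0]
                out.append(
                    RelationshipFact(
                        subject=f.fid,
                        relationship=rel,
                        object=g.fid,
                        provenance=(
                            f"types ({f.term} {rel} {g.term}) admissible; {why}; "
                            f"span {f.span[0]}..{f.span[1]} within {g.span[0]}..{g.span[1]}"
                        ),
                    )
                )
    return out


def assign_reference_evidence(facts: list[Fact]) -> list[tuple[int, int]]:
    """(feature id, reference ordinal) links: feature span contained in a cited range."""
    views = feature_views(facts)
    ranges: dict[int, list[tuple[int, int]]] = {}
    for f in facts:
        if f.template == "reference_portion":
            ranges.setdefault(f["ordinal"], []).append((f["start"], f["end"]))
    links: list[tuple[int, int]] = []
    for v in sorted(views.values(), key=lambda x: x.rank):
        fs, fe = v.span
        for ordinal in sorted(ranges):
            if any(s <= fs and fe <= e for s, e in ranges[ordinal]):
                links.append((v.fid, ordinal))
    return links


@dataclass
class InferredIntron:
    start: int
    end: int
    strand: str
    donors: list[int]  # feature ids whose portion gaps produced this intron


def infer_introns(
    facts: list[Fact],
    snapshot: OntologySnapshot,
    donor_terms: tuple[str, ...] = DEFAULT_INTRON_DONOR_TERMS,
) -> list[InferredIntron]:
    """Implicit introns: gaps between consecutive portions of transcript- or
    CDS-class features.  Introns with identical coordinates are merged into
    one feature carrying a part_of edge to every donor; an interval already
    present as an explicit intron feature is suppressed.
    """
    views = feature_views(facts)
    donor_set = set(donor_terms)
    explicit = {
        (v.span[0], v.span[1], v.strand)
        for v in views.values()
        if v.term == INTRON_TERM or v.key == "intron"
    }
    found: dict[tuple[int, int, str], InferredIntron] = {}
    for v in sorted(views.values(), key=lambda x: x.rank):
        if not (snapshot.ancestors_or_self(v.term) & donor_set):
            continue
        ports = sorted((s, e) for s, e, _st, between in v.portions if not between)
        if len(ports) < 2 or v.strand is None:
            continue
        for (s1, e1), (s2, e2) in zip(ports, ports[1:]):
            if s2 > e1 + 1:
                key = (e1 + 1, s2 - 1, v.strand)
                if (key[0], key[1], key[2]) in explicit:
                    continue
                intron = found.setdefault(key, InferredIntron(key[0], key[1], key[2], []))
                if v.fid not in intron.donors:
                    intron.donors.append(v.fid)
    return [found[k] for k in sorted(found)]


@dataclass
class RoutedAnnotations:
    collection: list[tuple[str, str]] = field(default_factory=list)  # (column, value)
    taxonomy: list[tuple[str, str]] = field(default_factory=list)
    annotations: list[tuple[int, str, str, Optional[str]]] = field(default_factory=list)
    # (feature id, term accession, qualifier name, value)
    suppressed: int = 0


def route_qualifiers(facts: list[Fact], snapshot: OntologySnapshot) -> RoutedAnnotations:
    """Send each qualifier fact to its destination table binding."""
    from .ontology import annotation_term

    routed = RoutedAnnotations()
    for f in facts:
        if f.template != "qualifier":
            continue
        name, value = f["name"], f["value"]
        r = snapshot.routing.route(name)
        if r.route == "suppressed":
            routed.suppressed += 1
        elif r.route == "collection":
            routed.collection.append((r.target, value if value is not None else "true"))
        elif r.route == "taxonomy":
            if name == "db_xref" and not (value or "").startswith("taxon:"):
                routed.annotations.append(
                    (f["feature_id"], annotation_term(name, snapshot.routing), name, value)
                )
            else:
                routed.taxonomy.append((r.target, value if value is not None else "true"))
        else:
            routed.annotations.append(
                (f["feature_id"], annotation_term(name, snapshot.routing), name, value)
            )
    return routed


# ---------------------------------------------------------------------------
# statement generation


def generate_statements(
    facts: list[Fact],
    relationships: list[RelationshipFact],
    evidences: list[tuple[int, int]],
    introns: list[InferredIntron],
    routed: RoutedAnnotations,
    snapshot: OntologySnapshot,
    sequence_residues: str = "",
) -> list[StatementFact]:
    """Translate one entry's derived facts into an ordered statement list.

    Counts increase strictly; every parent insert precedes the statements
    that cite its generated key through ``foreign_counts``.
    """
    from .facts import validate_statements

    header = next(f for f in facts if f.template == "header")
    key_facts = [f for f in facts if f.template == "key"]
    portion_facts = [f for f in facts if f.template == "portion"]
    ref_facts = [f for f in facts if f.template == "reference"]
    refport_facts = [f for f in facts if f.template == "reference_portion"]

    statements: list[StatementFact] = []
    counter = 0

    def emit(kind, table, columns, values, fk=(), fkcols=()) -> int:
        nonlocal counter
        counter += 1
        statements.append(
            StatementFact(
                kind=kind,
                count=counter,
                table_name=table,
                column_names=list(columns),
                column_values=list(values),
                foreign_counts=list(fk),
                foreign_columns=list(fkcols),
            )
        )
        return counter

    # ontology terms this entry introduces (local fallbacks, mapped terms the
    # installed ontology may lack) -- idempotent upserts keep the FK sound.
    used_terms = sorted(
        {f["term"] for f in key_facts}
        | {term for _, term, _, _ in routed.annotations}
        | ({INTRON_TERM} if introns else set())
    )
    for acc in used_terms:
        term = snapshot.graph.terms.get(acc)
        if term is not None:
            name, namespace = term.name, term.namespace
        elif acc.startswith("local:"):
            name, namespace = acc.split(":", 1)[1], "local"
        else:
            name, namespace = acc, "sequence"
        emit("upsert", "ontology_term",
             ("accession", "name", "namespace", "obsolete"), (acc, name, namespace, 0))
        emit("upsert", "cvpath",
             ("subject", "object", "relationship", "distance"), (acc, acc, "is_a", 0))

    taxonomy_cols = {"organism_name": header["organism_name"],
                     "lineage": "; ".join(header["lineage"])}
    for col, val in routed.taxonomy:
        taxonomy_cols[col] = val
    tax_count = emit("insert", "taxonomy", taxonomy_cols.keys(), taxonomy_cols.values())

    indiv_count = emit("insert", "individual", ("label",),
                       (header["accession"] or header["locus_name"],))

    if routed.collection:
        coll_cols: dict[str, str] = {}
        for col, val in routed.collection:
            coll_cols.setdefault(col, val)
        emit("insert", "collection_event",
             ["individual_id"] + list(coll_cols.keys()),
             [None] + list(coll_cols.values()),
             fk=[indiv_count], fkcols=["individual_id"])

    entry_count = emit(
        "insert", "entry",
        ("gi", "accession", "version", "locus_name", "sequence_length", "molecule_type",
         "topology", "division_code", "modification_date", "definition", "keywords",
         "taxonomy_id", "individual_id"),
        (header["gi"], header["accession"], header["version"], header["locus_name"],
         header["sequence_length"], header["molecule_type"], header["topology"],
         header["division_code"], header["modification_date"], header["definition"],
         "; ".join(header["keywords"]), None, None),
        fk=[tax_count, indiv_count], fkcols=["taxonomy_id", "individual_id"],
    )

    emit("insert", "sequence", ("entry_id", "length", "residues"),
         (None, header["sequence_length"], sequence_residues),
         fk=[entry_count], fkcols=["entry_id"])

    ref_counts: dict[int, int] = {}
    for rf in ref_facts:
        ranges = [
            f"{p['start']}..{p['end']}" for p in refport_facts if p["ordinal"] == rf["ordinal"]
        ]
        ref_counts[rf["ordinal"]] = emit(
            "insert", "reference",
            ("entry_id", "ordinal", "authors", "title", "journal", "pubmed_id", "cited_ranges"),
            (None, rf["ordinal"], rf["authors"], rf["title"], rf["journal"],
             rf["pubmed_id"], ";".join(ranges)),
            fk=[entry_count], fkcols=["entry_id"],
        )

    views = feature_views(facts)
    feature_counts: dict[int, int] = {}
    for kf in key_facts:
        fid = kf["feature_id"]
        view = views.get(fid)
        span = view.span if view else (None, None)
        strand = view.strand if view else None
        feature_counts[fid] = emit(
            "insert", "sequence_feature",
            ("entry_id", "type_accession", "feature_key", "rank", "span_start",
             "span_end", "strand", "inferred"),
            (None, kf["term"], kf["key"], kf["rank"], span[0], span[1], strand, 0),
            fk=[entry_count], fkcols=["entry_id"],
        )
    for pf in portion_facts:
        emit(
            "insert", "feature_portion",
            ("feature_id", "start", "end", "strand", "partial5", "partial3",
             "between_bases", "remote_accession", "rank"),
            (None, pf["start"], pf["end"], pf["strand"], int(pf["partial5"]),
             int(pf["partial3"]), int(pf["between_bases"]), pf["remote_accession"],
             pf["rank"]),
            fk=[feature_counts[pf["feature_id"]]], fkcols=["feature_id"],
        )

    next_rank = max((kf["rank"] for kf in key_facts), default=-1) + 1
    intron_ids: list[tuple[InferredIntron, int]] = []
    for intron in introns:
        cnt = emit(
            "insert", "sequence_feature",
            ("entry_id", "type_accession", "feature_key", "rank", "span_start",
             "span_end", "strand", "inferred"),
            (None, INTRON_TERM, "intron", next_rank, intron.start, intron.end,
             intron.strand, 1),
            fk=[entry_count], fkcols=["entry_id"],
        )
        emit(
            "insert", "feature_portion",
            ("feature_id", "start", "end", "strand", "partial5", "partial3",
             "between_bases", "remote_accession", "rank"),
            (None, intron.start, intron.end, intron.strand, 0, 0, 0, None, 0),
            fk=[cnt], fkcols=["feature_id"],
        )
        intron_ids.append((intron, cnt))
        next_rank += 1

    for fid, term, name, value in routed.annotations:
        emit(
            "insert", "feature_annotation",
            ("feature_id", "type_accession", "name", "value"),
            (None, term, name, value),
            fk=[feature_counts[fid]], fkcols=["feature_id"],
        )

    for rel in relationships:
        emit(
            "insert", "feature_relationship",
            ("subject_id", "object_id", "reltype", "provenance"),
            (None, None, rel.relationship, rel.provenance),
            fk=[feature_counts[rel.subject], feature_counts[rel.object]],
            fkcols=["subject_id", "object_id"],
        )
    for intron, cnt in intron_ids:
        for donor in intron.donors:
            emit(
                "insert", "feature_relationship",
                ("subject_id", "object_id", "reltype", "provenance"),
                (None, None, "part_of",
                 f"implicit intron {intron.start}..{intron.end} from donor portion gap"),
                fk=[cnt, feature_counts[donor]], fkcols=["subject_id", "object_id"],
            )

    for fid, ordinal in evidences:
        emit(
            "insert", "reference_evidence",
            ("feature_id", "reference_id"),
            (None, None),
            fk=[feature_counts[fid], ref_counts[ordinal]],
            fkcols=["feature_id", "reference_id"],
        )

    validate_statements(statements)
    return statements


@dataclass
class EngineResult:
    facts: list[Fact]
    relationships: list[RelationshipFact]
    evidences: list[tuple[int, int]]
    introns: list[InferredIntron]
    routed: RoutedAnnotations
    statements: list[StatementFact]


def process_entry(
    entry,
    snapshot: OntologySnapshot,
    donor_terms: tuple[str, ...] = DEFAULT_INTRON_DONOR_TERMS,
) -> EngineResult:
    """Run all strata on one parsed entry."""
    from .facts import entry_to_facts

    facts = entry_to_facts(entry, snapshot.mapping)
    relationships = infer_relationships(facts, snapshot)
    evidences = assign_reference_evidence(facts)
    introns = infer_introns(facts, snapshot, donor_terms)
    routed = route_qualifiers(facts, snapshot)
    statements = generate_statements(
        facts, relationships, evidences, introns, routed, snapshot,
        sequence_residues=entry.sequence,
    )
    return EngineResult(facts, relationships, evidences, introns, routed, statements)
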