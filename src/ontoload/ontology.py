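"""Sequence Ontology knowledge: typing system, closure, admissible triples.

The is_a transitive closure is precomputed once at setup time and persisted
(the CVPath content), so subsumption queries reduce to a single join.  The
admissible-relationship triples play the role of the restriction
entailments a description-logic reasoner would produce for a class
hierarchy with transitive properties: ``(C, R, T)`` is admissible iff some
directed path from C to T uses is_a edges (upward), R edges, and contains
at least one R edge.  Each triple is emitted with a witness path so its
derivation can be audited.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import obonet

from .errors import OntologyError
from .resources import feature_key_table, qualifier_routing_table

RELATIONSHIPS = ("part_of", "member_of", "derives_from")
LOCAL_NAMESPACE = "local"


@dataclass(frozen=True)
class OntologyTerm:
    accession: str
    name: str
    namespace: str = "sequence"
    obsolete: bool = False


@dataclass(frozen=True)
class ClosurePath:
    subject: str
    object: str
    relationship: str = "is_a"
    distance: int = 0


@dataclass(frozen=True)
class AdmissibleTriple:
    subject_type: str
    relationship: str
    object_type: str


@dataclass
class OntologyGraph:
    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    is_a_edges: set[tuple[str, str]] = field(default_factory=set)
    rel_edges: set[tuple[str, str, str]] = field(default_factory=set)  # (subj, rel, obj)
    other_edges: set[tuple[str, str, str]] = field(default_factory=set)  # preserved, inert

    def active_terms(self) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if not t.obsolete]

    def is_a_graph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(t.accession for t in self.active_terms())
        g.add_edges_from(self.is_a_edges)
        return g


def load_obo(obo_stream) -> OntologyGraph:
    """Load an OBO 1.2 flat stream into an OntologyGraph.

    Obsolete terms are kept (flagged) but excluded from edges and closure.
    Relationship types other than part_of/member_of/derives_from are
    preserved but inert.
    """
    if isinstance(obo_stream, str):
        obo_stream = io.StringIO(obo_stream)
    multi = obonet.read_obo(obo_stream, ignore_obsolete=False)
    graph = OntologyGraph()
    for acc, data in multi.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        graph.terms[acc] = OntologyTerm(
            accession=acc,
            name=data.get("name", acc),
            namespace=data.get("namespace", "sequence"),
            obsolete=obsolete,
        )
    for child, parent, rel in multi.edges(keys=True):
        if graph.terms[child].obsolete or graph.terms[parent].obsolete:
            continue
        if rel == "is_a":
            graph.is_a_edges.add((child, parent))
        elif rel in RELATIONSHIPS:
            graph.rel_edges.add((child, rel, parent))
        else:
            graph.other_edges.add((child, rel, parent))
    isa = graph.is_a_graph()
    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise OntologyError(f"is_a graph is cyclic: {' -> '.join(a for a, _ in cycle)}")
    return graph


def compute_is_a_closure(graph: OntologyGraph) -> set[ClosurePath]:
    """Transitive closure of is_a with minimal distances and self-paths."""
    isa = graph.is_a_graph()
    if not nx.is_directed_acyclic_graph(isa):
        raise OntologyError("is_a graph is cyclic")
    closure: set[ClosurePath] = set()
    for node in isa.nodes:
        lengths = nx.single_source_shortest_path_length(isa, node)
        for target, dist in lengths.items():
            closure.add(ClosurePath(subject=node, object=target, distance=dist))
    return closure


def descendants(term: str, closure: Iterable[ClosurePath]) -> set[str]:
    """All accessions subsumed by ``term`` (self included, distance 0)."""
    known = {p.object for p in closure} | {p.subject for p in closure}
    if term not in known:
        raise OntologyError(f"unknown term {term!r}")
    return {p.subject for p in closure if p.object == term}


def _entailment_graph(graph: OntologyGraph, relationship: str) -> "nx.DiGraph":
    """Product graph on (term, flag) pairs where flag marks "the last edge
    taken was an R edge".  is_a edges reset the flag, R edges set it, so
    (C,0) reaching (T,1) certifies a path C -(is_a* R)+-> T: subject-side
    inheritance and R-transitivity (with is_a hops between R edges) are
    allowed, but the path must end on the relationship itself.  Ending on a
    trailing is_a hop would promote every R target to its ancestors (e.g.
    everything part_of some broad region-class term) and admit biologically
    wrong pairs once the runtime check generalizes over the object's
    ancestors."""
    g = nx.DiGraph()
    for t in graph.active_terms():
        g.add_node((t.accession, 0))
        g.add_node((t.accession, 1))
    for child, parent in graph.is_a_edges:
        for flag in (0, 1):
            g.add_edge((child, flag), (parent, 0), rel="is_a")
    for subj, rel, obj in graph.rel_edges:
        if rel == relationship:
            for flag in (0, 1):
                g.add_edge((subj, flag), (obj, 1), rel=relationship)
    return g


def compute_admissible_triples(
    graph: OntologyGraph, relationship: str, with_witnesses: bool = False
):
    """All (C, relationship, T) triples entailed by the ontology.

    When ``with_witnesses`` is true, returns (triples, witnesses) where each
    witness is the node path certifying one triple.
    """
    if relationship not in RELATIONSHIPS:
        raise OntologyError(f"unknown relationship {relationship!r}")
    g = _entailment_graph(graph, relationship)
    triples: set[AdmissibleTriple] = set()
    witnesses: dict[AdmissibleTriple, list[str]] = {}
    for term in graph.active_terms():
        src = (term.accession, 0)
        reachable = nx.descendants(g, src)
        for node, flag in reachable:
            if flag != 1 or node == term.accession:
                continue
            triple = AdmissibleTriple(term.accession, relationship, node)
            triples.add(triple)
            if with_witnesses and triple not in witnesses:
                path = nx.shortest_path(g, src, (node, 1))
                witnesses[triple] = [n for n, _ in path]
    if with_witnesses:
        return triples, witnesses
    return triples


def all_admissible_triples(graph: OntologyGraph) -> set[AdmissibleTriple]:
    out: set[AdmissibleTriple] = set()
    for rel in RELATIONSHIPS:
        out |= compute_admissible_triples(graph, rel)
    return out


# ---------------------------------------------------------------------------
# bundled mapping tables


@dataclass
class FeatureKeyMapping:
    entries: dict[str, str]
    names: dict[str, str]
    fallback_namespace: str = LOCAL_NAMESPACE

    @classmethod
    def bundled(cls) -> "FeatureKeyMapping":
        table = feature_key_table()
        return cls(
            entries={k: acc for k, (acc, _) in table.items()},
            names={k: name for k, (_, name) in table.items()},
        )

    def map_feature_key(self, key: str) -> str:
        """Total mapping: bundled hit -> SO accession; miss -> local term."""
        return self.entries.get(key, f"{self.fallback_namespace}:{key}")


@dataclass(frozen=True)
class QualifierRoute:
    route: str  # annotation | collection | taxonomy | suppressed
    target: str  # column name for collection/taxonomy; term for annotation


@dataclass
class QualifierRouting:
    entries: dict[str, QualifierRoute]

    @classmethod
    def bundled(cls) -> "QualifierRouting":
        return cls(
            entries={
                q: QualifierRoute(route=route, target=target)
                for q, (route, target) in qualifier_routing_table().items()
            }
        )

    def route(self, qualifier: str) -> QualifierRoute:
        """Unknown qualifiers fall back to local-term annotations."""
        return self.entries.get(qualifier, QualifierRoute("annotation", "-"))


def annotation_term(qualifier: str, routing: QualifierRouting) -> str:
    r = routing.route(qualifier)
    if r.route == "annotation" and r.target not in ("-", ""):
        return r.target
    return f"{LOCAL_NAMESPACE}:{qualifier}"


@dataclass
class OntologySnapshot:
    """Everything the ETL needs from the ontology, computed once at setup."""

    graph: OntologyGraph
    closure: set[ClosurePath]
    triples: set[AdmissibleTriple]
    witnesses: dict[AdmissibleTriple, list[str]]
    mapping: FeatureKeyMapping
    routing: QualifierRouting
    name_index: dict[str, str] = field(default_factory=dict)  # term name -> accession
    _up: dict[str, set[str]] = field(default_factory=dict)  # subject -> ancestors incl self
    _down: dict[str, set[str]] = field(default_factory=dict)  # object -> descendants incl self

    def __post_init__(self) -> None:
        for p in self.closure:
            self._up.setdefault(p.subject, set()).add(p.object)
            self._down.setdefault(p.object, set()).add(p.subject)

    @classmethod
    def build(cls, graph: OntologyGraph) -> "OntologySnapshot":
        closure = compute_is_a_closure(graph)
        triples: set[AdmissibleTriple] = set()
        witnesses: dict[AdmissibleTriple, list[str]] = {}
        for rel in RELATIONSHIPS:
            t, w = compute_admissible_triples(graph, rel, with_witnesses=True)
            triples |= t
            witnesses.update(w)
        return cls(
            graph=graph,
            closure=closure,
            triples=triples,
            witnesses=witnesses,
            mapping=FeatureKeyMapping.bundled(),
            routing=QualifierRouting.bundled(),
            name_index={t.name: t.accession for t in graph.active_terms()},
        )

    def ancestors_or_self(self, accession: str) -> set[str]:
        return self._up.get(accession, {accession})

    def is_admissible(self, subject_type: str, relationship: str, object_type: str) -> bool:
        """Runtime admissibility: (Tf, R, Tg) is accepted when a triple
        (Tf, R, A) exists for Tg itself or any is_a ancestor of Tg."""
        for anc in self.ancestors_or_self(object_type):
            if AdmissibleTriple(subject_type, relationship, anc) in self.triples:
                return True
        return False

    def resolve_term(self, term: str) -> str:
        """Accept an accession or a term name; return the accession."""
        if term in self.graph.terms or ":" in term:
            return term
        if term in self.name_index:
            return self.name_index[term]
        raise OntologyError(f"unknown term {term!r}")

    def descendants_or_self(self, accession: str) -> set[str]:
        if accession in self._down:
            return self._down[accession]
        return descendants(accession, self.closure)
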