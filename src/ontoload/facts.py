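"""Working-memory fact templates and statement facts.

The rule engine's working memory is a list of typed facts mirroring the
entry structure: one ``header`` fact, one ``sequence`` fact (length and
presence only — residues never enter working memory, to keep the reasoner
light), then ``key``/``portion``/``qualifier`` facts per feature and
``reference``/``reference_portion`` facts per bibliographic reference.

Its output is an ordered list of ``StatementFact`` rows: symbolic insert /
select statements whose ``count`` identifiers let a later statement cite
the database-generated primary key of an earlier one via ``foreign_counts``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from .errors import StatementError
from .model import Entry
from .ontology import FeatureKeyMapping

TEMPLATES = (
    "header",
    "sequence",
    "key",
    "portion",
    "qualifier",
    "reference",
    "reference_portion",
)


@dataclass(frozen=True)
class Fact:
    template: str
    slots: tuple[tuple[str, Any], ...]

    def __getitem__(self, name: str) -> Any:
        for k, v in self.slots:
            if k == name:
                return v
        raise KeyError(name)

    def get(self, name: str, default: Any = None) -> Any:
        try:
            return self[name]
        except KeyError:
            return default


def _fact(template: str, **slots: Any) -> Fact:
    return Fact(template=template, slots=tuple(slots.items()))


@dataclass(frozen=True)
class RelationshipFact:
    subject: int  # feature id within entry
    relationship: str
    object: int
    provenance: str = ""


@dataclass
class StatementFact:
    kind: str  # insert | upsert | select
    count: int
    table_name: str
    column_names: list[str]
    column_values: list[Any]
    foreign_counts: list[int] = field(default_factory=list)
    foreign_columns: list[str] = field(default_factory=list)


# Domain-expert type refinements: qualifier evidence that narrows a mapped
# term to a more specific ontology class than the feature key alone implies.
_GENE, _MITO_GENE = "SO:0000704", "SO:0000088"
_TF_BINDING_SITE = "SO:0000235"


def _refine_term(feature, base_term: str, organelle: str) -> str:
    if base_term == _GENE and organelle.lower().startswith("mitochondri"):
        return _MITO_GENE
    if feature.key == "protein_bind" and any(
        "transcription factor" in v.lower()
        for v in feature.qualifier_values("bound_moiety")
    ):
        return _TF_BINDING_SITE
    return base_term


def entry_to_facts(entry: Entry, mapping: FeatureKeyMapping) -> list[Fact]:
    """Serialize a parsed entry into working-memory facts.

    Feature ids are the feature ranks; portion/qualifier facts reference
    their feature through that id.  Mapped terms are refined by qualifier
    evidence (e.g. a gene on a mitochondrial source becomes a
    mitochondrial gene).
    """
    h = entry.header
    organelle = ""
    for feat in entry.features:
        if feat.key == "source":
            vals = feat.qualifier_values("organelle")
            if vals:
                organelle = vals[0]
            break
    facts: list[Fact] = [
        _fact(
            "header",
            locus_name=h.locus_name,
            sequence_length=h.sequence_length,
            molecule_type=h.molecule_type,
            topology=h.topology,
            division_code=h.division_code,
            modification_date=h.modification_date,
            definition=h.definition,
            accession=h.accession,
            version=h.version,
            gi=h.gi,
            keywords=tuple(h.keywords),
            organism_name=h.organism_name,
            lineage=tuple(h.lineage),
        ),
        _fact("sequence", length=h.sequence_length, present=bool(entry.sequence)),
    ]
    for feat in entry.features:
        facts.append(
            _fact(
                "key",
                feature_id=feat.rank,
                key=feat.key,
                term=_refine_term(feat, mapping.map_feature_key(feat.key), organelle),
                rank=feat.rank,
                unknown=feat.unknown_key,
                location_operator=feat.location_operator,
            )
        )
        for p in feat.portions:
            facts.append(
                _fact(
                    "portion",
                    feature_id=feat.rank,
                    start=p.start,
                    end=p.end,
                    strand=p.strand,
                    partial5=p.partial5,
                    partial3=p.partial3,
                    between_bases=p.between_bases,
                    remote_accession=p.remote_accession,
                    rank=p.rank,
                )
            )
        for q in feat.qualifiers:
            facts.append(_fact("qualifier", feature_id=feat.rank, name=q.name, value=q.value))
    for ref in entry.references:
        facts.append(
            _fact(
                "reference",
                ordinal=ref.ordinal,
                authors=ref.authors,
                title=ref.title,
                journal=ref.journal,
                pubmed_id=ref.pubmed_id,
            )
        )
        for start, end in ref.cited_ranges:
            facts.append(_fact("reference_portion", ordinal=ref.ordinal, start=start, end=end))
    return facts


def validate_statements(statements: list[StatementFact]) -> None:
    """Check the statement-list contract: strictly increasing counts and
    every foreign_count citing an earlier statement."""
    seen: set[int] = set()
    last = None
    for st in statements:
        if last is not None and st.count <= last:
            raise StatementError(f"counts not strictly increasing at {st.count}")
        if len(st.foreign_counts) != len(st.foreign_columns):
            raise StatementError(f"statement {st.count}: foreign multislots misaligned")
        for fc in st.foreign_counts:
            if fc not in seen:
                raise StatementError(
                    f"statement {st.count} cites count {fc} which does not precede it"
                )
        for col in st.foreign_columns:
            if col not in st.column_names:
                raise StatementError(
                    f"statement {st.count}: foreign column {col!r} not in column list"
                )
        seen.add(st.count)
        last = st.count
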