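"""Structured representation of a GenBank flat-file entry.

Coordinates are kept exactly as they appear in the flat file: 1-based,
inclusive on both ends.  (Chado proper uses interbase coordinates; we
prioritise flat-file fidelity and convert nowhere.)
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class RawEntrySections:
    """The four textual sections of one entry, in file order."""

    header_text: str
    references_text: str
    features_text: str
    sequence_text: str


@dataclass
class Header:
    locus_name: str
    sequence_length: int
    molecule_type: str
    topology: str  # "linear" | "circular"
    division_code: str
    modification_date: str
    definition: str = ""
    accession: str = ""
    version: str = ""
    gi: Optional[int] = None
    keywords: list[str] = field(default_factory=list)
    organism_name: str = ""
    lineage: list[str] = field(default_factory=list)


@dataclass
class Reference:
    ordinal: int
    cited_ranges: list[tuple[int, int]]
    authors: str = ""
    title: str = ""
    journal: str = ""
    pubmed_id: Optional[int] = None


@dataclass
class LocationPortion:
    start: int
    end: int
    strand: str = FORWARD
    partial5: bool = False
    partial3: bool = False
    between_bases: bool = False
    remote_accession: Optional[str] = None
    rank: int = 0

    def __post_init__(self) -> None:
        if self.between_bases:
            if self.end != self.start + 1:
                raise ValueError(
                    f"between-bases portion must span adjacent bases: {self.start}^{self.end}"
                )
        elif self.start > self.end:
            raise ValueError(f"portion start {self.start} > end {self.end}")


@dataclass
class Qualifier:
    name: str
    value: Optional[str] = None  # None for flag qualifiers like /germline


@dataclass
class Feature:
    key: str
    portions: list[LocationPortion]
    qualifiers: list[Qualifier] = field(default_factory=list)
    rank: int = 0
    location_operator: Optional[str] = None  # "order" when order() was used
    unknown_key: bool = False
    inferred: bool = False

    def qualifier_values(self, name: str) -> list[str]:
        return [q.value for q in self.qualifiers if q.name == name and q.value is not None]

    def span(self, include_remote: bool = False) -> tuple[int, int]:
        """[min start, max end] over local portions (remote excluded by default)."""
        ports = [p for p in self.portions if include_remote or p.remote_accession is None]
        if not ports:
            ports = self.portions
        return min(p.start for p in ports), max(p.end for p in ports)

    def strand(self) -> Optional[str]:
        """Uniform strand of local portions, or None when mixed/absent."""
        strands = {p.strand for p in self.portions if p.remote_accession is None}
        if len(strands) == 1:
            return next(iter(strands))
        return None


@dataclass
class Entry:
    header: Header
    references: list[Reference]
    features: list[Feature]
    sequence: str = ""

    @property
    def gi(self) -> Optional[int]:
        return self.header.gi

    @property
    def accession(self) -> str:
        return self.header.accession
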