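"""GenBank flat-file parsing (FTv8 dialect).

The reader is streaming: ``index_entries``/``iter_entry_texts`` hold at most
one entry in memory at a time, so memory is bounded by the largest entry,
not the file.  Parsing itself is regular expressions plus small
content-specific functions; the feature-location grammar gets a recursive
descent parser.
"""
from __future__ import annotations

import logging
import re
from typing import Iterator, Optional

from .errors import IndexingError, LocationParseError, ParseError
from .model import (
    FORWARD,
    REVERSE,
    Entry,
    Feature,
    Header,
    LocationPortion,
    Qualifier,
    RawEntrySections,
)
from .resources import feature_key_table

log = logging.getLogger(__name__)

_LOCUS_RE = re.compile(
    r"^LOCUS\s+(?P<name>\S+)\s+(?P<length>\d+)\s+bp\s+"
    r"(?P<mol>\S+)?\s*(?P<topo>linear|circular)?\s*"
    r"(?P<div>[A-Z]{3})?\s*(?P<date>\d{2}-[A-Z]{3}-\d{4})?\s*$"
)
_VERSION_RE = re.compile(r"^VERSION\s+(?P<version>\S+)(?:\s+GI:(?P<gi>\d+))?\s*$")
_GI_RE = re.compile(r"\bGI:(\d+)")
_REFHEAD_RE = re.compile(r"^REFERENCE\s+(?P<ordinal>\d+)(?:\s+\((?P<clause>[^)]*)\))?")
_BASES_RE = re.compile(r"(\d+)\s+to\s+(\d+)")
_QUALSTART_RE = re.compile(r"^/(?P<name>[A-Za-z_][\w'\-]*)(?:=(?P<value>.*))?$", re.S)


# ---------------------------------------------------------------------------
# indexing and streaming


def index_entries(path) -> list[tuple[int, int, int]]:
    """Scan a flat file and return (header_offset, sequence_offset, gi) per entry.

    header_offset is the byte position of the LOCUS line; sequence_offset the
    byte position of the first sequence line after ORIGIN (the line holding
    the first nucleotide).  The gi comes from the VERSION line.
    """
    records: list[tuple[int, int, int]] = []
    offset = 0
    locus_offset: Optional[int] = None
    seq_offset: Optional[int] = None
    gi: Optional[int] = None
    pending_origin = False
    with open(path, "rb") as fh:
        for raw in fh:
            line = raw.decode("ascii", errors="replace")
            if pending_origin:
                seq_offset = offset
                pending_origin = False
            if line.startswith("LOCUS"):
                locus_offset = offset
                seq_offset = None
                gi = None
            elif line.startswith("VERSION") and locus_offset is not None:
                m = _GI_RE.search(line)
                if m:
                    gi = int(m.group(1))
            elif line.startswith("ORIGIN") and locus_offset is not None:
                pending_origin = True
            elif line.startswith("//"):
                if locus_offset is None:
                    raise IndexingError(
                        f"entry terminator at byte {offset} with no preceding LOCUS line"
                    )
                if gi is None:
                    raise IndexingError(
                        f"entry at byte {locus_offset} has no GI on its VERSION line"
                    )
                records.append((locus_offset, seq_offset if seq_offset is not None else -1, gi))
                locus_offset = None
            offset += len(raw)
    if locus_offset is not None:
        raise IndexingError(f"unterminated entry starting at byte {locus_offset} (no //)")
    return records


def iter_entry_texts(path) -> Iterator[str]:
    """Yield the text of each LOCUS..// entry, one at a time."""
    buf: list[str] = []
    inside = False
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for line in fh:
            if line.startswith("LOCUS"):
                inside = True
                buf = [line]
            elif inside:
                buf.append(line)
                if line.startswith("//"):
                    yield "".join(buf)
                    inside = False
                    buf = []
    if inside:
        raise IndexingError("unterminated final entry (no //)")


def read_entry_at(path, header_offset: int) -> str:
    """Read one entry's text starting at a previously indexed seek offset."""
    lines = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        fh.seek(header_offset)
        for line in fh:
            lines.append(line)
            if line.startswith("//"):
                break
    if not lines or not lines[0].startswith("LOCUS"):
        raise IndexingError(f"offset {header_offset} does not address a LOCUS line")
    return "".join(lines)


# ---------------------------------------------------------------------------
# section split


def split_entry(entry_text: str) -> RawEntrySections:
    """Localize the four sections: header, references, features, sequence."""
    lines = entry_text.splitlines(keepends=True)
    if not lines or not lines[0].startswith("LOCUS"):
        raise ParseError("header: entry does not begin with a LOCUS line")
    ref_i = feat_i = origin_i = None
    for i, line in enumerate(lines):
        if ref_i is None and line.startswith("REFERENCE"):
            ref_i = i
        if feat_i is None and line.startswith("FEATURES"):
            feat_i = i
        if line.startswith("ORIGIN"):
            origin_i = i
            break
    if origin_i is None:
        raise ParseError("sequence: entry has no ORIGIN line")
    if not any(l.startswith("//") for l in lines[origin_i:]):
        raise ParseError("sequence: entry has no // terminator")
    header_end = ref_i if ref_i is not None else (feat_i if feat_i is not None else origin_i)
    ref_end = feat_i if feat_i is not None else origin_i
    return RawEntrySections(
        header_text="".join(lines[:header_end]),
        references_text="".join(lines[ref_i:ref_end]) if ref_i is not None else "",
        features_text="".join(lines[feat_i:origin_i]) if feat_i is not None else "",
        sequence_text="".join(lines[origin_i:]),
    )


# ---------------------------------------------------------------------------
# header


def _fold_keyword_blocks(text: str) -> dict[str, str]:
    """Group header lines by their leading keyword (continuations indented)."""
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        m = re.match(r"^(\s*)([A-Z]+)\b(.*)$", line)
        if m and m.group(1) == "" and line[:1] != " ":
            current = m.group(2)
            blocks.setdefault(current, []).append(m.group(3).strip())
        elif re.match(r"^  [A-Z]+\b", line):  # sub-keyword, e.g. ORGANISM
            current = line.strip().split()[0]
            rest = line.strip()[len(current):].strip()
            blocks.setdefault(current, []).append(rest)
        elif current is not None:
            blocks.setdefault(current, []).append(line.strip())
    return {k: "\n".join(v).strip() for k, v in blocks.items()}


def parse_header(header_text: str) -> Header:
    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("LOCUS"):
        raise ParseError("header: missing LOCUS line")
    m = _LOCUS_RE.match(lines[0])
    if not m:
        raise ParseError(f"header: unparseable LOCUS line: {lines[0]!r}")
    blocks = _fold_keyword_blocks(header_text)
    version = ""
    gi = None
    if "VERSION" in blocks:
        vm = _VERSION_RE.match("VERSION  " + blocks["VERSION"].replace("\n", " "))
        if vm:
            version = vm.group("version")
            gi = int(vm.group("gi")) if vm.group("gi") else None
    keywords: list[str] = []
    if "KEYWORDS" in blocks:
        kw = blocks["KEYWORDS"].replace("\n", " ").strip().rstrip(".")
        keywords = [k.strip() for k in kw.split(";") if k.strip()]
    organism_name = ""
    lineage: list[str] = []
    if "ORGANISM" in blocks:
        org_lines = blocks["ORGANISM"].split("\n")
        organism_name = org_lines[0].strip()
        lineage_text = " ".join(org_lines[1:]).strip().rstrip(".")
        lineage = [t.strip() for t in lineage_text.split(";") if t.strip()]
    return Header(
        locus_name=m.group("name"),
        sequence_length=int(m.group("length")),
        molecule_type=m.group("mol") or "",
        topology=m.group("topo") or "linear",
        division_code=m.group("div") or "",
        modification_date=m.group("date") or "",
        definition=(blocks.get("DEFINITION", "").replace("\n", " ").strip()),
        accession=blocks.get("ACCESSION", "").split()[0] if blocks.get("ACCESSION") else "",
        version=version,
        gi=gi,
        keywords=keywords,
        organism_name=organism_name,
        lineage=lineage,
    )


# ---------------------------------------------------------------------------
# references


def parse_references(references_text: str, sequence_length: Optional[int] = None) -> list:
    """Parse REFERENCE blocks; a block without a parsable base clause is
    assigned the whole-entry range when the sequence length is known."""
    from .model import Reference  # local to keep module import order flat

    refs = []
    block: list[str] = []
    blocks: list[list[str]] = []
    for line in references_text.splitlines():
        if line.startswith("REFERENCE"):
            if block:
                blocks.append(block)
            block = [line]
        elif block:
            block.append(line)
    if block:
        blocks.append(block)
    for blines in blocks:
        m = _REFHEAD_RE.match(blines[0])
        if not m:
            raise ParseError(f"references: unparseable REFERENCE line: {blines[0]!r}")
        ordinal = int(m.group("ordinal"))
        clause = m.group("clause") or ""
        ranges = [(int(a), int(b)) for a, b in _BASES_RE.findall(clause)]
        if not ranges:
            if sequence_length:
                ranges = [(1, sequence_length)]
                log.warning("reference %d has no base clause; whole-entry range assumed", ordinal)
        fields = _fold_keyword_blocks("\n".join(blines))
        pubmed = None
        if fields.get("PUBMED"):
            try:
                pubmed = int(fields["PUBMED"].split()[0])
            except ValueError:
                pubmed = None
        refs.append(
            Reference(
                ordinal=ordinal,
                cited_ranges=ranges,
                authors=fields.get("AUTHORS", "").replace("\n", " "),
                title=fields.get("TITLE", "").replace("\n", " "),
                journal=fields.get("JOURNAL", "").replace("\n", " "),
                pubmed_id=pubmed,
            )
        )
    return refs


# ---------------------------------------------------------------------------
# feature locations (recursive descent over the FTv8 location grammar)

_POINT_RE = re.compile(r"^(\d+)$")
_RANGE_RE = re.compile(r"^(?P<p5><?)(?P<start>\d+)\.\.(?P<p3>>?)(?P<end>\d+)$")
_BETWEEN_RE = re.compile(r"^(\d+)\^(\d+)$")
_REMOTE_RE = re.compile(r"^(?P<acc>[A-Za-z][A-Za-z0-9_]*(?:\.\d+)?):(?P<rest>.+)$")


def _split_top_level(text: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise LocationParseError(f"unbalanced parentheses in {text!r}")
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise LocationParseError(f"unbalanced parentheses in {text!r}")
    parts.append("".join(cur))
    return parts


def _parse_simple(text: str, remote: Optional[str] = None) -> LocationPortion:
    m = _RANGE_RE.match(text)
    if m:
        return LocationPortion(
            start=int(m.group("start")),
            end=int(m.group("end")),
            partial5=bool(m.group("p5")),
            partial3=bool(m.group("p3")),
            remote_accession=remote,
        )
    m = _POINT_RE.match(text)
    if m:
        n = int(m.group(1))
        return LocationPortion(start=n, end=n, remote_accession=remote)
    m = _BETWEEN_RE.match(text)
    if m:
        a, b = int(m.group(1)), int(m.group(2))
        if b != a + 1:
            raise LocationParseError(f"between-bases location must be adjacent: {text!r}")
        return LocationPortion(start=a, end=b, between_bases=True, remote_accession=remote)
    raise LocationParseError(f"unparseable location element: {text!r}")


def _parse_expr(text: str, in_complement: bool) -> tuple[list[LocationPortion], Optional[str]]:
    text = text.strip()
    op: Optional[str] = None
    if text.startswith("complement(") and text.endswith(")"):
        if in_complement:
            raise LocationParseError(f"nested complement() rejected: {text!r}")
        inner, op = _parse_expr(text[len("complement("):-1], True)
        for p in inner:
            p.strand = REVERSE if p.strand == FORWARD else FORWARD
        return inner, op
    for name in ("join", "order"):
        prefix = name + "("
        if text.startswith(prefix) and text.endswith(")"):
            portions: list[LocationPortion] = []
            for part in _split_top_level(text[len(prefix):-1]):
                sub, sub_op = _parse_expr(part, in_complement)
                portions.extend(sub)
                if sub_op == "order":
                    name = "order"
            return portions, (op if name == "join" else "order")
    if text.startswith(("join", "order", "complement")):
        raise LocationParseError(f"malformed operator expression: {text!r}")
    m = _REMOTE_RE.match(text)
    if m:
        return [_parse_simple(m.group("rest"), remote=m.group("acc"))], None
    if re.match(r"^[A-Za-z]", text):
        raise LocationParseError(f"unknown location operator in {text!r}")
    return [_parse_simple(text)], None


def parse_location_full(location_text: str) -> tuple[list[LocationPortion], Optional[str]]:
    """Parse a location string; returns portions (ranked in textual order)
    and the location operator annotation ("order" or None)."""
    if not location_text.strip():
        raise LocationParseError("empty location string")
    portions, op = _parse_expr(location_text, False)
    for rank, p in enumerate(portions):
        p.rank = rank
    return portions, op


def parse_location(location_text: str) -> list[LocationPortion]:
    return parse_location_full(location_text)[0]


# ---------------------------------------------------------------------------
# feature table

_FEATKEY_RE = re.compile(r"^ {5}(?P<key>\S+)\s+(?P<loc>\S.*)$")
_CONT_RE = re.compile(r"^ {21}(?P<body>.*)$")


def parse_feature_table(features_text: str) -> list[Feature]:
    """Parse a FEATURES block into Feature objects (file order, rank 0..n-1)."""
    known_keys = feature_key_table()
    features: list[Feature] = []
    cur_key: Optional[str] = None
    cur_loc: list[str] = []
    cur_quals: list[tuple[str, Optional[str], bool]] = []  # (name, raw value, quoted)

    def finish_qualifiers() -> list[Qualifier]:
        quals = []
        for name, raw, quoted in cur_quals:
            if raw is None:
                quals.append(Qualifier(name=name, value=None))
                continue
            value = raw
            if quoted:
                value = value.strip()
                if value.startswith('"'):
                    value = value[1:]
                if value.endswith('"'):
                    value = value[:-1]
                value = value.replace('""', '"')
            quals.append(Qualifier(name=name, value=value))
        return quals

    def finish_feature() -> None:
        nonlocal cur_key, cur_loc, cur_quals
        if cur_key is None:
            return
        loc_text = "".join(s.strip() for s in cur_loc)
        portions, op = parse_location_full(loc_text)
        features.append(
            Feature(
                key=cur_key,
                portions=portions,
                qualifiers=finish_qualifiers(),
                rank=len(features),
                location_operator=op,
                unknown_key=cur_key not in known_keys,
            )
        )
        cur_key, cur_loc, cur_quals = None, [], []

    open_quote = False
    for line in features_text.splitlines():
        if line.startswith("FEATURES") or not line.strip():
            continue
        mk = _FEATKEY_RE.match(line)
        if mk and not line.startswith(" " * 21):
            finish_feature()
            cur_key = mk.group("key")
            cur_loc = [mk.group("loc")]
            open_quote = False
            continue
        mc = _CONT_RE.match(line)
        body = mc.group("body") if mc else line.strip()
        qm = _QUALSTART_RE.match(body) if body.startswith("/") else None
        if qm and not open_quote:
            if cur_key is None:
                raise ParseError(f"features: qualifier line before any feature key: {line!r}")
            raw = qm.group("value")
            quoted = raw is not None and raw.startswith('"')
            if quoted:
                open_quote = raw.count('"') % 2 == 1
            cur_quals.append((qm.group("name"), raw, quoted))
        else:
            if cur_key is None:
                raise ParseError(f"features: continuation before any feature key: {line!r}")
            if cur_quals:
                name, raw, quoted = cur_quals[-1]
                sep = "" if name == "translation" else " "
                new_raw = (raw or "") + sep + body.strip()
                cur_quals[-1] = (name, new_raw, quoted)
                open_quote = quoted and new_raw.count('"') % 2 == 1
            else:
                cur_loc.append(body)
    finish_feature()
    return features


# ---------------------------------------------------------------------------
# whole entry


def extract_sequence(sequence_text: str) -> str:
    """Residue letters from an ORIGIN block, digits/spacing stripped."""
    seq = []
    for line in sequence_text.splitlines():
        if line.startswith("ORIGIN") or line.startswith("//"):
            continue
        seq.append(re.sub(r"[\d\s]", "", line))
    return "".join(seq).lower()


def parse_entry(entry_text: str) -> Entry:
    sections = split_entry(entry_text)
    header = parse_header(sections.header_text)
    try:
        references = parse_references(sections.references_text, header.sequence_length)
        features = parse_feature_table(sections.features_text)
    except ParseError as exc:
        raise ParseError(f"entry GI:{header.gi}: {exc}") from exc
    sequence = extract_sequence(sections.sequence_text)
    if sequence and len(sequence) != header.sequence_length:
        log.warning(
            "entry GI:%s sequence length %d != LOCUS declaration %d",
            header.gi, len(sequence), header.sequence_length,
        )
    return Entry(header=header, references=references, features=features, sequence=sequence)
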