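"""Synthetic flat files and a mini ontology fragment with known ground truth.

Every generated file comes with a manifest that records the planted truth
(header fields, features, portions, qualifiers, relationship tree, intron
intervals, reference ranges, byte offsets), which downstream tests treat
as the single source of truth for round-trip and inference assertions.

The generator emulates a controlled dataset: small entries with
pre-established characteristics covering every bundled feature key and
qualifier, nested gene models for relationship recovery, reference-heavy
entries, and adversarial location grammar.  It does not emulate realistic
sequence composition or taxonomic distributions.
"""
from __future__ import annotations

import random
from typing import Any, Optional

from .errors import OntoloadError
from .resources import feature_key_table, qualifier_routing_table

PROFILES = (
    "minimal",
    "nested_gene_models",
    "reference_rich",
    "key_coverage",
    "qualifier_coverage",
    "adversarial",
)

FORWARD, REVERSE = "forward", "reverse"

# ---------------------------------------------------------------------------
# mini ontology fragment

_MINI_SO_TERMS = [
    # (accession, name, is_a parents)
    ("SO:0000110", "sequence_feature", []),
    ("SO:0000001", "region", ["SO:0000110"]),
    ("SO:0005836", "regulatory_region", ["SO:0000001"]),
    ("SO:0000167", "promoter", ["SO:0005836"]),
    ("SO:0000551", "polyA_signal_sequence", ["SO:0005836"]),
    ("SO:0000235", "TF_binding_site", ["SO:0005836"]),
    ("SO:0000141", "terminator", ["SO:0005836"]),
    ("SO:0000165", "enhancer", ["SO:0005836"]),
    ("SO:0000139", "ribosome_entry_site", ["SO:0005836"]),
    ("SO:0000174", "TATA_box", ["SO:0005836"]),
    ("SO:0000704", "gene", ["SO:0000001"]),
    ("SO:0000088", "mitochondrial_gene", ["SO:0000704"]),
    ("SO:0000673", "transcript", ["SO:0000001"]),
    ("SO:0000234", "mRNA", ["SO:0000673"]),
    ("SO:0000185", "primary_transcript", ["SO:0000673"]),
    ("SO:0000655", "ncRNA", ["SO:0000673"]),
    ("SO:0000252", "rRNA", ["SO:0000655"]),
    ("SO:0000253", "tRNA", ["SO:0000655"]),
    ("SO:0000147", "exon", ["SO:0000001"]),
    ("SO:0000195", "coding_exon", ["SO:0000147"]),
    ("SO:0000316", "CDS", ["SO:0000001"]),
    ("SO:0000188", "intron", ["SO:0000001"]),
    ("SO:0000204", "five_prime_UTR", ["SO:0000001"]),
    ("SO:0000205", "three_prime_UTR", ["SO:0000001"]),
    ("SO:0000419", "mature_protein_region", ["SO:0000001"]),
    ("SO:0000418", "signal_peptide", ["SO:0000001"]),
    ("SO:2000061", "databank_entry", ["SO:0000001"]),
    ("SO:0000657", "repeat_region", ["SO:0000001"]),
    ("SO:0000296", "origin_of_replication", ["SO:0000001"]),
    ("SO:0000313", "stem_loop", ["SO:0000001"]),
    ("SO:0000553", "polyA_site", ["SO:0000001"]),
]

_MINI_SO_OBSOLETE = [("SO:9999999", "retired_term")]

_MINI_SO_RELS = [
    # (subject, relationship, object)
    ("SO:0000147", "part_of", "SO:0000673"),  # exon part_of transcript
    ("SO:0000188", "part_of", "SO:0000673"),  # intron part_of transcript
    ("SO:0000188", "part_of", "SO:0000316"),  # intron part_of CDS (flattened)
    ("SO:0000673", "part_of", "SO:0000704"),  # transcript part_of gene
    ("SO:0000316", "part_of", "SO:0000234"),  # CDS part_of mRNA
    ("SO:0000204", "part_of", "SO:0000234"),  # five_prime_UTR part_of mRNA
    ("SO:0000205", "part_of", "SO:0000234"),  # three_prime_UTR part_of mRNA
    ("SO:0000553", "part_of", "SO:0000673"),  # polyA_site part_of transcript
    ("SO:0005836", "member_of", "SO:0000704"),  # regulatory_region member_of gene
    ("SO:0000419", "derives_from", "SO:0000316"),  # mat peptide derives_from CDS
    ("SO:0000418", "derives_from", "SO:0000316"),  # signal peptide derives_from CDS
]


def _brute_force_closure(edges: list[tuple[str, str]], nodes: list[str]) -> set[tuple[str, str]]:
    """Independent reachability oracle: plain DFS, self-pairs included."""
    adj: dict[str, list[str]] = {}
    for child, parent in edges:
        adj.setdefault(child, []).append(parent)
    pairs: set[tuple[str, str]] = set()
    for start in nodes:
        stack, seen = [start], {start}
        while stack:
            cur = stack.pop()
            pairs.add((start, cur))
            for nxt in adj.get(cur, []):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
    return pairs


def generate_mini_so(seed: int = 0) -> tuple[str, dict[str, Any]]:
    """Deterministic ~30-term ontology fragment as OBO text plus manifest."""
    del seed  # the fragment is fixed; the signature mirrors the entry generator
    lines = ["format-version: 1.2", "ontology: mini-so", ""]
    names = {acc: name for acc, name, _ in _MINI_SO_TERMS}
    for acc, name, parents in _MINI_SO_TERMS:
        lines += [f"[Term]", f"id: {acc}", f"name: {name}"]
        for p in parents:
            lines.append(f"is_a: {p} ! {names[p]}")
        for s, rel, o in _MINI_SO_RELS:
            if s == acc:
                lines.append(f"relationship: {rel} {o} ! {names[o]}")
        lines.append("")
    for acc, name in _MINI_SO_OBSOLETE:
        lines += ["[Term]", f"id: {acc}", f"name: {name}", "is_obsolete: true", ""]
    is_a_edges = [(acc, p) for acc, _, parents in _MINI_SO_TERMS for p in parents]
    nodes = [acc for acc, _, _ in _MINI_SO_TERMS]
    closure = _brute_force_closure(is_a_edges, nodes)
    manifest = {
        "term_count": len(_MINI_SO_TERMS),
        "obsolete_count": len(_MINI_SO_OBSOLETE),
        "is_a_edge_count": len(is_a_edges),
        "rel_edge_count": len(_MINI_SO_RELS),
        "closure_pairs": sorted(map(list, closure)),
        "regulatory_region_children": [
            "SO:0000551", "SO:0000235", "SO:0000141", "SO:0000167",
            "SO:0000165", "SO:0000139", "SO:0000174",
        ],
    }
    return "\n".join(lines), manifest


# ---------------------------------------------------------------------------
# entry plans

_SPECIAL_QUALIFIER_VALUES = {
    "codon_start": "1",
    "transl_table": "11",
    "db_xref": "taxon:32644",
    "translation": "MKVLITTSWAARDGELKNMPFW",
    "lat_lon": "41.90 N 12.49 E",
    "collection_date": "12-Mar-2008",
    "country": "Italy: Bari",
    "estimated_length": "120",
    "number": "1",
    "direction": "left",
    "frequency": "0.5",
    "mol_type": "genomic DNA",
    "organism": "Synthetica exempli",
    "anticodon": "(pos:34..36,aa:Met)",
    "rpt_type": "tandem",
    "compare": "AJ634150.1",
    "citation": "[1]",
}

_FLAG_QUALIFIERS = {
    "germline", "pseudo", "partial", "proviral", "focus", "macronuclear",
    "rearranged", "ribosomal_slippage", "trans_splicing", "transgenic",
    "environmental_sample", "virion",
}


def _qual_value(name: str, i: int) -> Optional[str]:
    if name in _FLAG_QUALIFIERS:
        return None
    if name in _SPECIAL_QUALIFIER_VALUES:
        return _SPECIAL_QUALIFIER_VALUES[name]
    return f"{name} value {i}"


def _portion(start: int, end: int, strand: str = FORWARD, p5=False, p3=False,
             between=False, remote: Optional[str] = None) -> list:
    return [start, end, strand, bool(p5), bool(p3), bool(between), remote]


def _loc_text(portions: list[list], operator: Optional[str] = None) -> str:
    """Render portions back to FTv8 location text."""
    parts = []
    for start, end, _strand, p5, p3, between, remote in portions:
        if between:
            body = f"{start}^{end}"
        elif start == end and not (p5 or p3):
            body = f"{start}"
        else:
            body = f"{'<' if p5 else ''}{start}..{'>' if p3 else ''}{end}"
        if remote:
            body = f"{remote}:{body}"
        parts.append(body)
    reverse = portions[0][2] == REVERSE
    inner = ",".join(parts)
    if len(parts) > 1:
        inner = f"{operator or 'join'}({inner})"
    if reverse:
        inner = f"complement({inner})"
    return inner


def _feature(key: str, portions: list[list], qualifiers: list[list],
             operator: Optional[str] = None) -> dict:
    return {
        "key": key,
        "portions": portions,
        "qualifiers": qualifiers,
        "operator": operator,
        "location": _loc_text(portions, operator),
    }


def _source_feature(length: int, extra: Optional[list[list]] = None) -> dict:
    quals = [
        ["organism", "Synthetica exempli"],
        ["mol_type", "genomic DNA"],
        ["db_xref", "taxon:32644"],
    ] + (extra or [])
    return _feature("source", [_portion(1, length)], quals)


def _base_plan(gi: int, length: int, division: str = "PLN") -> dict:
    acc = f"SYN{gi}"
    return {
        "gi": gi,
        "accession": acc,
        "version": f"{acc}.1",
        "locus_name": acc,
        "length": length,
        "molecule_type": "DNA",
        "topology": "linear",
        "division": division,
        "date": "15-JAN-2010",
        "definition": f"Synthetica exempli synthetic fixture entry {acc}.",
        "keywords": [],
        "organism": "Synthetica exempli",
        "lineage": ["Eukaryota", "Viridiplantae", "Synthetaceae"],
        "references": [],
        "features": [],
        "relationships": [],
        "introns": [],
    }


def _whole_entry_reference(ordinal: int, length: int, pubmed: Optional[int] = None) -> dict:
    return {
        "ordinal": ordinal,
        "ranges": [[1, length]],
        "no_clause": False,
        "authors": "Doe,J. and Roe,R.",
        "title": "Synthetic fixture entry",
        "journal": "Unpublished",
        "pubmed": pubmed,
    }


def _plan_minimal(rng: random.Random, i: int, gi: int) -> dict:
    length = rng.randint(100, 400)
    plan = _base_plan(gi, length)
    plan["references"] = [_whole_entry_reference(1, length)]
    plan["features"] = [_source_feature(length)]
    return plan


def _plan_nested(rng: random.Random, i: int, gi: int) -> dict:
    length = rng.randint(1200, 3000)
    plan = _base_plan(gi, length)
    reverse = rng.random() < 0.5
    strand = REVERSE if reverse else FORWARD
    gene_name = f"abc{i:03d}"
    locus_tag = f"SYN_{gi}"
    protein_id = f"SYP{gi}.1"

    p_start = rng.randint(2, 30)
    p_end = p_start + rng.randint(20, 60)
    n_exons = rng.randint(2, 3)
    exons = []
    cursor = p_end + rng.randint(20, 60)
    for _ in range(n_exons):
        e_len = rng.randint(80, 200)
        exons.append((cursor, cursor + e_len - 1))
        cursor += e_len + rng.randint(50, 150)
    gene_start = max(1, p_start - rng.randint(0, 1))
    gene_end = min(length, exons[-1][1] + rng.randint(10, 40))

    cds_start = exons[0][0] + 3 * rng.randint(3, 9)
    cds_end = exons[-1][1] - 3 * rng.randint(3, 9)
    cds_portions = [(cds_start, exons[0][1])] + exons[1:-1] + [(exons[-1][0], cds_end)]

    def ports(pairs):
        return [_portion(s, e, strand) for s, e in pairs]

    product = "VP35" if i == 0 else f"P{i:04d}"
    with_matpep = rng.random() < 0.5
    mito = i % 4 == 1  # source /organelle refines the gene's type downstream
    source_extra = [["country", "Italy: Bari"]]
    if mito:
        source_extra.append(["organelle", "mitochondrion"])
    features = [
        _source_feature(length, extra=source_extra),
        _feature("promoter", ports([(p_start, p_end)]), [["gene", gene_name]]),
        _feature("gene", ports([(gene_start, gene_end)]),
                 [["gene", gene_name], ["locus_tag", locus_tag]]),
        _feature("mRNA", ports(exons),
                 [["gene", gene_name], ["product", f"{product} mRNA"]]),
        _feature("CDS", ports(cds_portions),
                 [["gene", gene_name], ["product", product],
                  ["protein_id", protein_id], ["codon_start", "1"]]),
    ]
    for j, (s, e) in enumerate(exons):
        features.append(
            _feature("exon", ports([(s, e)]), [["gene", gene_name], ["number", str(j + 1)]])
        )
    relationships = [
        [1, "member_of", 2],  # promoter member_of gene
        [3, "part_of", 2],    # mRNA part_of gene
        [4, "part_of", 3],    # CDS part_of mRNA (minimal containing span)
    ]
    for j in range(n_exons):
        relationships.append([5 + j, "part_of", 3])  # exon part_of mRNA
    if with_matpep:
        mp_start = cds_start + 3
        mp_end = min(exons[0][1], mp_start + 60)
        features.append(
            _feature("mat_peptide", ports([(mp_start, mp_end)]),
                     [["protein_id", protein_id], ["product", f"{product} peptide"]])
        )
        relationships.append([len(features) - 1, "derives_from", 4])
    # one regulatory-region flavour per entry (all inside the gene span so
    # the member_of edge is location-coherent)
    flavour = i % 3
    if flavour in (0, 1):  # 3' site in the gene tail, after the last exon
        tail_start = exons[-1][1] + 2
        tail_end = min(gene_end, tail_start + rng.randint(5, 15))
        key = "polyA_signal" if flavour == 0 else "terminator"
        features.append(_feature(key, ports([(tail_start, tail_end)]),
                                 [["gene", gene_name]]))
    else:  # transcription-factor site between promoter and first exon
        site_start = p_end + 2
        site_end = min(exons[0][0] - 2, site_start + rng.randint(8, 16))
        features.append(
            _feature("protein_bind", ports([(site_start, site_end)]),
                     [["gene", gene_name],
                      ["bound_moiety", "transcription factor TFIIA"]])
        )
    relationships.append([len(features) - 1, "member_of", 2])
    introns = [
        {"start": e1 + 1, "end": s2 - 1, "strand": strand, "donors": [3, 4]}
        for (s1, e1), (s2, e2) in zip(exons, exons[1:])
    ]
    plan["features"] = features
    plan["relationships"] = relationships
    plan["introns"] = introns
    plan["references"] = [_whole_entry_reference(1, length, pubmed=20000000 + i)]
    return plan


def _plan_reference_rich(rng: random.Random, i: int, gi: int) -> dict:
    length = rng.randint(800, 2000)
    plan = _base_plan(gi, length)
    g_start = rng.randint(50, 200)
    g_end = g_start + rng.randint(200, 400)
    plan["features"] = [
        _source_feature(length),
        _feature("gene", [_portion(g_start, g_end)],
                 [["gene", f"ref{i:03d}"], ["locus_tag", f"SYN_{gi}"]]),
    ]
    r2_start = max(1, g_start - rng.randint(0, 20))
    r2_end = min(length, g_end + rng.randint(0, 20))
    plan["references"] = [
        _whole_entry_reference(1, length, pubmed=21000000 + i),
        {
            "ordinal": 2, "ranges": [[r2_start, r2_end]], "no_clause": False,
            "authors": "Poe,A.", "title": "Partial-range citation",
            "journal": "J. Synth. Data 1:1-2", "pubmed": None,
        },
        {
            # no base clause: parser assigns the whole-entry range
            "ordinal": 3, "ranges": [[1, length]], "no_clause": True,
            "authors": "Noe,C.", "title": "Direct Submission",
            "journal": "Submitted (01-JAN-2010)", "pubmed": None,
        },
    ]
    return plan


def _coverage_plans(rng, n, gi_base, items, per_feature_quals=None):
    """Distribute each item into exactly two distinct entries."""
    n_entries = max(n, 2)
    assignment: dict[int, list[str]] = {e: [] for e in range(n_entries)}
    for copy in range(2):
        for j, item in enumerate(items):
            e = (j * 2 + copy) % n_entries
            if item in assignment[e]:
                e = (e + 1) % n_entries
            assignment[e].append(item)
    return n_entries, assignment


def _plan_key_coverage(rng: random.Random, i: int, gi: int, keys: list[str]) -> dict:
    needed = [k for k in keys if k != "source"]
    length = max(400, 60 * len(needed) + 100)
    plan = _base_plan(gi, length)
    features = [_source_feature(length)]
    cursor = 10
    for key in needed:
        span = rng.randint(20, 40)
        features.append(
            _feature(key, [_portion(cursor, cursor + span)],
                     [["note", f"coverage fixture for key {key}"]])
        )
        cursor += span + rng.randint(15, 30)
    plan["length"] = max(length, cursor + 50)
    features[0] = _source_feature(plan["length"])
    plan["features"] = features
    plan["references"] = [_whole_entry_reference(1, plan["length"])]
    return plan


def _plan_qualifier_coverage(rng: random.Random, i: int, gi: int, quals: list[str]) -> dict:
    length = rng.randint(600, 1200)
    plan = _base_plan(gi, length)
    features = [_source_feature(length)]
    cursor = 10
    batch: list[list] = []
    for q in quals:
        batch.append([q, _qual_value(q, i)])
        if len(batch) == 6:
            span = rng.randint(30, 60)
            features.append(_feature("misc_feature", [_portion(cursor, cursor + span)], batch))
            cursor += span + 20
            batch = []
    if batch:
        span = rng.randint(30, 60)
        features.append(_feature("misc_feature", [_portion(cursor, cursor + span)], batch))
    plan["features"] = features
    plan["references"] = [_whole_entry_reference(1, length)]
    return plan


def _plan_adversarial(rng: random.Random, i: int, gi: int) -> dict:
    length = rng.randint(500, 1200)
    plan = _base_plan(gi, length)
    plan["relationships"] = None  # unasserted for this profile
    kind = i % 6
    features = [_source_feature(length)]
    introns: list[dict] = []
    if kind == 0:  # fuzzy ends
        features.append(_feature("gene", [_portion(1, 206, FORWARD, p5=True)],
                                 [["gene", f"fz{i}"]]))
        features.append(_feature("CDS", [_portion(3, 200, FORWARD, p3=True)],
                                 [["gene", f"fz{i}"]]))
    elif kind == 1:  # between-bases site
        features.append(_feature("variation", [_portion(123, 124, between=True)],
                                 [["replace", "g"]]))
    elif kind == 2:  # remote accession portion inside a join
        portions = [_portion(1, 100), _portion(50, 80, remote="REM1234.1"),
                    _portion(201, 300)]
        features.append(_feature("mRNA", portions, [["gene", f"rm{i}"]]))
        introns.append({"start": 101, "end": 200, "strand": FORWARD, "donors": [1]})
    elif kind == 3:  # order() operator
        features.append(_feature("exon", [_portion(1, 50), _portion(100, 150)],
                                 [["number", "1"]], operator="order"))
    elif kind == 4:  # explicit intron suppresses the inferred one
        features.append(_feature("mRNA", [_portion(1, 100), _portion(201, 300)],
                                 [["gene", f"xi{i}"]]))
        features.append(_feature("intron", [_portion(101, 200)], [["gene", f"xi{i}"]]))
    else:  # wrapped long values, point location
        long_note = " ".join(f"wrapped-token-{k}" for k in range(18))
        features.append(_feature("polyA_site", [_portion(467, 467)], [["note", long_note]]))
        features.append(_feature("CDS", [_portion(10, 120)],
                                 [["translation", "MKVLITTSWAARDGELKNMPFW" * 4]]))
    plan["features"] = features
    plan["introns"] = introns
    if kind != 5:  # one flavour omits REFERENCE entirely
        plan["references"] = [_whole_entry_reference(1, length)]
    return plan


# ---------------------------------------------------------------------------
# rendering

_QUAL_INDENT = " " * 21
_WRAP_WIDTH = 79


def _wrap_value_lines(first_line: str, breakable: bool) -> list[str]:
    """Wrap a qualifier line to the feature-table width.  Space-separated
    values break at spaces only (so parsers re-join them losslessly);
    sequence-like values break anywhere.  ``first_line`` carries the
    21-column indent already."""
    if len(first_line) <= _WRAP_WIDTH:
        return [first_line]
    lines = []
    if breakable:
        cur = first_line
        while len(cur) > _WRAP_WIDTH:
            lines.append(cur[:_WRAP_WIDTH])
            cur = _QUAL_INDENT + cur[_WRAP_WIDTH:]
        lines.append(cur)
        return lines
    indent, content = first_line[:21], first_line[21:]
    cur_line = indent
    for w in content.split(" "):
        cand = cur_line + w if cur_line.endswith(" ") or cur_line == indent \
            else cur_line + " " + w
        if len(cand) > _WRAP_WIDTH and cur_line != indent:
            lines.append(cur_line)
            cur_line = _QUAL_INDENT + w
        else:
            cur_line = cand
    lines.append(cur_line)
    return lines


def _render_feature(feat: dict) -> str:
    loc = feat["location"]
    lines = [f"     {feat['key']:<16}{loc}"]
    for name, value in feat["qualifiers"]:
        if value is None:
            lines.append(f"{_QUAL_INDENT}/{name}")
        elif name in ("codon_start", "transl_table", "number", "estimated_length",
                      "citation", "direction", "frequency", "compare"):
            lines.append(f"{_QUAL_INDENT}/{name}={value}")
        else:
            prefix = f'{_QUAL_INDENT}/{name}="{value}"'
            lines.extend(_wrap_value_lines(prefix, breakable=name == "translation"))
    return "\n".join(lines)


def _render_origin(seq: str) -> str:
    lines = ["ORIGIN"]
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        groups = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


def _render_reference(ref: dict) -> str:
    head = f"REFERENCE   {ref['ordinal']}"
    if not ref.get("no_clause"):
        clauses = "; ".join(f"{s} to {e}" for s, e in ref["ranges"])
        head += f"  (bases {clauses})"
    lines = [head,
             f"  AUTHORS   {ref['authors']}",
             f"  TITLE     {ref['title']}",
             f"  JOURNAL   {ref['journal']}"]
    if ref.get("pubmed"):
        lines.append(f"  PUBMED    {ref['pubmed']}")
    return "\n".join(lines)


def render_entry(plan: dict, seq: str) -> str:
    lines = [
        # canonical column layout: length right-justified to col 40, units at
        # 40:44, molecule 47:54, topology 55:63, division 64:67, date 68:79
        f"LOCUS       {plan['locus_name']:<16}{plan['length']:>12} bp    "
        f"{plan['molecule_type']:<7} {plan['topology']:<8} {plan['division']} {plan['date']}",
        f"DEFINITION  {plan['definition']}",
        f"ACCESSION   {plan['accession']}",
        f"VERSION     {plan['version']}  GI:{plan['gi']}",
        "KEYWORDS    " + ("; ".join(plan["keywords"]) + "." if plan["keywords"] else "."),
        f"SOURCE      {plan['organism']}",
        f"  ORGANISM  {plan['organism']}",
        "            " + "; ".join(plan["lineage"]) + ".",
    ]
    for ref in plan["references"]:
        lines.append(_render_reference(ref))
    lines.append("FEATURES             Location/Qualifiers")
    for feat in plan["features"]:
        lines.append(_render_feature(feat))
    lines.append(_render_origin(seq))
    lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# evidence + fact-count derivation (applied uniformly to all plans)


def _derive_expectations(plan: dict) -> None:
    features = plan["features"]
    evidence = []
    for fi, feat in enumerate(features):
        local = [p for p in feat["portions"] if p[6] is None]
        if not local:
            continue
        fs = min(p[0] for p in local)
        fe = max(p[1] for p in local)
        for ref in plan["references"]:
            if any(s <= fs and fe <= e for s, e in ref["ranges"]):
                evidence.append([fi, ref["ordinal"]])
    plan["evidence"] = evidence
    n_portions = sum(len(f["portions"]) for f in features)
    n_quals = sum(len(f["qualifiers"]) for f in features)
    n_ranges = sum(len(r["ranges"]) for r in plan["references"])
    plan["fact_count"] = 2 + len(features) + n_portions + n_quals + \
        len(plan["references"]) + n_ranges


def generate_entries(n: int, seed: int, profile: str) -> tuple[str, dict[str, Any]]:
    """Generate a flat file with ``n`` entries (profiles may round up to
    meet their coverage guarantees) plus the ground-truth manifest."""
    if profile not in PROFILES:
        raise OntoloadError(f"unknown fixture profile {profile!r}")
    rng = random.Random(f"{seed}:{profile}")
    gi_base = 10_000_000 + (seed % (1 << 15)) * 10_000
    plans: list[dict] = []
    if n > 0:
        if profile == "key_coverage":
            keys = sorted(feature_key_table())
            n_entries, assignment = _coverage_plans(rng, n, gi_base, keys)
            for i in range(n_entries):
                plans.append(_plan_key_coverage(rng, i, gi_base + i, assignment[i]))
        elif profile == "qualifier_coverage":
            quals = sorted(qualifier_routing_table())
            n_entries, assignment = _coverage_plans(rng, n, gi_base, quals)
            for i in range(n_entries):
                plans.append(_plan_qualifier_coverage(rng, i, gi_base + i, assignment[i]))
        else:
            builder = {
                "minimal": _plan_minimal,
                "nested_gene_models": _plan_nested,
                "reference_rich": _plan_reference_rich,
                "adversarial": _plan_adversarial,
            }[profile]
            for i in range(n):
                plans.append(builder(rng, i, gi_base + i))

    chunks: list[str] = []
    offset = 0
    entries_manifest = []
    for plan in plans:
        _derive_expectations(plan)
        seq = "".join(rng.choices("acgt", k=plan["length"]))
        text = render_entry(plan, seq)
        seq_rel = text.index("ORIGIN\n") + len("ORIGIN\n") if "ORIGIN\n" in text \
            else text.index("ORIGIN") + len("ORIGIN")
        entries_manifest.append({
            "gi": plan["gi"],
            "accession": plan["accession"],
            "version": plan["version"],
            "locus_name": plan["locus_name"],
            "sequence_length": plan["length"],
            "molecule_type": plan["molecule_type"],
            "topology": plan["topology"],
            "division": plan["division"],
            "date": plan["date"],
            "organism": plan["organism"],
            "lineage": plan["lineage"],
            "header_offset": offset,
            "sequence_offset": offset + seq_rel,
            "sequence": seq,
            "features": plan["features"],
            "references": [
                {"ordinal": r["ordinal"], "ranges": r["ranges"],
                 "pubmed": r.get("pubmed")}
                for r in plan["references"]
            ],
            "relationships": plan["relationships"],
            "introns": plan["introns"],
            "evidence": plan["evidence"],
            "fact_count": plan["fact_count"],
        })
        chunks.append(text)
        offset += len(text)
    manifest = {"seed": seed, "profile": profile, "n_requested": n,
                "n_entries": len(plans), "entries": entries_manifest}
    return "".join(chunks), manifest
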