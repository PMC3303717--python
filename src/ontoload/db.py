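"""Relational schema and statement execution.

A Chado-style ontological schema on an embedded SQLite database: all
feature types share one ``sequence_feature`` table typed by ontology-term
accessions, relationships share ``feature_relationship``, and the
precomputed is_a closure lives in ``cvpath`` so subsumption queries are a
single join.  SQL stays in the portable core so another relational engine
could be substituted.
"""
from __future__ import annotations

import queue
import re
import sqlite3
import threading
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import OntoloadError, StatementError
from .facts import StatementFact, validate_statements
from .ontology import ClosurePath, OntologyTerm, RELATIONSHIPS

SCHEMA_VERSION = 1

_DDL = [
    """CREATE TABLE IF NOT EXISTS schema_meta (
        key TEXT PRIMARY KEY, value TEXT NOT NULL)""",
    """CREATE TABLE IF NOT EXISTS ontology_term (
        accession TEXT PRIMARY KEY,
        name TEXT NOT NULL,
        namespace TEXT NOT NULL DEFAULT 'sequence',
        obsolete INTEGER NOT NULL DEFAULT 0)""",
    """CREATE TABLE IF NOT EXISTS cvpath (
        subject TEXT NOT NULL REFERENCES ontology_term(accession),
        object TEXT NOT NULL REFERENCES ontology_term(accession),
        relationship TEXT NOT NULL,
        distance INTEGER NOT NULL,
        PRIMARY KEY (subject, object, relationship))""",
    """CREATE TABLE IF NOT EXISTS individual (
        id INTEGER PRIMARY KEY,
        label TEXT)""",
    """CREATE TABLE IF NOT EXISTS taxonomy (
        id INTEGER PRIMARY KEY,
        organism_name TEXT,
        lineage TEXT,
        taxon_db_xref TEXT)""",
    """CREATE TABLE IF NOT EXISTS collection_event (
        id INTEGER PRIMARY KEY,
        individual_id INTEGER REFERENCES individual(id),
        bio_material TEXT, collected_by TEXT, collection_date TEXT, country TEXT,
        culture_collection TEXT, environmental_sample TEXT, host TEXT,
        identified_by TEXT, isolate TEXT, isolation_source TEXT, lab_host TEXT,
        lat_lon TEXT, specimen_voucher TEXT, strain TEXT)""",
    """CREATE TABLE IF NOT EXISTS entry (
        id INTEGER PRIMARY KEY,
        gi INTEGER NOT NULL UNIQUE,
        accession TEXT,
        version TEXT,
        locus_name TEXT,
        sequence_length INTEGER,
        molecule_type TEXT,
        topology TEXT,
        division_code TEXT,
        modification_date TEXT,
        definition TEXT,
        keywords TEXT,
        taxonomy_id INTEGER REFERENCES taxonomy(id),
        individual_id INTEGER REFERENCES individual(id))""",
    """CREATE TABLE IF NOT EXISTS sequence (
        id INTEGER PRIMARY KEY,
        entry_id INTEGER NOT NULL REFERENCES entry(id),
        length INTEGER,
        residues TEXT)""",
    """CREATE TABLE IF NOT EXISTS sequence_feature (
        id INTEGER PRIMARY KEY,
        entry_id INTEGER NOT NULL REFERENCES entry(id),
        type_accession TEXT NOT NULL REFERENCES ontology_term(accession),
        feature_key TEXT NOT NULL,
        rank INTEGER NOT NULL,
        span_start INTEGER,
        span_end INTEGER,
        strand TEXT,
        inferred INTEGER NOT NULL DEFAULT 0)""",
    """CREATE TABLE IF NOT EXISTS feature_portion (
        id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES sequence_feature(id),
        start INTEGER NOT NULL,
        end INTEGER NOT NULL,
        strand TEXT,
        partial5 INTEGER NOT NULL DEFAULT 0,
        partial3 INTEGER NOT NULL DEFAULT 0,
        between_bases INTEGER NOT NULL DEFAULT 0,
        remote_accession TEXT,
        rank INTEGER NOT NULL)""",
    """CREATE TABLE IF NOT EXISTS feature_annotation (
        id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES sequence_feature(id),
        type_accession TEXT NOT NULL REFERENCES ontology_term(accession),
        name TEXT NOT NULL,
        value TEXT)""",
    """CREATE TABLE IF NOT EXISTS feature_relationship (
        id INTEGER PRIMARY KEY,
        subject_id INTEGER NOT NULL REFERENCES sequence_feature(id),
        object_id INTEGER NOT NULL REFERENCES sequence_feature(id),
        reltype TEXT NOT NULL,
        provenance TEXT)""",
    """CREATE TABLE IF NOT EXISTS reference (
        id INTEGER PRIMARY KEY,
        entry_id INTEGER NOT NULL REFERENCES entry(id),
        ordinal INTEGER NOT NULL,
        authors TEXT, title TEXT, journal TEXT,
        pubmed_id INTEGER,
        cited_ranges TEXT)""",
    """CREATE TABLE IF NOT EXISTS reference_evidence (
        id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES sequence_feature(id),
        reference_id INTEGER NOT NULL REFERENCES reference(id))""",
    """CREATE TABLE IF NOT EXISTS load_metrics (
        id INTEGER PRIMARY KEY,
        gi INTEGER NOT NULL,
        sequence_length INTEGER,
        feature_table_length INTEGER,
        n_features INTEGER,
        n_statements INTEGER,
        parsing_ms REAL,
        reasoning_ms REAL,
        insert_ms REAL,
        total_ms REAL)""",
    "CREATE INDEX IF NOT EXISTS idx_cvpath_object ON cvpath(object, relationship)",
    "CREATE INDEX IF NOT EXISTS idx_feature_entry ON sequence_feature(entry_id)",
    "CREATE INDEX IF NOT EXISTS idx_feature_type ON sequence_feature(type_accession)",
    "CREATE INDEX IF NOT EXISTS idx_rel_subject ON feature_relationship(subject_id)",
    "CREATE INDEX IF NOT EXISTS idx_rel_object ON feature_relationship(object_id)",
    "CREATE INDEX IF NOT EXISTS idx_annot_feature ON feature_annotation(feature_id)",
]

CORE_TABLES = (
    "ontology_term", "cvpath", "individual", "entry", "sequence", "sequence_feature",
    "feature_portion", "feature_annotation", "feature_relationship", "reference",
    "reference_evidence", "taxonomy", "collection_event",
)


def resolve_db_path(db_url: str) -> str:
    """Accept sqlite:///path, sqlite://:memory:, or a bare filesystem path."""
    m = re.match(r"^sqlite:///?(.*)$", db_url)
    return m.group(1) or ":memory:" if m else db_url


def connect(db_url: str) -> sqlite3.Connection:
    conn = sqlite3.connect(resolve_db_path(db_url), check_same_thread=False)
    conn.isolation_level = None  # explicit BEGIN/COMMIT; per-entry transactions
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


@dataclass
class SchemaCatalog:
    tables: dict[str, list[str]] = field(default_factory=dict)  # table -> columns
    version: int = SCHEMA_VERSION


def create_schema(conn: sqlite3.Connection) -> SchemaCatalog:
    """Create all tables, constraints and indexes; idempotent."""
    row = None
    try:
        row = conn.execute("SELECT value FROM schema_meta WHERE key='version'").fetchone()
    except sqlite3.OperationalError:
        pass
    if row is not None and int(row[0]) != SCHEMA_VERSION:
        raise OntoloadError(
            f"database schema version {row[0]} != supported {SCHEMA_VERSION}; migrate first"
        )
    with conn:
        for ddl in _DDL:
            conn.execute(ddl)
        conn.execute(
            "INSERT OR REPLACE INTO schema_meta (key, value) VALUES ('version', ?)",
            (str(SCHEMA_VERSION),),
        )
    catalog = SchemaCatalog()
    for (name,) in conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' AND name NOT LIKE 'sqlite_%'"
    ):
        cols = [r[1] for r in conn.execute(f"PRAGMA table_info({name})")]
        catalog.tables[name] = cols
    return catalog


def install_ontology(
    closure: Iterable[ClosurePath],
    terms: Iterable[OntologyTerm],
    conn: sqlite3.Connection,
) -> dict[str, int]:
    """Persist ontology terms and the precomputed closure (CVPath rows)."""
    closure = list(closure)
    terms = list(terms)
    with conn:
        for t in terms:
            conn.execute(
                "INSERT INTO ontology_term (accession, name, namespace, obsolete) "
                "VALUES (?, ?, ?, ?) ON CONFLICT(accession) DO UPDATE SET "
                "name=excluded.name, namespace=excluded.namespace, obsolete=excluded.obsolete",
                (t.accession, t.name, t.namespace, int(t.obsolete)),
            )
        for rel in RELATIONSHIPS:  # relationship terms used by feature_relationship
            conn.execute(
                "INSERT OR IGNORE INTO ontology_term (accession, name, namespace) "
                "VALUES (?, ?, 'relationship')",
                (rel, rel),
            )
        for p in closure:
            conn.execute(
                "INSERT INTO cvpath (subject, object, relationship, distance) "
                "VALUES (?, ?, ?, ?) ON CONFLICT(subject, object, relationship) "
                "DO UPDATE SET distance=excluded.distance",
                (p.subject, p.object, p.relationship, p.distance),
            )
    n_terms = conn.execute("SELECT COUNT(*) FROM ontology_term").fetchone()[0]
    n_paths = conn.execute("SELECT COUNT(*) FROM cvpath").fetchone()[0]
    return {"ontology_term": n_terms, "cvpath": n_paths}


@dataclass
class LoadResult:
    gi: Optional[int]
    statements_executed: int
    keymap: dict[int, int]
    status: str  # "loaded" | "failed"
    reason: str = ""
    failed_count: Optional[int] = None


def execute_statements(
    statements: list[StatementFact], conn: sqlite3.Connection
) -> LoadResult:
    """Execute one entry's statement list inside a single transaction.

    For each ``foreign_count`` the generated key of the cited statement is
    substituted into the aligned column before execution.  Any failure rolls
    the whole entry back.
    """
    validate_statements(statements)
    gi = None
    for st in statements:
        if st.table_name == "entry" and "gi" in st.column_names:
            gi = st.column_values[st.column_names.index("gi")]
    keymap: dict[int, int] = {}
    executed = 0
    try:
        conn.execute("BEGIN")
        for st in statements:
            values = list(st.column_values)
            for fc, col in zip(st.foreign_counts, st.foreign_columns):
                if fc not in keymap:
                    raise StatementError(
                        f"statement {st.count}: cited count {fc} produced no key"
                    )
                values[st.column_names.index(col)] = keymap[fc]
            cols = ", ".join(f'"{c}"' for c in st.column_names)
            marks = ", ".join("?" for _ in values)
            if st.kind == "insert":
                cur = conn.execute(
                    f'INSERT INTO "{st.table_name}" ({cols}) VALUES ({marks})', values
                )
                keymap[st.count] = cur.lastrowid
            elif st.kind == "upsert":
                conn.execute(
                    f'INSERT OR IGNORE INTO "{st.table_name}" ({cols}) VALUES ({marks})',
                    values,
                )
            elif st.kind == "select":
                where = " AND ".join(f'"{c}" = ?' for c in st.column_names)
                row = conn.execute(
                    f'SELECT id FROM "{st.table_name}" WHERE {where}', values
                ).fetchone()
                if row is None:
                    raise StatementError(f"select statement {st.count} matched no row")
                keymap[st.count] = row[0]
            else:
                raise StatementError(f"unknown statement kind {st.kind!r}")
            executed += 1
        conn.commit()
    except Exception as exc:  # noqa: BLE001 - any failure must roll back the entry
        conn.rollback()
        failed = statements[executed].count if executed < len(statements) else None
        return LoadResult(
            gi=gi, statements_executed=0, keymap={}, status="failed",
            reason=str(exc), failed_count=failed,
        )
    return LoadResult(gi=gi, statements_executed=executed, keymap=keymap, status="loaded")


class ConnectionPool:
    """Bounded pool of SQLite connections shared (in turn) among workers."""

    def __init__(self, db_url: str, size: int = 2, timeout: float = 30.0):
        self._db_url = db_url
        self._timeout = timeout
        self._q: "queue.Queue[sqlite3.Connection]" = queue.Queue()
        self._all: list[sqlite3.Connection] = []
        self._closed = False
        self._lock = threading.Lock()
        for _ in range(size):
            conn = connect(db_url)
            self._q.put(conn)
            self._all.append(conn)

    @contextmanager
    def lease(self):
        if self._closed:
            raise OntoloadError("connection pool is closed")
        try:
            conn = self._q.get(timeout=self._timeout)
        except queue.Empty:
            raise OntoloadError(
                f"connection pool exhausted (waited {self._timeout}s)"
            ) from None
        try:
            yield conn
        finally:
            self._q.put(conn)

    def close(self) -> None:
        with self._lock:
            self._closed = True
            for conn in self._all:
                conn.close()


# ---------------------------------------------------------------------------
# audits and subsumption retrieval


def features_of_type(conn: sqlite3.Connection, accession: str) -> list[tuple]:
    """Subsumption retrieval: features typed by the term or any descendant."""
    return conn.execute(
        "SELECT f.id, e.accession, f.type_accession, f.span_start, f.span_end, f.strand "
        "FROM sequence_feature f JOIN entry e ON f.entry_id = e.id "
        "WHERE f.type_accession IN "
        "(SELECT subject FROM cvpath WHERE object = ? AND relationship = 'is_a') "
        "ORDER BY e.accession, f.rank",
        (accession,),
    ).fetchall()


def referential_integrity_audit(conn: sqlite3.Connection) -> list[tuple]:
    return conn.execute("PRAGMA foreign_key_check").fetchall()


def relationship_admissibility_audit(conn: sqlite3.Connection, snapshot) -> list[tuple]:
    """Database-level replay of the rule-engine admissibility invariant."""
    bad = []
    rows = conn.execute(
        "SELECT r.id, s.type_accession, r.reltype, o.type_accession, s.inferred "
        "FROM feature_relationship r "
        "JOIN sequence_feature s ON r.subject_id = s.id "
        "JOIN sequence_feature o ON r.object_id = o.id"
    ).fetchall()
    for rid, subj_type, reltype, obj_type, _inferred in rows:
        if not snapshot.is_admissible(subj_type, reltype, obj_type):
            bad.append((rid, subj_type, reltype, obj_type))
    return bad


def table_row_counts(conn: sqlite3.Connection) -> dict[str, int]:
    counts = {}
    for name in CORE_TABLES:
        counts[name] = conn.execute(f'SELECT COUNT(*) FROM "{name}"').fetchone()[0]
    return counts


def content_digest(conn: sqlite3.Connection) -> str:
    """Digest of DB content with auto-generated keys canonicalized away."""
    import hashlib

    h = hashlib.sha256()
    queries = [
        "SELECT accession, name, namespace, obsolete FROM ontology_term ORDER BY accession",
        "SELECT subject, object, relationship, distance FROM cvpath ORDER BY subject, object, relationship",
        "SELECT gi, accession, locus_name, sequence_length, division_code FROM entry ORDER BY gi",
        "SELECT e.gi, f.feature_key, f.type_accession, f.rank, f.span_start, f.span_end, "
        "f.strand, f.inferred FROM sequence_feature f JOIN entry e ON f.entry_id = e.id "
        "ORDER BY e.gi, f.rank",
        "SELECT e.gi, f.rank, p.rank, p.start, p.end, p.strand, p.partial5, p.partial3, "
        "p.between_bases, IFNULL(p.remote_accession,'') FROM feature_portion p "
        "JOIN sequence_feature f ON p.feature_id = f.id JOIN entry e ON f.entry_id = e.id "
        "ORDER BY e.gi, f.rank, p.rank",
        "SELECT e.gi, f.rank, a.type_accession, a.name, IFNULL(a.value,'') "
        "FROM feature_annotation a JOIN sequence_feature f ON a.feature_id = f.id "
        "JOIN entry e ON f.entry_id = e.id ORDER BY e.gi, f.rank, a.name, a.value",
        "SELECT e.gi, s.rank, o.rank, r.reltype FROM feature_relationship r "
        "JOIN sequence_feature s ON r.subject_id = s.id "
        "JOIN sequence_feature o ON r.object_id = o.id "
        "JOIN entry e ON s.entry_id = e.id ORDER BY e.gi, s.rank, o.rank, r.reltype",
        'SELECT e.gi, r.ordinal, IFNULL(r.pubmed_id,0), r.cited_ranges FROM "reference" r '
        "JOIN entry e ON r.entry_id = e.id ORDER BY e.gi, r.ordinal",
        "SELECT e.gi, f.rank, r.ordinal FROM reference_evidence ev "
        "JOIN sequence_feature f ON ev.feature_id = f.id "
        'JOIN "reference" r ON ev.reference_id = r.id '
        "JOIN entry e ON f.entry_id = e.id ORDER BY e.gi, f.rank, r.ordinal",
    ]
    for q in queries:
        for row in conn.execute(q):
            h.update(repr(row).encode())
        h.update(b"|")
    return h.hexdigest()
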