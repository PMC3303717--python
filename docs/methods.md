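# Methods

This note records the models, rules and numerical conventions behind
`ontoload`, and the design choices made where more than one reasonable
option existed.

## Coordinate and strand conventions

Coordinates are stored exactly as the flat file prints them: 1-based,
inclusive on both ends. Chado proper uses interbase (0-based,
exclusive-end) coordinates; we deliberately keep flat-file fidelity and
convert nowhere, so a `join(115..299,447..595)` round-trips byte-for-byte.
Strand is `forward`/`reverse`; `complement(...)` flips every enclosed
portion, and `complement(complement(...))` is rejected as malformed rather
than silently normalized. Fuzzy bounds (`<`, `>`) set partial flags tied to
the low/high coordinate of the portion, regardless of strand. A
between-bases site `a^b` requires b = a+1. `order(...)` is treated like
`join(...)` but the feature is annotated with `location_operator=order`, so
the weaker ordering claim is preserved without a separate code path.
Remote portions (`ACC.1:10..50`) are parsed and stored but excluded from
all inference (relationships, introns, evidence): their coordinates live
on another sequence.

## The ontology snapshot

`load_obo` reads OBO 1.2 through `obonet`; obsolete terms are kept but
flagged and excluded from every edge and closure row. The is_a closure is
computed once per ontology content-hash and cached: rows `(subject,
object, is_a, distance)` with minimal distance per pair and self-paths at
distance 0, so subsumption queries need no special case for exact-type
matches. Queries use pair membership, not distance; the distance is kept
because it is cheap and useful for inspection.

Admissibility is a graph entailment: (C, R, T) holds iff there is a
directed path from C to T consisting of is_a edges (upward) and R edges,
with at least one R edge, **ending on an R edge**. The implementation runs
reachability on a product graph over (term, last-edge-was-R) states; an
independent exhaustive enumeration over the same state space is the test
oracle, and every triple is emitted with a witness path that tests replay
edge by edge. The trailing-R restriction matters: allowing a trailing is_a
hop would propagate every R target to its ancestors (everything would be
`part_of` some broad region-class term), and since the runtime check
generalizes over the *object's* ancestors — necessary so an exon can attach
to a concrete mRNA through `exon part_of transcript` — the two
generalizations together would admit pairs like `CDS part_of promoter`,
which the loader must refuse. With the restriction, the runtime check is
sound and the system stores only ontology-sanctioned relationships; a
database-level audit replays this invariant over every loaded
`feature_relationship` row.

## Rule engine

The engine is a deterministic forward-chaining evaluator with stratified
phases: facts → relationships → reference evidence → implicit introns →
qualifier routing → statement generation. Stratification removes the need
for a general conflict-resolution strategy and makes the statement list
reproducible bit-for-bit for a given entry and ontology snapshot — a
property the determinism tests assert end to end. Rules that vary by data
are data: the feature-key mapping, the qualifier routing table and the
intron-donor term list are editable configuration, not code.

Relationship inference combines three predicates:

* **admissibility** as above (object side generalized over ancestors);
* **qualifier consistency**: a shared identical value for `/locus_tag` or
  `/gene` (plus `/protein_id` for derives_from). When *neither* feature
  carries any of these qualifiers, consistency defaults to true and
  location decides alone; when only one side carries them, the features
  are treated as inconsistent — identity evidence present on one side but
  unmatched on the other is taken as evidence against the link.
* **location coherence**: span(f) ⊆ span(g) with span = [min portion
  start, max portion end] over local portions, on the same strand.
  Features whose key is `source` and features with mixed-strand portions
  are containment-checked ignoring strand.

When several parents qualify for the same relationship, the smallest
containing parent wins, with size measured first as **covered length**
(sum of portion lengths), then span extent, then entry order. Covered
length rather than extent is essential: a spliced mRNA and its gene often
share the same outer span, and extent alone would attach the CDS to the
gene instead of the mRNA.

Implicit introns are computed for donors whose type is, via the closure, a
transcript-class or CDS term (configurable; defaults SO:0000673 and
SO:0000316). Portions are sorted by start; every gap s₂ > e₁+1 yields
intron (e₁+1, s₂−1) on the donor's strand. Introns with identical
coordinates from different donors (an mRNA and its CDS sharing splice
boundaries) are merged into one inferred feature carrying a part_of edge
to each donor, and an explicit intron feature with the same coordinates
suppresses the inferred one. By construction the emitted introns exactly
tile the inter-portion gaps: portions plus introns partition the donor's
span with no overlap — asserted as a property over every fixture.

Type refinements encode small pieces of domain expertise as data-like
rules: a `gene` in an entry whose source carries
`/organelle="mitochondri…"` is typed `mitochondrial_gene`; a
`protein_bind` feature whose `/bound_moiety` mentions a transcription
factor is typed `TF_binding_site`. These give the subsumption machinery
genuinely refined types to retrieve.

Reference evidence uses containment (feature span inside a cited base
range), the stricter of the plausible readings of location coherence; a
reference without a parsable base clause is assigned the whole-entry range
and therefore supports every feature. Qualifiers route to one of four
destinations: collection columns (sampling metadata such as `country`,
`lat_lon`, `specimen_voucher`), taxonomy columns (`organism`, taxon
`db_xref`s), suppression (`citation`, `compare`, which are represented
elsewhere), or feature annotations typed by a `local:` term named after
the qualifier — the fallback mirrors naming attributes after the source
field when no ontology term applies.

## Statements and loading

Statement generation assigns strictly increasing `count` identifiers; any
statement may cite an earlier one through aligned `foreign_counts` /
`foreign_columns`, and the executor substitutes the cited statement's
database-generated key before execution. Beyond plain inserts the list may
contain idempotent upserts (used only for ontology terms an entry
introduces — `local:` fallbacks and mapped accessions absent from the
installed ontology — so the `sequence_feature.type → ontology_term`
foreign key holds without cross-entry coordination) and selects (key
lookup by column equality). Each entry executes in a single transaction:
a failure at any statement rolls back the whole entry, which is what makes
re-dispatch after a crash harmless.

The schema is deliberately portable SQLite (core SQL only): 13 core tables
— `ontology_term`, `cvpath`, `individual`, `entry`, `sequence`,
`sequence_feature`, `feature_portion`, `feature_annotation`,
`feature_relationship`, `reference`, `reference_evidence`, `taxonomy`,
`collection_event` — plus `schema_meta` and a `load_metrics` table that
records per-entry observables (sequence length, feature-table bytes,
feature and statement counts, parse/reason/insert/total milliseconds).
Timings are logged, never asserted: they are hardware facts, not package
properties. The collection and taxonomy tables carry exactly the columns
the routing table produces; a fuller biodiversity schema is out of scope.

## Job control

Entries are indexed into jobs keyed by GI with byte offsets for the LOCUS
line and the first sequence line; states move ready → pending → loaded,
with pending → ready on reset. The ledger persists as a JSON snapshot
written atomically (tmp + rename + fsync) at checkpoints — every k
completions (default 10) and at the end of a batch. Completions between
checkpoints are deliberately *not* individually durable: after a hard
crash they are simply re-dispatched, and the loader's GI-idempotence
(an entry already present in the database is skipped, per-entry
transactions guarantee no partial entries) turns at-least-once dispatch
into exactly-once effect. Duplicate completion messages are acknowledged
silently. The dispatch contract is in-process and thread-safe; a socket
transport could satisfy the same contract but is not built.

## Query engine

A query is a tree `term [memberOf|hasMember (subtree)] [hasAnnotation
name=value]`. Compilation produces one SQL statement: term nodes expand to
their descendant sets through the `cvpath` table (so the expansion uses
the same persisted closure the loader installed, and an in-memory oracle
cross-checks it in tests); chain edges traverse `feature_relationship`
rows of type part_of or member_of **transitively** via a recursive CTE,
within one entry. Transitivity is required because the loader stores only
minimal containing parents: the CDS reaches its gene through the mRNA.
derives_from is excluded from chains. Annotation matching is exact and
case-sensitive by default; `--like` switches to substring matching. The
spelling `hasAnnonation` is accepted and normalized. Results are ordered
by entry accession and feature rank, so output is deterministic.

## Synthetic fixtures

The generator emulates a controlled dataset of small entries with
pre-established characteristics; the manifest it writes is the single
source of truth for round-trip and inference assertions. Profiles:
`minimal` (source-only entries), `nested_gene_models` (promoter + gene +
spliced mRNA + CDS + exons, optional mat_peptide sharing the CDS's
`/protein_id`, one regulatory-region flavour per entry — polyA_signal,
terminator or a TF-binding protein_bind site — and every fourth entry
mitochondrial via `/organelle`), `reference_rich` (multiple cited ranges,
including a clause-less reference), `key_coverage` and
`qualifier_coverage` (each bundled feature key / qualifier planted in at
least two entries), and `adversarial` (fuzzy and between-bases locations,
remote portions, `order()`, wrapped qualifier values, an explicit intron
that must suppress the inferred one, entries without references).

Synthetic conventions worth knowing: sequences are uniform random acgt
(lengths roughly 100–5000 bp; nested entries 1200–3000 bp) — composition
is not realistic and nothing downstream depends on it; GI numbers are
assigned sequentially from a seed-derived base; gene spans are drawn to
*contain* their promoter so the planted member_of edge satisfies span
containment — real annotation often places promoters outside the gene
span, in which case this system would (correctly per its rules) not link
them. Generation is deterministic: same (n, seed, profile) gives
byte-identical output. What passing tests show is therefore that the
implementation matches its stated rules on well-formed FTv8 input with
consistent qualifiers; they do not show robustness to the full variety of
historical GenBank formatting, nor correct inference when annotators omit
identity qualifiers.

The bundled mini ontology fragment (~30 terms, real SO accessions) covers
the types the rules and queries exercise, including `mitochondrial_gene
is_a gene` and the regulatory_region children. Two simplifications: the
fragment asserts `intron part_of CDS` directly (real SO routes intron
parthood through transcript regions) so inferred intron edges from CDS
donors satisfy the admissibility invariant, and `mature_protein_region
derives_from CDS` is asserted directly for the same reason.

## Problem sizes and numerical choices

Default verification sizes: 200 random DAGs of up to 50 nodes for the
closure oracle, 100 nested entries for relationship/intron recovery and
query checks, 50 entries for crash-injection, 30 for determinism — sizes
chosen so the whole suite and the acceptance script each run in seconds
while every code path is exercised. There is no floating-point numerics in
the core; determinism comes from ordered iteration and seeded generators
only. Database content comparisons canonicalize auto-generated keys away
by digesting natural-key projections of every table.

## Known limitations

* Only the flat-file dialect is read (no ASN.1/XML, no EMBL/DDBJ line
  types, no CON records); entries must carry a GI number, which the ETL
  uses as the job key.
* Qualifier-consistency logic (D-style AND/OR combination across identity
  qualifiers) is a reconstruction; annotation practice that relies on
  `/gene` synonyms or omits identity qualifiers on one side will miss
  links.
* The relationship inference compares feature pairs within an entry
  (quadratic per entry); entries with tens of thousands of features would
  need an interval index.
* `member_of` vs `part_of` distinctions are as coarse as the ontology
  fragment's edges; chains treat them interchangeably.
* The web-style GUI, socket transport and multi-host deployment are out of
  scope; the in-process contracts are the normative ones.
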