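# ontoload

Ontology-aware ETL for GenBank flat files.

GenBank entries state *what* is annotated on a sequence — a `gene`, an
`mRNA`, a `CDS`, a `promoter` — but not how those features relate to one
another. The relationships are implicit, recoverable only by combining the
feature types, their qualifiers (`/gene`, `/locus_tag`, `/product`,
`/protein_id`) and their coordinates with background knowledge from the
Sequence Ontology (SO). `ontoload` makes that knowledge explicit: it parses
flat files in the classic Feature Table dialect (FTv8), runs a
deterministic forward-chaining rule engine over the parsed facts, and loads
the result into a Chado-style *ontological* relational schema — one
`sequence_feature` table for every feature type, typed by SO terms, with
relationships in a shared `feature_relationship` table. The loaded database
answers subsumption-aware queries: asking for `gene` also returns
`mitochondrial_gene` features, asking for `regulatory_region` returns
promoters, terminators, polyA signals and TF binding sites.

It is intended for groups that want a local, queryable, semantically
enriched mirror of sequence annotation data — for data integration, not for
sequence analysis itself.

## What the core computes

**Typing.** Each feature key maps to an SO accession through a bundled
60-key table; unmapped keys fall back to a reserved `local:` namespace.
Qualifier evidence can refine a type (a `gene` on a source with
`/organelle="mitochondrion"` becomes `mitochondrial_gene`).

**Subsumption.** The is_a transitive closure of the ontology is computed
once at setup and persisted in a `cvpath` table: rows `(subject, object,
is_a, distance)` for every ancestor pair, with self-paths at distance 0.
Retrieval by term *T* is then a single join against
`cvpath.object = T`.

**Admissible relationships.** For each relationship *R* in {part_of,
member_of, derives_from}, a type pair (C, R, T) is admissible iff the
ontology contains a directed path `C -(is_a* R)+-> T` — subject-side is_a
inheritance and R-transitivity, with the path ending on an R edge. Each
triple is emitted with a witness path. At run time the object side
generalizes over is_a ancestors, so an exon may attach to a concrete mRNA
because `exon part_of transcript` holds and `mRNA is_a transcript`. The
biologically wrong direction (`CDS part_of promoter`) is not entailed and
is refused.

**Relationship inference.** Features f, g of one entry are related by R
when (i) their types are admissible for R, (ii) they are
qualifier-consistent (shared `/locus_tag` or `/gene` value; `/protein_id`
for derives_from; if neither carries any, location decides), and (iii)
span(f) ⊆ span(g) on the same strand. Among several admissible parents the
smallest containing one wins (covered length, then span, then entry
order), so a CDS attaches to its mRNA, not directly to the gene.

**Implicit introns.** For transcript- and CDS-class features with spliced
locations `join((s₁,e₁),(s₂,e₂),…)`, every gap with s₂ > e₁+1 yields an
intron `(e₁+1, s₂−1)` on the donor's strand, stored as an inferred feature
with a part_of edge to each donor — unless an explicit intron feature with
those coordinates already exists.

**Reference evidence.** A feature is linked to a bibliographic reference
when its span lies within one of the reference's cited base ranges.

**Loading.** The rule engine emits an ordered list of insert statements
with symbolic `count` identifiers; a later statement cites an earlier one
through `foreign_counts`, and the executor substitutes the
database-generated primary key at run time. One transaction per entry;
a job ledger with ready/pending/loaded states makes batch loads resumable
and crash-safe (exactly-once effect per GI).

## Worked example

Everything below runs offline on generated data with planted ground truth:

```
$ ontoload fixtures generate --n 4 --seed 11 --profile nested_gene_models --out demo.gbff
4 entries -> demo.gbff (manifest: demo.gbff.manifest.json)
$ ontoload --db-url demo.db init-db
schema ready: 15 tables in demo.db
$ ontoload --db-url demo.db setup-ontology
ontology installed: 32 terms, 106 closure paths, 32 admissible triples
$ ontoload --db-url demo.db load demo.gbff
loaded=4 skipped=0 failed=0
$ ontoload --db-url demo.db status
ready=0 pending=0 loaded=4
```

The first entry's feature table (gene/mRNA/CDS/exons plus a promoter and a
polyA signal) is now stored with its types, the inferred relationship tree,
and one inferred intron (300..446 — the gap between the two exons):

```
source       SO:2000061    1..1396
promoter     SO:0000167   24..78
gene         SO:0000704   23..628
mRNA         SO:0000234  115..595
CDS          SO:0000316  139..568
exon         SO:0000147  115..299
exon         SO:0000147  447..595
mat_peptide  SO:0000419  142..202
polyA_signal SO:0000551  597..602
intron       SO:0000188  300..446   (inferred)
```

An ontological query in the tree notation — find regulatory regions of
genes whose CDS is annotated with product VP35 — returns the promoter and
the polyA signal of that gene, even though neither feature mentions VP35:

```
$ ontoload --db-url demo.db query \
    "regulatory_region memberOf (gene hasMember (CDS hasAnnotation product=VP35))"
2       SYN10110000     SO:0000167      24      78      forward
9       SYN10110000     SO:0000551      597     602     forward
```

Column order: feature id, entry accession, SO type, span start, span end,
strand. The root term was expanded through `cvpath` (promoter and
polyA_signal_sequence are regulatory_region descendants) and the
`memberOf`/`hasMember` chain traversed the stored part_of/member_of edges
transitively (CDS → mRNA → gene).

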