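# Methods

## Scope and model

genovault is an embedded exploration layer for reference and
subject-personalized genomes and proteomes.  Its data model is the
Ensembl-style annotation hierarchy — genome → chromosome → gene →
transcript → exon, with a protein per coding transcript — stored in a
single SQLite file, one table per record kind.  On top of that sit two
mechanisms: a lazy object store that serves records in minimal view, and
a personalization engine that overlays polymorphism sets (SNPs and short
indels) on a reference and derives subject-specific transcript and
protein sequences on demand.

The intended organisms are diploid nuclear genomes annotated in the
Ensembl GTF dialect.  Only the standard genetic code is implemented (the
code-table argument of `translate` is the extension point); selenocysteine,
mitochondrial codes, RNA editing, structural variants and phased
haplotype pairs are out of scope.

## Coordinates

All internal coordinates are 0-based half-open `[start, end)`, so
`end - start` is always a length.  GTF (1-based inclusive) and VCF
(1-based, anchor-base conventions) are converted exactly once, at the
parser boundary, and back-converted on export.  VCF REF/ALT pairs are
normalized by trimming shared leading then trailing bases; after
normalization a variant is exactly one of:

* substitution — one base for one base, at `position`;
* insertion — `alt` inserted immediately **after** `position` (the anchor
  base);
* deletion — `len(ref)` bases removed starting at `position`.

Trimming is idempotent, which the test suite asserts directly.

## The lazy store

`get(kind, filter)` is the single query entry point; filters are
conjunctions of equals / less-than / greater-than / prefix constraints
compiled to SQL.  Records come back in *minimal view*: heavy columns
(chromosome, transcript and protein sequences) are fetched by a second
one-row query on first attribute access.  Every heavy fetch is appended
to a load-event log, which is how the laziness guarantees are asserted
rather than assumed.  Loaded records are per-session singletons keyed by
`(kind, id)`, so inflation through one handle is visible through all
handles and a chromosome sequence is loaded at most once per session.
The singleton cache is unbounded — at the intended working scale (a few
chromosomes of interest at a time) eviction buys nothing — and sessions
are single-threaded by contract.

Index creation is user-controlled (`ensure_global_index` /
`drop_global_index`, idempotent both ways) because indexing every field
of every imported genome would bloat the store; indexes may change query
speed but never query results, and that invariance is tested over random
filters.

## Personalization

A `PersonalizedGenome` binds a reference name, an ordered list of
polymorphism-set names and an *allele filter*.  The filter is the user's
decision procedure: for each locus carrying variants it receives every
candidate polymorphism (across all bound sets, grouped by position) and
returns one decision — keep reference, substitute one (possibly IUPAC)
base, insert, or delete.  Sequence assembly is: collect decisions per
exon/CDS interval via the interval index → apply edits to the reference
slice → concatenate intervals in genomic order → reverse-complement for
minus-strand genes → (for proteins) trim the annotated frame offset and
translate, truncating at the first stop.

Numerical/ordering choices:

* Edits are applied in **descending genomic position**, so indel length
  changes never shift pending coordinates; this is provably equivalent to
  editing a position-tagged character list, and the equivalence is tested
  against exactly that brute-force editor on thousands of random cases.
* Retained decisions must have pairwise non-overlapping edit spans
  (insertions count as zero-width points).  Overlaps are a hard
  `ConflictError`: the filter owns conflict resolution and the engine
  refuses to guess.
* Substitution and deletion decisions carry the expected reference
  allele; a disagreement with the stored genome raises a
  `ConsistencyError` naming position, expected and found.
* A deletion crossing an interval boundary is clipped to the overlap with
  a warning (`clip_policy="clip"`, default) or raises in strict mode.
  Splice-site-destroying edits are out of modeling scope; clipping keeps
  the pipeline total.
* An insertion anchored on an interval's half-open end coordinate belongs
  to the downstream interval and is excluded from the upstream one.
* Intronic and intergenic variants never enter transcript or protein
  sequences.

### The default filter

The paper-level contract leaves filter semantics to the user, so the
default had to be deterministic and information-preserving.  For
substitution loci it encodes reference-plus-alternates as the minimal
IUPAC ambiguity code (heterozygosity-preserving: `A` ref + `G` alt →
`R`).  For indels it keeps the reference unless the variant is marked
validated (VCF `FILTER PASS` or a truthy `validated` metadata entry),
because an unvalidated frameshift destroys the entire downstream protein.
Named filters `ref-only`, `validated-only` and `qual-ge:<N>` cover the
common alternatives; arbitrary callables are the library-level interface.

### Translation of ambiguous codons

An ambiguous codon translates by the all-expansions-agree rule: if every
concrete expansion gives the same amino acid, that amino acid is emitted;
if all expansions are stops, a stop; otherwise `X`.  This is a design
choice of this package (the behavior is unspecified upstream) and it is
cross-checked against Biopython's independent implementation on all 64
concrete codons and hundreds of random ambiguous ones.

## Interval index

Annotations and polymorphisms are indexed per chromosome in a balanced
interval tree (the `intervaltree` library) under half-open overlap
semantics; a zero-length locus (insertion anchor) is indexed as
`[pos, pos+1)` so exon-range queries find it.  The contract is oracle
equivalence with a naive linear scan — asserted over tens of thousands of
random intervals and queries — not any particular tree shape.  Indexes
are rebuilt per session; they are cheap at this scale and persisting them
would complicate the single-file store story.

## Synthetic datawraps and oracle independence

The fixture generator stands in for genome-scale Ensembl/dbSNP datawraps.
Its defaults define the test conditions: one 10 kb chromosome, 2 genes
(one per strand), 3 transcripts, 7 exons (seed 42), and a variant set of
5 VCF lines — two simple substitutions (one low-quality, q=10, the rest
drawn from U(30, 60) with `FILTER PASS`), one multi-allelic substitution
with two alternates, one 2 bp insertion and one 3 bp deletion — all
placed inside coding sequence with ≥5 bp margins from interval boundaries
and pairwise non-overlapping edit spans.  Exon/intron lengths (60–150 /
30–80 bp) are toy-scale choices that keep multi-exon splicing, both
strands and CDS trimming in play while the whole suite stays in seconds.

Every planted fact is recorded in a ledger computed by a deliberately
separate oracle: Biopython for reverse complement, IUPAC sets and
codon translation, and a position-tagged-list editor for variant
application.  The pipeline shares no code with this oracle, so byte
equality between the two is an end-to-end check, not a tautology.

What the toy data does *not* emulate: realistic base composition and
length distributions, UTR-rich gene structure, overlapping genes,
population allele frequencies, genotype phasing, or genome-scale data
volume.  Passing tests therefore demonstrate correctness of the
coordinate arithmetic, the edit/assembly/translation semantics and the
store contracts — not performance or robustness at human-genome scale.

## Problem sizes used in checks

The stochastic checks run at sizes chosen to exercise the algorithms well
past the fixture scale while keeping the whole suite interactive: 2 000
random edit sets on 1 kb sequences (10 seeds) for the edit engine, 10⁴
random intervals × 500 queries per seed for the interval index, 200
random ambiguous codons for translation, 50 random filter specifications
for index invariance.  `scripts/acceptance.py` recomputes all of these
from scratch and reports agreement rates; the CLI `--seed` drives the
stochastic parts, while the toy datawrap keeps its defining seed.

## Known limitations

* One decision per locus: a filter cannot apply two alternates of a
  multi-allelic site simultaneously (the IUPAC encoding is the supported
  way to retain both).
* Complex multi-base substitutions (same-length REF/ALT blocks after
  trimming) are rejected at VCF parse time rather than decomposed.
* Concurrent writers are unsupported; the store is a single-user
  embedded file by design.
* `validate_hierarchy` checks containment, ordering, strand and CDS
  coverage, not biological plausibility (e.g. start codons).
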