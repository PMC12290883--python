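# Methods

This note documents the models, algorithms and numerical choices behind
`litkg`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Data model

A corpus is an ordered list of documents, each with a digit-string PMID,
bibliographic metadata and labeled sections (`abstract`, `intro`,
`results`, `discuss`, `other`). Long sections may be processed in
chunks; a chunk is addressed by a provenance key `<pmid>_<label><ordinal>`
(`37008510_intro`, `24009617_intro3`), which round-trips losslessly.
Abstract-only documents are first-class: most of the literature is
available only as abstracts, and all per-section analytics treat the
abstract as just another section. Every extracted statement and entity
definition carries exactly one provenance key, and these keys survive
resolution and graph assembly untouched, so any edge in the final graph
can be traced back to the text chunk asserting it.

## Extraction

Extraction is a backend contract: `extract(section_text, provenance) ->
(triples, definitions)`. The shipped `TemplateExtractor` is a pure
function bound to the synthetic template grammar (active sentences
`A <rel> B in <organ>.`, passive sentences `B <passive> A.`, glossary
sentences `X is defined as D.`); it records passive statements verbatim
in surface order — the grammatical subject becomes the triple source —
because repairing direction is the canonicalizer's job, and an
extraction backend should not need voice-awareness. Entity types are
assigned at extraction time by pattern: AGI locus identifiers
(`AT#G#####`, case-insensitive, tolerating a plural `s`) become
`gene identifier`, template organs `organ`, everything else `gene`. A
live language-model backend plugs in behind the same contract; its
prompt templates are shipped as opaque configuration strings and no test
depends on them. Backend failures are recorded per section and never
abort the surrounding document or corpus.

## Resolution

Text-mined graphs are redundant: the same entity appears under casing,
pluralization, abbreviation and synonym variants, relations under
several tenses and the passive voice. Resolution proceeds in tiers.

**Rules (deterministic).** (1) Case folding: every group of surfaces
differing only by case is rewritten to its most frequent casing, ties
lexicographic. (2) Passive repair: relations matching
`is/are/was/were <participle> by` are rewritten to the active form with
source and target swapped; regular participles use the `-ed → -es`
rule (`is regulated by → regulates`), irregulars come from an editable
map (`bound → binds`), and unlisted passives pass through with a log
entry. (3) Synonym collapsing: among the top-100 most frequent relation
and entity surfaces, morphological variants sharing a stem (a light
verb/plural stemmer) collapse onto the most frequent member of their
group. In the standalone `canonicalize_rules` operation the three rules
run in that order; in the full pipeline rule 3 runs *after* the
embedding tiers, on the vocabulary the resolver left unmerged. The
reason is subtle but important: if a frequent tense variant wins the
most-frequent-form contest *before* the resolver runs, the canonical
surface is erased from the vocabulary and no member-representative rule
can ever restore it.

**Type resolution.** The 30 most frequent entity types seed a reference
set (preserving their integrity); remaining types are processed in
descending frequency, each offered its 10 nearest reference types by
cosine similarity of text embeddings, and either mapped onto one or
promoted into the reference set. The resulting map is idempotent.

**Entity resolution.** Each surface form becomes one record (name,
majority resolved type, concatenated distinct definitions, mention
count) and is embedded as `"name | type | definition"` — the definition
field is what pulls an abbreviation toward its expansion. Embeddings
are clustered by recursive 2-means until every leaf holds at most 30
items (the cap exists so a language-model resolver can see a whole
cluster in one context window; bisection gives a deterministic tree,
with child seeds derived from the parent seed and child index, and a
forced halving for degenerate identical-point clusters). Each leaf is
passed to the resolver backend, which returns sub-clusters with one
member as representative; each sub-cluster is validated once, invalid
ones replaced by the corrected partition; every member then maps to its
representative.

Two repair mechanisms address the fact that leaf boundaries are k-means
artifacts rather than semantic ones: the cluster→resolve→merge cycle is
iterated to a fixpoint (representatives of one round are re-clustered
with a fresh seed), and a final candidate pass offers every surviving
representative together with its 8 nearest neighbor representatives to
the resolver. Both are conservative — all merge authority stays with
the resolver, so an identity resolver merges nothing beyond case
variants — and both are standard record-linkage practice (iterative
deduplication; blocking with candidate adjudication).

**Relation resolution.** Relation surfaces are embedded in their
dominant type context, `"<source type> <relation> <target type>"`, and
clustered with the same machinery.

**Backends.** The mock embedder hashes case-folded character trigrams
(with boundary padding) into 256 buckets and L2-normalizes; it is
deterministic, needs no network, and places casing/plural variants
nearby. 256 buckets keep hash collisions tolerable at desk-scale
vocabularies; the dimension is configurable. The mock resolvers are a
case-folding identity resolver and a synonym-table resolver driven by an
explicit surface→canonical table (the stand-in for a fine-tuned
language model); both choose as representative the member equal to the
group's canonical form when present, otherwise the most frequent member
(ties lexicographic).

## Graph assembly and analytics

Duplicate canonical triples collapse into one edge holding the
order-preserving union of provenance keys, evidence and species
annotations, and the set of original relation surfaces. Entities keep
their surface forms and definitions. Edges are stored directionally;
degree and the ranking tables ignore direction, and degree counts
incident unique edge records (a node tied to the same partner by two
relation types has degree 2 — edges are typed assertions).

Retention is `100 × resolved count / original count` per category at
two decimals, with zero-denominator categories flagged undefined. On
the reference synthetic corpus retention shows the same asymmetry seen
in real mined graphs: entities are heavily redundant (31 % survive),
triples barely at all (99.8 % survive), because distinct statements
rarely collide even when their endpoint names do.

The power-law fit regresses log10 P(k) on log10 k by least squares over
nonzero bins with k ≥ 1 and reports r² plus a discrete
maximum-likelihood exponent as a diagnostic; it refuses to fit fewer
than two bins. The companion benchmark generator builds a
configuration-model graph whose degree sequence is prescribed
deterministically from rounded expected counts ∝ k^−γ; prescribing
rather than sampling the sequence keeps the empirical distribution on
the power law into the tail, which is what a controlled slope-recovery
experiment needs (sampling noise in the tail otherwise biases the
least-squares slope toward zero). Stub-matching artifacts (self-loops,
parallel edges) are collapsed.

Saturation removes a fixed fraction of articles uniformly at random
(100 replicates per fraction by default, one seeded generator for the
whole curve) and recounts unique entities and triples; a linear decay of
the means signals a corpus far from saturation. Fractions are validated
to [0, 1]; fraction 0 reproduces the full-graph counts with zero
standard deviation.

## Query engine

Search modes: `normal` (case-insensitive exact match on canonical name
or any surface form), `substring` (containment), `title` (PubMed-ID
lookup through edge provenance), `author` (requires optional author
metadata; without it the mode is disabled with a clear error). Multiple
hits are ranked by degree, hubs first — a deliberate choice, since
landing-page ranking is otherwise arbitrary. Neighborhoods are induced
subgraphs on the hits plus direct neighbors, reporting node and distinct
paper counts. Filtering restricts node types and edge relations; query
nodes survive regardless of type while they keep at least one edge, and
nodes that were already isolated in the input are kept when their type
is selected (so selecting everything is the identity, while an empty
selection empties the result). The text summary emits one line per
edge, grouped by relation and ordered deterministically, each statement
citing its provenance keys. The mock edge validator declares an edge
supported when both endpoints (any surface form) co-occur in one
sentence of the source text.

## Network comparison

Gene identifiers are normalized before any comparison: AGI locus codes
to upper-case `AT#G#####`, other symbols upper-cased. Overlap is
computed on normalized gene-pair identity only — relation labels ride
along as annotations but do not affect Venn membership. GRN comparisons
keep direction (TF → target); PPI comparisons first project to
unidirectional pairs (endpoints sorted, duplicates collapsed). Score
thresholds are strict inequalities. Curation sampling is uniform
without replacement and deterministic per seed.

## Literature meta-analysis

Keyword matching is case-insensitive, word-boundary and phrase-aware;
no stemming is applied because dictionaries list variants explicitly.
Topic counts are occurrence counts (an abstract mentioning `root` twice
scores 2). Journal×topic matrices divide each journal's topic sums by
that journal's row maximum, so every nonzero row attains 1; all-zero
rows are left and flagged. Co-occurrence edges connect topics co-present
in at least `min_abstracts` abstracts (default 600), weighted by that
count. Method diversity is, per document and category, the fraction of
the category's keywords present anywhere in the document, averaged per
journal. Section yields use linear-interpolation quartiles (the common
default; no convention was otherwise forced) and Tukey bounds
Q1 − 1.5·IQR, Q3 + 1.5·IQR for outlier exclusion. The 2-D embedding of
the topic matrix is delegated to a library t-SNE; this package only
assembles the matrix and records the parameters (perplexity 40, 1,000
iterations).

## The synthetic generator: what it does and does not emulate

The generator plants canonical entities (half AGI-style locus ids, half
two-word alias names with unique upper-case abbreviations), renders
mentions with independent casing / plural / abbreviation variation and
active/passive voice, and introduces every surface with a glossary
sentence carrying the entity's definition. Reference conditions: 100
articles, 200 canonical entities, 6 relation families, variant rates
0.3 / 0.3 / 0.2, passive rate 0.3, 2–4 triples per section, seed 7.
The canonical relation tense is drawn with weight 0.6 (papers mostly
use the third-person singular), the rest uniformly. All random draws
are consumed unconditionally, so raising one variant rate never changes
which other draws fire — the surface vocabulary grows monotonically in
each rate.

It deliberately does **not** emulate scientific prose: sentences follow
a minimal template grammar, definitions follow fixed templates,
synonymy beyond morphology (true aliases, species common names) occurs
only through the abbreviation channel, and there is no extraction noise
— the mock backend recovers planted statements exactly. Passing tests
therefore demonstrate that the resolution protocol and analytics are
correct *given* faithful extraction and an informative resolver; they
do not certify extraction accuracy on real text, which requires a live
backend and manual curation.

## Numerical choices and degenerate inputs

Ties anywhere (frequencies, rankings, representative choice) break
lexicographically. k-means uses 10 restarts per bisection with seeds
derived from (parent seed, child index); identical points exceeding the
cap are split arbitrarily and flagged. Resolution iterates at most 4
cluster rounds and 5 neighbor passes (it converges much earlier on
corpus-scale inputs). Empty corpora, empty sections, empty selections,
zero-denominator retentions, sub-2-bin power-law fits and out-of-range
saturation fractions all either return well-defined empty results or
raise named errors, as documented per function.

## Known limitations

- The hashed-trigram embedder is morphological: it cannot place
  semantically related but textually dissimilar names nearby unless the
  definition field links them. Live embedding backends lift this.
- The synonym-table resolver is only as complete as its table; on real
  data the table would come from a fine-tuned model, with accuracy well
  below 100 %.
- Cluster validation runs once per sub-cluster; corrections are not
  re-validated.
- The relation-class lists for GRN/PPI partitioning are exact-match
  configuration; "or similar" judgments on novel relation surfaces need
  a human or a model.
- Mapping free-text entity names to database gene identifiers for
  external comparison relies on the AGI pattern or explicit annotations;
  alias-to-locus mapping tables are out of scope.
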