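# Methods

This note documents the models and procedures implemented in `pkgraph`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Data model

The corpus is tabular: seven CSV schemas cover author instances
(`Author_List`), entity mentions (`Bio_entities_Main`, plus a mutation
detail table), affiliations, researcher employment/education, and the
grant crosswalk (`NIH_Projects`).  Conventions:

- Entity-mention offsets are 0-based, half-open character positions
  into the abstract, so `mention == abstract[start:end]`.
- CSV files are comma-separated UTF-8 with double-quote escaping.
- An unassigned author is written as `AND_ID = 0` in `Author_List`
  (keeping the column integer-typed) but as an empty cell in every
  other schema; internally absence is `None`/label 0, never a magic
  number in computation.
- Surrogate `id` columns are assigned sequentially on write and not
  retained on read, which makes write∘read∘write byte-stable; the
  `Author_List` `id` is the meaningful instance ID and is retained.

## AND integration

Inputs are two partial clusterings over author-instance IDs.  The
primary source is treated as authoritative: its labels are never
rewritten.  Secondary clusters act only as grouping evidence:

1. primary-labeled instances keep their labels;
2. a secondary cluster with no primary-labeled member receives one
   fresh label for all members, allocated sequentially above the
   maximum primary label, clusters processed in ascending order of
   their smallest member ID (output therefore independent of dict
   iteration order);
3. a secondary cluster with primary-labeled members propagates a
   primary label to its unlabeled members.

When a secondary cluster spans ≥2 distinct primary labels, the labeled
members keep their own labels and unlabeled members take the *majority*
primary label, ties to the smallest.  Majority preserves primary
precision and is deterministic; recency-based and splitting
resolutions were considered and rejected because they either need
metadata the clustering interface does not carry or degrade coverage.
Every such conflict is returned and logged rather than silently
resolved.

Integration is idempotent (re-running with its own output as primary
changes nothing), and on noise-free inputs the output is the truth up
to relabeling of authors invisible to the primary source.

## Evaluation

Precision and recall use most-frequent matching over crosswalk links
(PI_ID, PMID, AND_ID).  Per cluster c, p_c = max_PI |articles(c, PI)| /
|articles(c)|; recall swaps the roles.  Micro aggregation
(article-weighted, i.e. ratio of sums) is the default because the
definitions are phrased in article counts; macro (unweighted mean over
clusters/PIs) is available by flag.  Clusters with no PI link cannot be
evaluated and simply never enter the link relation.  F1 is the
harmonic mean of the two percentages, reported to two decimals;
P = R = 0 is reported as 0 with a warning rather than an error.
Article counts are counts of *distinct* PMIDs.

Lumping is reported as the fraction of clusters containing ≥2 true
individuals; splitting as the fraction of labeled instances whose true
author is spread over ≥2 clusters.

## NER post-processing

The seven-tag scheme is {B, I, O, X, [CLS], [SEP], PAD} in fixed index
order.  `softmax_tags` is a numerically shifted softmax
(scipy's implementation); the sequence loss is the mean negative log
probability of the gold tags, defined as +inf when a gold tag has zero
probability.

Decoding walks argmax tags: B opens a span, I and X extend it, and O,
B, the special tags or end of sequence close it.  Malformed sequences
(an I or X with no open span) are handled leniently by default — the
dangling token opens a span — or dropped in strict mode; both modes are
exercised against an independent reference decoder.  Span confidence is
the mean argmax-tag probability over the span's B/I tokens (all tokens
for a lenient all-X fragment); X tokens are excluded because
sub-token continuations carry no independent boundary evidence.

Cross-type overlap resolution is greedy by descending confidence, ties
broken by the fixed type order gene > disease > drug > species >
mutation, then leftmost start.  The ordering makes the rule a
deterministic, monotone function of the confidences.  Resolution is
per-mention; a per-document variant (one type per surface string per
abstract) was considered and not adopted, as it couples decisions
across unrelated sentence positions.

## Normalization

Dictionary keys canonicalize by casefold + whitespace collapse +
punctuation strip; an exact policy is available where vocabularies are
already clean.  Merging is the union of canonical (name, ID) pairs —
commutative, associative, idempotent — and can create polysemy, which
lookup reports as `ambiguous-unresolved` by default.  The optional
tie-break (more synonyms, then smaller ID) exists because some
downstream uses prefer a forced choice; it is off by default since a
wrong forced ID is worse than an explicit ambiguity flag.  Statistics
report distinct IDs, distinct canonical names, and their ratio rounded
to one decimal; the ratio of an empty dictionary is undefined (`None`),
never 0.

Mutation normalization is plain dictionary lookup over
(mention → normalized name) pairs; no pattern engine for novel variant
nomenclature is included.

## Record linkage

All name matching uses the key (casefolded last name, uppercased first
initial) — the coarsest key the linked sources can all supply.

*Grant crosswalk.*  Projects are filtered in order: zero matched
articles first, then ≥2 PIs (credit would be ambiguous).  The filters
partition the input exactly (`projects_in = retained + dropped_*`), a
conservation law asserted in tests.  For each retained (project, PMID)
the PI's key is matched against the byline; each matching assigned
instance yields one link.

*Registry linkage.*  Pass 1 matches works on (DOI, name key); failures
retry on (canonical title, canonical journal, name key), where
canonicalization is casefold + punctuation strip + whitespace collapse.
Candidate (AND_ID, ORCID) pairs are scored by matched-work count and a
1:1 set is emitted; ties are dropped and logged rather than guessed —
match count was chosen over recency because the work list carries no
reliable dates.

*Affiliations.*  Parsing is segment-based: split on commas; email by
regular expression anywhere; ZIP as a US 5-digit pattern (configurable
patterns are out of scope); country by gazetteer match on the final
segment; institution as the first segment containing an institution
keyword (University, Institute, Hospital, College, Center, ...);
department as the first containing Dept/Department/Division, never
reused as the institution.  Propagation past the parsing-coverage
cutoff year: per author, the latest pre-cutoff record with fine-grained
fields donates to post-cutoff raw-only records **iff** the canonical
institution strings match — "did not change affiliation" is
operationalized as exact canonical institution equality, the strictest
reading, which can only under-propagate.  Pre-cutoff records are never
modified, so coverage is non-decreasing by construction.  Geocode
fields (latitude/longitude/FIPS) are pass-through only.

## Bipartite networks

Edge weight between an author and an entity is the number of distinct
papers (a mention repeated within one abstract counts once).
Projection weight is the plain common-neighbor count, ignoring
bipartite edge weights; it is computed by an inverted neighbor index
(each opposite-side vertex contributes one unit to every pair of its
neighbors) and cross-checked against all-pairs set intersection.
Community detection and layout are out of scope; edge lists export as
TSV for external tools.

## Synthetic worlds

`WorldConfig` defaults: 100 authors; papers per author 1 + Poisson(3)
(mean 4, a modest research career at desk scale); surname pool 40 (so
collisions — homonyms — occur but do not dominate); years 1990–2018;
byline size 1 + Poisson(1.5); DOI coverage 0.8 (DOIs are common but not
universal); ORCID coverage 0.4 and PI coverage 0.3 (registry and funder
coverage are partial in reality); multi-PI rate 0.1 so the crosswalk
filter is exercised.  All sampling flows from one `numpy` generator
seeded by `seed`, so worlds are bit-reproducible.

One deliberate constraint: a byline never lists two authors with the
same name key, because a printed byline cannot distinguish them and no
instance-level ground truth could exist for such a pair.

Noise operators are per-cluster Bernoulli events.  Lumping merges a
marked cluster into a partner — the next same-name-key cluster
cyclically when instance names are supplied (homonyms are what real
disambiguators lump), else the next cluster in label order; cyclic
pairing keeps one mark ≈ one realized merge, so injected rates are
recoverable from the output.  Splitting moves a contiguous
publication-year suffix to a fresh label (a "career break", the
failure mode time-limited sources exhibit).  Truncation unassigns
instances after a cutoff year except a Bernoulli `leak_fraction`
(late-indexed preprints).

What the generator does *not* emulate: realistic abstract text (it
assembles sentences from a fixed term table), name variants and
misspellings, citation structure, non-uniform journal/venue effects,
and correlated noise (real lumping concentrates on common names far
more than a uniform rate).  Passing the synthetic suite therefore
demonstrates algorithmic correctness of each stage and of their
composition — not field performance on real bibliographic data.

## Problem sizes and numerics

The test suite runs worlds of 25–300 authors; oracle-equivalence
checks use 50 random link sets, 200 random tag sequences and random
graphs with ≤20 vertices per side; noise-rate recovery uses 1000
clusters with two-sided 99% binomial acceptance bounds; monotonicity
checks sweep 100 seeded worlds.  These sizes give stable statistics
while the whole suite runs in seconds.  Floating-point comparisons in
oracle tests use absolute tolerance 1e-9 (1e-12 where closed forms
exist); reported percentages are rounded only at the reporting edge,
never inside a computation.

## Known limitations

- The crosswalk assumes a PI appears on the byline of articles their
  project funded; articles acknowledging a grant without the PI as
  author produce no link.
- Name keys use only the first initial; two same-key individuals on
  *different* articles of one project are indistinguishable to the
  crosswalk (this is a property of the evaluation scheme itself).
- Affiliation parsing is rule-based for English-style comma-segmented
  strings; free-form or non-Latin affiliations parse as absent fields.
- Registry linkage trusts title+journal equality in pass 2; retitled
  reprints or journal renames are missed.
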