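# pkgraph

Construction stages for a bibliographic knowledge graph over a
PubMed-style article corpus: disambiguated authors, normalized
bio-entities, funder and registry links, enriched affiliations, and
author–entity networks.  The package is aimed at bibliometrics and
biomedical text-mining researchers who need these stages as tested,
composable library code — every stage runs on synthetic corpora with
known ground truth, so the whole chain is verifiable without any
external data download.

## What it implements

**Author-name-disambiguation (AND) integration.**  Two AND sources are
combined: a *primary* clustering with high precision but a coverage
horizon in time, and a *secondary* clustering with full coverage but
more noise.  Integration (i) keeps every primary label, (ii) allocates a
fresh AND_ID — continuing the primary ID space — to each secondary
cluster the primary never saw, and (iii) propagates a primary ID to the
uncovered members of a secondary cluster that contains primary-labeled
instances (majority label, ties to the smallest, conflicts logged).

**Evaluation against funder ground truth.**  Principal-investigator IDs
from grant records are trusted identities.  With links
(PI_ID, PMID, AND_ID) built by name-key crosswalk,

- precision = per AND_ID cluster, articles of its most frequent PI over
  all its articles;
- recall = per PI, articles in their most frequent cluster over all
  their articles;
- F1 = 2PR/(P+R),

aggregated article-weighted (micro, default) or unweighted (macro),
plus lumping/splitting diagnostics against a known true world.

**NER post-processing.**  From per-token scores over the seven tags
{B, I, O, X, [CLS], [SEP], PAD}: softmax p(T_i) = softmax(T_i W^T + b),
the sequence loss L = −(1/N) Σ log p(y_i|T_i), WordPiece re-merging
(`I ##mm ##uno ##g ##lo ##bul ##in` → `Immunoglobulin`), IOB2 span
decoding, and confidence-based resolution of overlapping spans from
different entity-type channels.

**Dictionary normalization.**  Per-type name→ID multimaps with
canonicalization, vocabulary merging by (name, ID) union, polysemy
reporting and size statistics (IDs, names, names-per-ID).

**Record linkage.**  Grant→article→author crosswalk with the
no-article and multi-PI filters; two-pass registry (ORCID-style)
linkage on (DOI, name) then (title, journal, name) with a 1:1
constraint; affiliation-string parsing (department, institution, email,
ZIP, country) and forward propagation of fine-grained fields past a
parsing-coverage cutoff when the institution is unchanged.

**Bipartite author–entity networks.**  Edge weight = distinct papers by
an author mentioning an entity; one-mode projections weighted by common
neighbors.

A synthetic-corpus generator produces worlds of true authors (with
controlled name homonymy), articles, abstracts with located entity
mentions, registry and project records, and noise operators
(lump/split perturbation, time truncation) so that every stage above is
exercised end to end.

## Worked example

```bash
python examples/04_integrate_and_evaluate.py
```

```
precision 99.15  recall 98.29  F1 98.72 (micro, on 234 crosswalk links)
lumped clusters: 3.883%, split-author instances: 6.950%
  primary: 485 instances
  secondary-new: 31 instances
  secondary-propagated: 261 instances
```

A 200-author world is generated; the primary clustering is truncated
ten years before the end of the corpus and the secondary gets 5% lump
and 5% split noise.  Integration keeps the 485 primary-labeled
instances untouched, invents 31 fresh IDs for authors the primary never
saw, and propagates primary IDs to 261 instances.  The evaluation runs
through the PI crosswalk: precision dips below 100 where lumping merged
two people, recall where splitting scattered one person.  With all
noise rates at zero the same pipeline scores exactly 100/100/100.

The other `examples/*.py` scripts each demonstrate one capability
(corpus generation, span decoding, normalization, linkage, networks)
and print a short interpretation with their numbers.

A thin CLI mirrors the library (`pkgraph simulate`, `pkgraph validate`,
`pkgraph decode-ner`, `pkgraph integrate-and`, `pkgraph evaluate-and`,
`pkgraph graph build|project`, ...); run `pkgraph --help`.

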