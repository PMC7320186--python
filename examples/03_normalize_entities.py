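"""Dictionary-based entity normalization with merging and ambiguity.

Each entity type owns a name -> ID multimap; merging a second vocabulary
takes the union of (name, ID) pairs, which can make a name ambiguous.
"""

from pkgraph.normalize import (
    build_dictionary,
    dictionary_stats,
    merge_dictionaries,
    normalize_mention,
)

base = build_dictionary([("influenza", 1), ("flu", 1), ("measles", 3)], "disease")
extra = build_dictionary([("flu", 2), ("grippe", 1)], "disease")
merged = merge_dictionaries(base, extra)

stats = dictionary_stats(merged)
print(f"merged dictionary: {stats.n_ids} IDs, {stats.n_names} names, "
      f"{stats.avg_names_per_id} names per ID on average")

for mention in ["Influenza", "flu", "rubella"]:
    r = normalize_mention(mention, "disease", merged)
    print(f"{mention!r}: {r.status}"
          + (f" -> ID {r.entity_id}" if r.entity_id else "")
          + (f" (candidates {sorted(r.candidates)})" if len(r.candidates) > 1 else ""))
# 'Influenza' hits one ID (case folds away); 'flu' is polysemous after the
# merge and stays unresolved by default; 'rubella' is not in the dictionary.
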