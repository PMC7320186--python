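"""Decode per-token tag scores into typed entity spans.

A sequence labeller scores each WordPiece sub-token over seven tags
(B, I, O, X, [CLS], [SEP], PAD).  Decoding merges ``##`` continuations
back into words, walks the argmax tags into spans, and resolves
cross-type character overlaps by span confidence.
"""

import numpy as np

from pkgraph.ner import TAGS, TokenTagMatrix, decode_spans, resolve_type_overlap

tokens = ["[CLS]", "I", "##mm", "##uno", "##g", "##lo", "##bul", "##in",
          "deficiency", "[SEP]"]
tags = ["[CLS]", "B", "X", "X", "X", "X", "X", "X", "O", "[SEP]"]

logits = np.full((len(tokens), 7), -4.0)
for i, t in enumerate(tags):
    logits[i, TAGS.index(t)] = 4.0

gene = TokenTagMatrix(tokens, logits, entity_type_channel="gene")
for span in decode_spans(gene):
    print(f"gene channel: {span.surface!r} tokens [{span.token_start}, "
          f"{span.token_end}) confidence {span.confidence:.3f}")
# The seven sub-tokens merge back into one surface word; special tokens
# never enter the span.

# When two type channels claim overlapping characters, the more confident
# span wins:
disease = TokenTagMatrix(tokens, logits * 0.5, entity_type_channel="disease")
resolved = resolve_type_overlap([decode_spans(gene), decode_spans(disease)])
print("after overlap resolution:",
      [(s.entity_type, s.surface, round(s.confidence, 3)) for s in resolved])
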