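"""From per-token tag scores to typed entity spans.

A sequence labeller emits, for every WordPiece sub-token, a score vector
over seven tags: the IOB2 tags ``B`` (begin), ``I`` (inside), ``O``
(outside), plus ``X`` (a WordPiece continuation sub-token), ``[CLS]``,
``[SEP]`` and ``PAD``.  This module owns everything downstream of those
scores: the softmax that turns logits into tag probabilities, the
mean negative-log-likelihood sequence loss (for verification), merging
``##``-prefixed sub-tokens back into surface words, decoding tag
sequences into entity spans, and resolving character overlaps between
spans of different entity types by confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import softmax as _softmax

logger = logging.getLogger(__name__)

#: The seven tags, in fixed index order.
TAGS = ("B", "I", "O", "X", "[CLS]", "[SEP]", "PAD")
K = len(TAGS)
_TAG_INDEX = {t: i for i, t in enumerate(TAGS)}

_SPECIAL_TOKENS = {"[CLS]", "[SEP]", "PAD", "[PAD]"}

#: Fixed priority used to break confidence ties between entity types.
TYPE_PRIORITY = ("gene", "disease", "drug", "species", "mutation")


def softmax_tags(logits: Sequence[float]) -> np.ndarray:
    """Softmax over the 7 tag logits.

    Shift-invariant and argmax-preserving; raises ``ValueError`` on
    non-finite input.
    """
    arr = np.asarray(logits, dtype=float)
    if arr.shape[-1] != K:
        raise ValueError(f"expected length-{K} logits, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite logits")
    return _softmax(arr, axis=-1)


def sequence_loss(
    probabilities: np.ndarray, gold_labels: Sequence[Union[int, str]]
) -> float:
    """Mean negative log-likelihood of the gold tags.

    ``L = -(1/N) * sum_i log p(y_i | token_i)``; zero probability at a gold
    label yields ``inf`` rather than an exception.  ``L == 0`` exactly when
    every gold label has probability 1.
    """
    probs = np.asarray(probabilities, dtype=float)
    n = probs.shape[0]
    if n == 0:
        raise ValueError("empty sequence")
    if len(gold_labels) != n:
        raise ValueError("one gold label required per token")
    idx = np.array([_TAG_INDEX[y] if isinstance(y, str) else int(y) for y in gold_labels])
    p = probs[np.arange(n), idx]
    if np.any(p <= 0.0):
        return float("inf")
    return float(-np.mean(np.log(p)))


@dataclass
class TokenTagMatrix:
    """Sub-tokens of one sentence plus their per-tag scores.

    ``scores`` is an (N, 7) array of logits, or of probabilities when
    ``is_probability`` is set (rows then sum to 1).
    ``entity_type_channel`` names the entity type this matrix scores.
    """

    tokens: list[str]
    scores: np.ndarray
    entity_type_channel: str = "gene"
    is_probability: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.tokens), K):
            raise ValueError(
                f"scores shape {self.scores.shape} != ({len(self.tokens)}, {K})")
        if self.is_probability:
            if np.any(self.scores < 0) or np.any(
                np.abs(self.scores.sum(axis=1) - 1.0) > 1e-9
            ):
                raise ValueError("probability rows must be non-negative and sum to 1")

    def probabilities(self) -> np.ndarray:
        return self.scores if self.is_probability else softmax_tags(self.scores)


@dataclass
class EntitySpan:
    """One decoded entity: a token range, its character range in the merged
    sentence text, the merged surface form, and a confidence equal to the
    mean probability of its B/I tags."""

    token_start: int
    token_end: int
    char_start: int
    char_end: int
    surface: str
    entity_type: str
    confidence: float

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.char_start < other.char_end and other.char_start < self.char_end


def merge_wordpieces(tokens: Sequence[str]) -> tuple[str, list[tuple[int, int]]]:
    """Rebuild surface text from WordPiece sub-tokens.

    ``##``-prefixed continuations are appended to the preceding unit; other
    tokens start a new space-separated word.  Returns the merged text and
    one (start, end) character range per sub-token.  A leading ``##`` token
    (no unit to attach to) is treated as its own word and logged.
    """
    text = ""
    ranges: list[tuple[int, int]] = []
    for i, tok in enumerate(tokens):
        if tok.startswith("##") and len(tok) > 2:
            piece = tok[2:]
            if i == 0 or tokens[i - 1] in _SPECIAL_TOKENS:
                logger.warning("leading continuation token %r treated as a word", tok)
                if text:
                    text += " "
                start = len(text)
                text += piece
            else:
                start = len(text)
                text += piece
        else:
            if text:
                text += " "
            start = len(text)
            text += tok
        ranges.append((start, len(text)))
    return text, ranges


def decode_spans(matrix: TokenTagMatrix, mode: str = "lenient") -> list[EntitySpan]:
    """Decode argmax tags into entity spans.

    A span opens at ``B``, extends through ``I`` and ``X``, and closes at
    ``O``, ``B``, ``[CLS]``, ``[SEP]``, ``PAD`` or end of sequence.  An
    ``I`` or ``X`` with no open span opens one in ``lenient`` mode
    (default) and is dropped in ``strict`` mode.  Special tokens never
    appear inside a returned surface.  Confidence is the mean argmax-tag
    probability over the span's B/I tokens (over all its tokens if the
    span has none, e.g. a lenient all-X fragment).
    """
    if mode not in ("lenient", "strict"):
        raise ValueError(f"mode must be 'lenient' or 'strict', got {mode!r}")
    probs = matrix.probabilities()
    tag_idx = np.argmax(probs, axis=1)
    text, ranges = merge_wordpieces(matrix.tokens)

    spans: list[EntitySpan] = []
    open_start: Optional[int] = None

    def close(end: int) -> None:
        nonlocal open_start
        if open_start is None:
            return
        toks = range(open_start, end)
        bi = [t for t in toks if TAGS[tag_idx[t]] in ("B", "I")]
        conf_tokens = bi if bi else list(toks)
        conf = float(np.mean([probs[t, tag_idx[t]] for t in conf_tokens]))
        cs, ce = ranges[open_start][0], ranges[end - 1][1]
        spans.append(EntitySpan(
            token_start=open_start, token_end=end, char_start=cs, char_end=ce,
            surface=text[cs:ce], entity_type=matrix.entity_type_channel,
            confidence=conf,
        ))
        open_start = None

    for i, tok in enumerate(matrix.tokens):
        tag = TAGS[tag_idx[i]]
        special = tok in _SPECIAL_TOKENS or tag in ("[CLS]", "[SEP]", "PAD")
        if special or tag == "O":
            close(i)
        elif tag == "B":
            close(i)
            open_start = i
        else:  # I or X
            if open_start is None and mode == "lenient":
                open_start = i
            # strict mode: dangling I/X dropped
    close(len(matrix.tokens))
    return spans


def resolve_type_overlap(
    span_lists: Sequence[Sequence[EntitySpan]],
) -> list[EntitySpan]:
    """Resolve character overlaps between spans of different type channels.

    Greedy by descending confidence; ties broken by the fixed type order
    gene > disease > drug > species > mutation, then by leftmost start.
    Kept spans are pairwise non-overlapping; spans that conflict with
    nothing pass through untouched.
    """
    prio = {t: i for i, t in enumerate(TYPE_PRIORITY)}
    flat = [s for lst in span_lists for s in lst]
    order = sorted(
        flat,
        key=lambda s: (-s.confidence, prio.get(s.entity_type, len(prio)),
                       s.char_start, s.char_end),
    )
    kept: list[EntitySpan] = []
    for span in order:
        if not any(span.overlaps(k) for k in kept):
            kept.append(span)
    kept.sort(key=lambda s: (s.char_start, s.char_end))
    return kept


# ---------------------------------------------------------------------------
# tag-matrix file format: TSV of token + 7 score columns, blank line
# between sentences

def read_tag_matrix_file(
    path, entity_type: str = "gene", is_probability: bool = False
) -> list[TokenTagMatrix]:
    """Read sentence tag matrices from a TSV file (token, then the 7 score
    columns in tag order; one blank line between sentences)."""
    sentences: list[TokenTagMatrix] = []
    tokens: list[str] = []
    scores: list[list[float]] = []

    def flush() -> None:
        nonlocal tokens, scores
        if tokens:
            sentences.append(TokenTagMatrix(
                tokens=tokens, scores=np.array(scores),
                entity_type_channel=entity_type, is_probability=is_probability))
        tokens, scores = [], []

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cells = line.split("\t")
            if len(cells) != 1 + K:
                raise ValueError(f"{path}:{lineno}: expected token + {K} scores")
            tokens.append(cells[0])
            scores.append([float(c) for c in cells[1:]])
    flush()
    return sentences


def write_tag_matrix_file(matrices: Sequence[TokenTagMatrix], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, matrix in enumerate(matrices):
            if m:
                fh.write("\n")
            for tok, row in zip(matrix.tokens, matrix.scores):
                fh.write(tok + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
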