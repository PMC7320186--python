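"""Tag softmax, sequence loss, WordPiece merging, span decoding and
multi-type overlap resolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkgraph.ner import (
    K,
    TAGS,
    EntitySpan,
    TokenTagMatrix,
    decode_spans,
    merge_wordpieces,
    read_tag_matrix_file,
    resolve_type_overlap,
    sequence_loss,
    softmax_tags,
    write_tag_matrix_file,
)

finite_logits = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=K, max_size=K)


class TestSoftmax:
    def test_uniform_logits_give_one_seventh(self):
        assert np.allclose(softmax_tags([2.0] * K), np.full(K, 1 / 7))

    def test_saturated_logit_dominates(self):
        p = softmax_tags([1000.0, 0, 0, 0, 0, 0, 0])
        assert abs(p[0] - 1.0) < 1e-12

    def test_matches_direct_exponentiation_oracle(self):
        logits = np.array([1.0, 2.0, 3.0, 0.0, 0.0, 0.0, 0.0])
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(softmax_tags(logits), expected, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(finite_logits)
    def test_normalization_shift_invariance_argmax(self, logits):
        p = softmax_tags(logits)
        assert p.min() >= 0 and abs(p.sum() - 1.0) < 1e-9
        shifted = softmax_tags([x + 13.5 for x in logits])
        assert np.allclose(p, shifted, atol=1e-9)
        ordered = sorted(logits, reverse=True)
        if ordered[0] - ordered[1] > 1e-6:  # argmax only well-defined off ties
            assert np.argmax(p) == np.argmax(logits)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax_tags([np.inf, 0, 0, 0, 0, 0, 0])


class TestSequenceLoss:
    def test_perfect_one_hot_gives_zero(self):
        probs = np.eye(K)[[0, 1, 2, 0]]
        assert sequence_loss(probs, [0, 1, 2, 0]) == 0.0

    def test_uniform_gives_ln_seven(self):
        probs = np.full((4, K), 1 / 7)
        assert math.isclose(sequence_loss(probs, ["O", "B", "I", "X"]), math.log(7),
                            rel_tol=1e-12)

    def test_matches_term_by_term_summation_oracle(self, rng):
        logits = rng.normal(size=(5, K))
        probs = softmax_tags(logits)
        labels = rng.integers(0, K, size=5)
        expected = -sum(math.log(probs[i, labels[i]]) for i in range(5)) / 5
        assert math.isclose(sequence_loss(probs, labels.tolist()), expected,
                            rel_tol=1e-12)

    def test_zero_probability_gold_label_is_inf(self):
        probs = np.eye(K)[[0, 0]]
        assert sequence_loss(probs, [0, 3]) == float("inf")

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_with_equality_iff_certain(self, seed):
        rng = np.random.default_rng(seed)
        probs = softmax_tags(rng.normal(size=(6, K)))
        labels = rng.integers(0, K, size=6).tolist()
        loss = sequence_loss(probs, labels)
        assert loss >= 0.0
        certain = all(probs[i, labels[i]] == 1.0 for i in range(6))
        assert (loss == 0.0) == certain


class TestMergeWordpieces:
    def test_immunoglobulin_tokenization(self):
        text, ranges = merge_wordpieces(
            ["I", "##mm", "##uno", "##g", "##lo", "##bul", "##in"])
        assert text == "Immunoglobulin"
        assert ranges[0] == (0, 1) and ranges[-1] == (12, 14)

    def test_single_token_identity(self):
        assert merge_wordpieces(["BRCA1"]) == ("BRCA1", [(0, 5)])

    def test_leading_continuation_is_own_word(self, caplog):
        with caplog.at_level("WARNING"):
            text, ranges = merge_wordpieces(["##ab", "cd"])
        assert text == "ab cd"
        assert any("leading" in r.message for r in caplog.records)

    def test_char_map_total_and_monotone(self):
        tokens = ["alpha", "##bet", "gamma", "##de", "##lta", "x"]
        text, ranges = merge_wordpieces(tokens)
        assert len(ranges) == len(tokens)
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            assert s1 < e1 and s1 <= s2 and e1 <= e2

    def test_inverts_reference_tokenizer_on_dictionary_words(self, rng):
        """Randomly re-tokenize words WordPiece-style; merging restores them."""
        words = ["hemoglobin", "serotonin", "microbiome", "antibody",
                 "receptor", "inhibitor", "sequence", "carcinoma",
                 "neuron", "enzyme", "peptide", "genome", "protein",
                 "kinase", "ligand", "vector", "plasmid", "epitope",
                 "operon", "chromatin"]
        for word in words:
            cuts = sorted(rng.choice(range(1, len(word)),
                                     size=int(rng.integers(0, 4)), replace=False))
            pieces, prev = [], 0
            for c in list(cuts) + [len(word)]:
                piece = word[prev:c]
                pieces.append(piece if prev == 0 else "##" + piece)
                prev = c
            text, _ = merge_wordpieces(pieces)
            assert text == word


def _matrix_for_tags(tokens, tags, margin=5.0, entity_type="gene", rng=None):
    scores = np.full((len(tokens), K), -margin)
    for i, t in enumerate(tags):
        scores[i, TAGS.index(t)] = margin
    if rng is not None:
        scores += rng.normal(scale=0.5, size=scores.shape)
        for i, t in enumerate(tags):  # keep the argmax on the intended tag
            scores[i, TAGS.index(t)] += 3.0
    return TokenTagMatrix(tokens, scores, entity_type_channel=entity_type)


def reference_decode(tokens, tags, mode="lenient"):
    """Independent decoder: enumerate candidate (start, end) token ranges
    and keep the maximal ones consistent with the tag rules."""
    n = len(tokens)
    special = {"[CLS]", "[SEP]", "PAD", "[PAD]"}

    def opens(i):
        if tokens[i] in special or tags[i] in ("[CLS]", "[SEP]", "PAD", "O"):
            return False
        if tags[i] == "B":
            return True
        # a dangling I/X opens only in lenient mode (coverage checked below)
        return mode == "lenient"

    def extends(i):
        return tokens[i] not in special and tags[i] in ("I", "X")

    candidates = []
    for start in range(n):
        if not opens(start):
            continue
        # an I/X start is real only if no earlier span already covers it
        if tags[start] != "B" and any(s <= start < e for s, e in candidates):
            continue
        end = start + 1
        while end < n and extends(end) and tokens[end] not in special:
            end += 1
        candidates.append((start, end))
    return candidates


class TestDecodeSpans:
    def test_all_outside_gives_no_spans(self):
        m = _matrix_for_tags(["a", "b", "c"], ["O", "O", "O"])
        assert decode_spans(m) == []

    def test_immunoglobulin_single_span(self):
        tokens = ["I", "##mm", "##uno", "##g", "##lo", "##bul", "##in"]
        m = _matrix_for_tags(tokens, ["B", "X", "X", "X", "X", "X", "X"])
        (span,) = decode_spans(m)
        assert span.surface == "Immunoglobulin"
        assert (span.token_start, span.token_end) == (0, 7)

    def test_special_tokens_never_in_surface(self):
        tokens = ["[CLS]", "BRCA1", "mutations", "[SEP]"]
        m = _matrix_for_tags(tokens, ["[CLS]", "B", "O", "[SEP]"])
        (span,) = decode_spans(m)
        assert span.surface == "BRCA1"

    def test_strict_mode_drops_dangling_inside_tag(self):
        tokens = ["a", "b", "c"]
        m = _matrix_for_tags(tokens, ["O", "I", "O"])
        assert decode_spans(m, mode="strict") == []
        (span,) = decode_spans(m, mode="lenient")
        assert span.surface == "b"

    @pytest.mark.parametrize("mode", ["lenient", "strict"])
    def test_random_sequences_match_reference_decoder(self, mode, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            tokens = []
            for i in range(n):
                r = rng.random()
                if r < 0.15 and i > 0:
                    tokens.append("##" + "abcdefg"[int(rng.integers(7))])
                elif r < 0.2:
                    tokens.append(["[CLS]", "[SEP]", "PAD"][int(rng.integers(3))])
                else:
                    tokens.append("tok%d" % i)
            tags = [TAGS[int(rng.integers(K))] for _ in range(n)]
            m = _matrix_for_tags(tokens, tags, rng=rng)
            got = [(s.token_start, s.token_end) for s in decode_spans(m, mode=mode)]
            expected = reference_decode(tokens, tags, mode=mode)
            assert got == expected, (tokens, tags)

    def test_surfaces_are_substrings_of_merged_text(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            tokens = ["t%d" % i for i in range(n)]
            tags = [TAGS[int(rng.integers(K))] for _ in range(n)]
            m = _matrix_for_tags(tokens, tags)
            text, _ = merge_wordpieces(tokens)
            for span in decode_spans(m):
                assert span.surface in text

    def test_confidence_is_mean_bi_probability(self):
        tokens = ["x", "##y"]
        scores = np.array([[3.0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 2.0, 0, 0, 0]])
        m = TokenTagMatrix(tokens, scores)
        (span,) = decode_spans(m)
        probs = m.probabilities()
        assert math.isclose(span.confidence, probs[0, 0])  # only the B token counts


def _span(cs, ce, etype, conf):
    return EntitySpan(token_start=0, token_end=1, char_start=cs, char_end=ce,
                      surface="s", entity_type=etype, confidence=conf)


class TestResolveTypeOverlap:
    def test_disjoint_spans_all_kept(self):
        spans = [[_span(0, 5, "gene", 0.9)], [_span(10, 15, "disease", 0.8)]]
        assert len(resolve_type_overlap(spans)) == 2

    def test_identical_range_higher_confidence_wins(self):
        out = resolve_type_overlap(
            [[_span(0, 5, "gene", 0.9)], [_span(0, 5, "disease", 0.7)]])
        assert [s.entity_type for s in out] == ["gene"]

    def test_confidence_tie_broken_by_type_order(self):
        out = resolve_type_overlap(
            [[_span(0, 5, "mutation", 0.8)], [_span(0, 5, "disease", 0.8)]])
        assert [s.entity_type for s in out] == ["disease"]

    def test_three_way_chain_matches_exhaustive_characterization(self, rng):
        """Greedy output must be maximal, overlap-free, and dominate every
        dropped span it conflicts with — checked exhaustively on <= 6 spans."""
        types = ["gene", "disease", "drug", "species", "mutation"]
        for _ in range(100):
            k = int(rng.integers(2, 7))
            spans = []
            for _ in range(k):
                cs = int(rng.integers(0, 10))
                ce = cs + int(rng.integers(1, 6))
                spans.append(_span(cs, ce, types[int(rng.integers(5))],
                                   round(float(rng.random()), 3)))
            kept = resolve_type_overlap([spans])
            # overlap-free
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert not a.overlaps(b)
            dropped = [s for s in spans if s not in kept]
            for d in dropped:
                conflicting = [x for x in kept if x.overlaps(d)]
                assert conflicting, "dropped span without conflict (not maximal)"
                assert max(x.confidence for x in conflicting) >= d.confidence


def test_tag_matrix_tsv_round_trip(tmp_path, rng):
    mats = [
        TokenTagMatrix(["a", "##b", "c"], rng.normal(size=(3, K))),
        TokenTagMatrix(["just", "one"], rng.normal(size=(2, K))),
    ]
    path = tmp_path / "m.tsv"
    write_tag_matrix_file(mats, path)
    back = read_tag_matrix_file(path)
    assert len(back) == 2
    for orig, rt in zip(mats, back):
        assert rt.tokens == orig.tokens
        assert np.allclose(rt.scores, orig.scores)
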