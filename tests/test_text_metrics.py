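"""Tokenization and pairwise pattern-recognition metrics."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from platewatch.config import ScreenConfig
from platewatch.text_metrics import (
    bigram_overlap,
    compare,
    find_duplicates,
    jaccard_similarity,
    screen_pair,
    tokenize,
    type_token_ratio,
)
from platewatch.types import TokenSequence

from .conftest import SENTENCE_1, SENTENCE_2

tokens_st = st.lists(
    st.text(alphabet="abcde", min_size=1, max_size=3), min_size=0, max_size=30
).map(lambda ts: TokenSequence(tokens=tuple(ts)))


# --- oracles: explicit enumeration, independent of the implementation -----

def oracle_jaccard(a, b):
    sa = {t for t in a.tokens}
    sb = {t for t in b.tokens}
    union = sa | sb
    if not union:
        return None
    return len(sa & sb) / len(union)


def oracle_bigrams(seq):
    out = set()
    for i in range(len(seq.tokens) - 1):
        out.add((seq.tokens[i], seq.tokens[i + 1]))
    return out


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("", ()),
            ("Good ambience and service.", ("good", "ambience", "and", "service")),
            ("buffet 50off that was really cool", ("buffet", "50off", "that", "was", "really", "cool")),
            ("5th star!!", ("5th", "star")),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text).tokens == expected

    def test_idempotent(self):
        seq = tokenize(SENTENCE_1)
        assert tokenize(" ".join(seq.tokens)).tokens == seq.tokens


class TestTypeTokenRatio:
    def test_printed_count_ratio(self):
        # 22 unique words out of 36 -> TTR 0.61
        seq = TokenSequence(tokens=tuple(f"w{i}" for i in range(22)) + ("w0",) * 14)
        assert seq.source_length == 36
        assert round(type_token_ratio(seq), 2) == 0.61

    @pytest.mark.parametrize(
        "tokens, expected",
        [(("a", "b", "c"), 1.0), (("a", "a", "b"), 2 / 3)],
    )
    def test_small_cases(self, tokens, expected):
        assert type_token_ratio(TokenSequence(tokens=tokens)) == pytest.approx(expected)

    def test_empty_is_undefined(self):
        assert type_token_ratio(TokenSequence(tokens=())) is None

    def test_verbatim_doubling_halves_ttr_for_distinct_tokens(self):
        a = TokenSequence(tokens=("x", "y", "z", "w"))
        doubled = TokenSequence(tokens=a.tokens + a.tokens)
        assert type_token_ratio(doubled) == pytest.approx(type_token_ratio(a) / 2)


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = TokenSequence(tokens=("a", "b", "c"))
        b = TokenSequence(tokens=("x", "y"))
        assert jaccard_similarity(a, a)[0] == 1.0
        assert jaccard_similarity(a, b)[0] == 0.0

    def test_printed_count_ratio(self):
        # 10 common words out of 62 total unique -> 0.16
        shared = tuple(f"s{i}" for i in range(10))
        a = TokenSequence(tokens=shared + tuple(f"a{i}" for i in range(20)))
        b = TokenSequence(tokens=shared + tuple(f"b{i}" for i in range(32)))
        jac, common, union = jaccard_similarity(a, b)
        assert (common, union) == (10, 62)
        assert round(jac, 2) == 0.16

    def test_both_empty_is_undefined(self):
        empty = TokenSequence(tokens=())
        assert jaccard_similarity(empty, empty)[0] is None


class TestBigramOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("a", "b", "c"), ("a", "b", "c"), 2),
            (("a", "b", "c", "d"), ("x", "b", "c", "y"), 1),
            (("a",), ("a", "b"), 0),  # under two tokens -> 0
        ],
    )
    def test_examples(self, a, b, expected):
        assert bigram_overlap(TokenSequence(tokens=a), TokenSequence(tokens=b)) == expected

    def test_worked_example_sentences_share_none(self):
        assert bigram_overlap(tokenize(SENTENCE_1), tokenize(SENTENCE_2)) == 0


@given(a=tokens_st, b=tokens_st)
@settings(max_examples=200, derandomize=True)
def test_metrics_match_bruteforce_oracle_and_are_symmetric(a, b):
    jac_ab, common, union = jaccard_similarity(a, b)
    jac_ba = jaccard_similarity(b, a)[0]
    assert jac_ab == oracle_jaccard(a, b)
    assert jac_ab == jac_ba
    if jac_ab is not None:
        assert 0.0 <= jac_ab <= 1.0
        assert jac_ab == pytest.approx(common / union)
    ov = bigram_overlap(a, b)
    assert ov == len(oracle_bigrams(a) & oracle_bigrams(b))
    assert ov == bigram_overlap(b, a)
    assert 0 <= ov <= min(len(oracle_bigrams(a)), len(oracle_bigrams(b)))
    ttr = type_token_ratio(a)
    if a.source_length:
        assert 0.0 < ttr <= 1.0


class TestScreenPair:
    def test_verbatim_copy_is_flagged(self, make_review):
        a = make_review("the dal was stale and the floor dirty")
        b = make_review("the dal was stale and the floor dirty")
        assert screen_pair(a, b).same_author_flag

    def test_worked_example_pair_is_different_authors(self, make_review):
        a = make_review(SENTENCE_1)
        b = make_review(SENTENCE_2)
        cmp = screen_pair(a, b)
        assert not cmp.same_author_flag
        assert cmp.bigram_overlap == 0

    def test_disjoint_vocabulary_not_flagged(self, make_review):
        cmp = screen_pair(make_review("alpha beta gamma delta"),
                          make_review("one two three four"))
        assert not cmp.same_author_flag
        assert cmp.jaccard == 0.0

    def test_cross_restaurant_pair_rejected(self, make_review):
        a = make_review("text", restaurant_id="R1")
        b = make_review("text", restaurant_id="R2")
        with pytest.raises(ValueError):
            screen_pair(a, b)


class TestFindDuplicates:
    def test_verbatim_cluster_keeps_earliest(self, make_review):
        base = "found a cockroach near the counter very bad"
        reviews = [
            make_review(base, date=dt.date(2025, 3, 1 + i), review_id=f"r{i}")
            for i in range(6)
        ]
        kept, excluded = find_duplicates(reviews)
        assert [r.review_id for r in kept] == ["r0"]
        assert len(excluded) == 5

    def test_distinct_reviews_all_kept(self, make_review):
        reviews = [
            make_review("service slow but food okay overall"),
            make_review("parking difficult near the main road entrance"),
            make_review("ordered the thali combo portions generous"),
        ]
        kept, excluded = find_duplicates(reviews)
        assert len(kept) == 3 and not excluded

    def test_threshold_config_respected(self, make_review):
        a = make_review("one two three four five six")
        b = make_review("one two three nine ten eleven")  # 2 shared bigrams
        assert not find_duplicates([a, b])[1]
        loose = ScreenConfig(jaccard_threshold=0.6, bigram_threshold=2)
        assert len(find_duplicates([a, b], loose)[1]) == 1
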