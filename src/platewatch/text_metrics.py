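"""Lexical pattern-recognition metrics for duplicate/noise screening.

Passive surveillance from consumer reviews is vulnerable to a single author
posting the same complaint many times.  Before any causality index is
computed, each restaurant's hygiene reviews are screened pairwise with three
cheap, auditable metrics:

* **Type-token ratio (TTR)** — unique tokens / total tokens, a lexical
  diversity profile of a single text.
* **Jaccard similarity** — intersection-over-union of the two texts' unique
  word sets.
* **Bigram overlap** — count of distinct adjacent word pairs shared by the
  two texts; shared phrasing is a much stronger same-author cue than shared
  vocabulary.

A pair is flagged as plausibly same-author when Jaccard or bigram overlap
exceeds its threshold; flagged reviews form connected components of which
only the earliest-dated member is retained.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

from .config import ScreenConfig, TokenizePolicy
from .types import PatternComparison, ReviewRecord, TokenSequence

_NON_ALNUM = re.compile(r"[^a-z0-9\s]")
_NON_ALNUM_CASED = re.compile(r"[^a-zA-Z0-9\s]")


def tokenize(text: str, policy: TokenizePolicy = TokenizePolicy()) -> TokenSequence:
    """Split free text into normalized word tokens.

    Default policy: lowercase, replace every non-alphanumeric character with
    a space, split on whitespace.  Alphanumeric tokens such as ``5th`` and
    ``50off`` survive intact.  Deterministic for a fixed policy; empty input
    yields an empty sequence.
    """
    if policy.lowercase:
        text = text.lower()
    if policy.strip_punct:
        pattern = _NON_ALNUM if policy.lowercase else _NON_ALNUM_CASED
        text = pattern.sub(" ", text)
    return TokenSequence(tokens=tuple(text.split()))


def type_token_ratio(seq: TokenSequence) -> Optional[float]:
    """Unique-token count over total-token count, in (0, 1].

    Returns ``None`` for an empty sequence (the ratio is undefined).
    """
    if seq.source_length == 0:
        return None
    return len(set(seq.tokens)) / seq.source_length


def jaccard_similarity(a: TokenSequence, b: TokenSequence) -> tuple[Optional[float], int, int]:
    """Jaccard similarity of the unique word sets.

    Returns ``(jaccard, common_word_count, union_word_count)``; the ratio is
    ``None`` when both sequences are empty.  Symmetric in its arguments.
    """
    sa, sb = set(a.tokens), set(b.tokens)
    union = sa | sb
    common = sa & sb
    if not union:
        return None, 0, 0
    return len(common) / len(union), len(common), len(union)


def _bigrams(seq: TokenSequence) -> set[tuple[str, str]]:
    return set(zip(seq.tokens, seq.tokens[1:]))


def bigram_overlap(a: TokenSequence, b: TokenSequence) -> int:
    """Number of distinct adjacent-token pairs present in both sequences.

    Returns 0 when either sequence has fewer than two tokens.
    """
    return len(_bigrams(a) & _bigrams(b))


def compare(
    a: TokenSequence,
    b: TokenSequence,
    thresholds: ScreenConfig = ScreenConfig(),
) -> PatternComparison:
    """Compute all pairwise metrics and the same-author flag for two token sequences."""
    jac, common, union = jaccard_similarity(a, b)
    overlap = bigram_overlap(a, b)
    flag = (jac is not None and jac >= thresholds.jaccard_threshold) or (
        overlap >= thresholds.bigram_threshold
    )
    return PatternComparison(
        ttr_a=type_token_ratio(a),
        ttr_b=type_token_ratio(b),
        jaccard=jac,
        common_word_count=common,
        union_word_count=union,
        bigram_overlap=overlap,
        same_author_flag=flag,
    )


def screen_pair(
    a: ReviewRecord,
    b: ReviewRecord,
    thresholds: ScreenConfig = ScreenConfig(),
    policy: TokenizePolicy = TokenizePolicy(),
) -> PatternComparison:
    """Pairwise same-author screen for two reviews of the same restaurant."""
    if a.restaurant_id != b.restaurant_id:
        raise ValueError("screen_pair expects two reviews of the same restaurant")
    return compare(tokenize(a.text, policy), tokenize(b.text, policy), thresholds)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def find_duplicates(
    reviews: Sequence[ReviewRecord],
    thresholds: ScreenConfig = ScreenConfig(),
    policy: TokenizePolicy = TokenizePolicy(),
) -> tuple[list[ReviewRecord], list[ReviewRecord]]:
    """Split a restaurant's reviews into kept and excluded-as-duplicate.

    All within-restaurant pairs are compared exactly (streams are small at
    desk scale, so no approximate-nearest-neighbour shortcut is needed).
    Flagged pairs are merged into connected components; within each
    component the earliest-dated review is kept and the rest are excluded.
    Ties on date are broken by input order, keeping the screen deterministic.

    Returns ``(kept, excluded)`` preserving input order within each list.
    """
    n = len(reviews)
    if n <= 1:
        return list(reviews), []
    seqs = [tokenize(r.text, policy) for r in reviews]
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            cmp = compare(seqs[i], seqs[j], thresholds)
            if cmp.same_author_flag:
                uf.union(i, j)
    # earliest review (then input order) survives each component
    keeper: dict[int, int] = {}
    for idx, r in enumerate(reviews):
        root = uf.find(idx)
        best = keeper.get(root)
        if best is None or r.date < reviews[best].date:
            keeper[root] = idx
    keep_idx = set(keeper.values())
    kept = [r for i, r in enumerate(reviews) if i in keep_idx]
    excluded = [r for i, r in enumerate(reviews) if i not in keep_idx]
    return kept, excluded
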