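"""Keyword-lexicon classification of negative hygiene reviews into sub-aspects.

Negative hygiene-aspect reviews are assigned to one or more of eight
food-safety sub-aspects (cleanliness of the dining area, food handling,
food packaging, pest control, external objects in food, infrastructure
upkeep, undercooked/rotten/smelly food, and unintended health outcomes)
by matching a phrase lexicon against normalized review text.  Positive
reviews are never sub-classified.  Multi-label matches are allowed.

Matching is normalized substring/phrase matching with a light stem rule for
single-word triggers ("rats" matches trigger "rat"), keeping every decision
auditable from the lexicon file alone.  The module also provides a
rule-based polarity override for the known failure mode where an upstream
sentiment model labels a review positive because of food-quality adjectives
("fresh", "crispy") even though the text reports stale or spoiled food.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

from .config import TokenizePolicy
from .text_metrics import tokenize
from .types import Polarity, ReviewRecord, SubAspectCounts, SUB_ASPECTS

# suffixes accepted by the stem-prefix rule for single-word triggers
_STEM_SUFFIXES = ("", "s", "es", "d", "ed", "ing")


@dataclass(frozen=True)
class SubAspect:
    name: str
    keywords: frozenset[str]
    definition: str = ""


@dataclass(frozen=True)
class ClassifiedReview:
    """A review with its hygiene polarity and matched sub-aspects.

    ``matched_subaspects`` is non-empty only for negative polarity; a
    negative with no lexicon hit has an empty set (counted toward the CAI
    numerator but contributing nothing to the severity score).
    """

    review: ReviewRecord
    polarity: Polarity
    matched_subaspects: frozenset[str] = frozenset()
    matched_phrases: tuple[str, ...] = ()


Lexicon = tuple[SubAspect, ...]


def _normalize_phrase(phrase: str) -> str:
    return " ".join(tokenize(str(phrase)).tokens)


def load_lexicon(source: Union[str, Path, Mapping[str, Sequence[str]], None] = None) -> Lexicon:
    """Load a sub-aspect lexicon from YAML/JSON or a mapping.

    ``None`` loads the default lexicon shipped with the package.  Rejects
    lexicons that miss any of the eight sub-aspects, have an empty phrase
    list, or assign the same phrase to two sub-aspects.
    """
    if source is None:
        ref = importlib.resources.files("platewatch.data") / "default_lexicon.yaml"
        data = yaml.safe_load(ref.read_text())
    elif isinstance(source, Mapping):
        data = source
    else:
        data = yaml.safe_load(Path(source).read_text())
    missing = set(SUB_ASPECTS) - set(data)
    if missing:
        raise ValueError(f"lexicon missing sub-aspects: {sorted(missing)}")
    unknown = set(data) - set(SUB_ASPECTS)
    if unknown:
        raise ValueError(f"lexicon has unknown sub-aspects: {sorted(unknown)}")
    seen: dict[str, str] = {}
    aspects = []
    for name in SUB_ASPECTS:
        phrases = [_normalize_phrase(p) for p in data[name]]
        phrases = [p for p in phrases if p]
        if not phrases:
            raise ValueError(f"sub-aspect {name} has no phrases")
        for p in phrases:
            if p in seen and seen[p] != name:
                raise ValueError(f"phrase {p!r} assigned to both {seen[p]} and {name}")
            seen[p] = name
        aspects.append(SubAspect(name=name, keywords=frozenset(phrases)))
    return tuple(aspects)


def _token_matches_trigger(token: str, trigger: str) -> bool:
    if not token.startswith(trigger):
        return False
    return token[len(trigger):] in _STEM_SUFFIXES


def _phrase_hits(tokens: tuple[str, ...], phrase: str) -> bool:
    words = phrase.split()
    if len(words) == 1:
        return any(_token_matches_trigger(t, words[0]) for t in tokens)
    # multi-word phrase: contiguous token-subsequence match with stem rule
    # on the final word (e.g. "unclean tables" matches "unclean table")
    k = len(words)
    for i in range(len(tokens) - k + 1):
        window = tokens[i:i + k]
        if all(w == t for w, t in zip(words[:-1], window[:-1])) and _token_matches_trigger(window[-1], words[-1]):
            return True
    return False


def match_subaspects(text: str, lexicon: Lexicon) -> tuple[frozenset[str], tuple[str, ...]]:
    """Return the sub-aspects whose phrases match the text, with the hits."""
    tokens = tokenize(text).tokens
    names: set[str] = set()
    hits: list[str] = []
    for aspect in lexicon:
        for phrase in sorted(aspect.keywords):
            if _phrase_hits(tokens, phrase):
                names.add(aspect.name)
                hits.append(phrase)
    return frozenset(names), tuple(hits)


def classify_review(
    review: ReviewRecord,
    lexicon: Lexicon,
    polarity: Optional[Polarity] = None,
) -> ClassifiedReview:
    """Classify one hygiene review into sub-aspects.

    ``polarity`` overrides the record's own label (used after the fallback
    labeller or a polarity override).  Negative reviews get lexicon matches;
    positive reviews return an empty set.  An unlabeled review raises
    ``ValueError`` — routing unlabeled reviews is the pipeline's job.
    """
    pol = polarity if polarity is not None else review.hygiene_polarity
    if pol is None or pol == Polarity.UNLABELED:
        raise ValueError(f"review {review.review_id or review.text[:30]!r} has no hygiene polarity label")
    if pol != Polarity.NEGATIVE:
        return ClassifiedReview(review=review, polarity=pol)
    names, hits = match_subaspects(review.text, lexicon)
    return ClassifiedReview(review=review, polarity=pol, matched_subaspects=names, matched_phrases=hits)


# --- rule-based polarity override -----------------------------------------

#: Cues indicating spoiled/old food even in an otherwise positive review.
DEFAULT_NEGATIVE_CUES: tuple[str, ...] = (
    "hard", "week ago", "days old", "stale", "fungus", "smelly", "rotten", "sour smell",
)
#: Strong positive food-quality cues that veto the override.
DEFAULT_POSITIVE_CUES: tuple[str, ...] = ("fresh", "crispy", "juicy", "delicious", "tasty")
#: Food nouns a quality cue must co-occur with to be about the food itself.
DEFAULT_FOOD_NOUNS: tuple[str, ...] = (
    "bread", "cake", "doughnut", "donut", "cream", "cheese", "paneer", "chicken",
    "fish", "curry", "rice", "biryani", "sandwich", "food", "dish", "meal", "mayonnaise",
)


def polarity_override(
    review: ReviewRecord,
    negative_cues: Iterable[str] = DEFAULT_NEGATIVE_CUES,
    positive_cues: Iterable[str] = DEFAULT_POSITIVE_CUES,
    food_nouns: Iterable[str] = DEFAULT_FOOD_NOUNS,
) -> tuple[Polarity, bool]:
    """Re-check an upstream *positive* hygiene label against spoilage cues.

    The upstream label is flipped to negative when a negative cue co-occurs
    with a food noun and no stronger positive cue is present; otherwise it
    is returned unchanged.  Returns ``(polarity, overridden)`` so callers
    can log override events.
    """
    pol = review.hygiene_polarity
    if pol != Polarity.POSITIVE:
        return (pol if pol is not None else Polarity.UNLABELED), False
    tokens = tokenize(review.text).tokens
    joined = " " + " ".join(tokens) + " "

    def present(cue: str) -> bool:
        c = _normalize_phrase(cue)
        return f" {c} " in joined if " " in c else any(_token_matches_trigger(t, c) for t in tokens)

    has_neg = any(present(c) for c in negative_cues)
    has_food = any(present(c) for c in food_nouns)
    has_pos = any(present(c) for c in positive_cues)
    if has_neg and has_food and not has_pos:
        return Polarity.NEGATIVE, True
    return Polarity.POSITIVE, False


def fallback_label(review: ReviewRecord, lexicon: Lexicon) -> Polarity:
    """Low-fidelity keyword labeller for reviews with no upstream label.

    A lexicon hit marks the review hygiene-negative; a positive cue with a
    food noun marks it hygiene-positive; anything else is non-hygiene.
    Clearly lower fidelity than a trained sentiment model — runs marked as
    using it are flagged in report provenance.
    """
    names, _ = match_subaspects(review.text, lexicon)
    if names:
        return Polarity.NEGATIVE
    tokens = tokenize(review.text).tokens
    has_pos = any(_token_matches_trigger(t, c) for t in tokens for c in DEFAULT_POSITIVE_CUES)
    has_food = any(_token_matches_trigger(t, c) for t in tokens for c in DEFAULT_FOOD_NOUNS)
    hygiene_words = ("clean", "hygiene", "hygienic", "spotless")
    has_hyg = any(_token_matches_trigger(t, c) for t in tokens for c in hygiene_words)
    if has_hyg or (has_pos and has_food):
        return Polarity.POSITIVE
    return Polarity.NON_HYGIENE


def tally_subaspects(classified: Sequence[ClassifiedReview]) -> SubAspectCounts:
    """Count negative reviews per sub-aspect over one restaurant's window.

    A multi-label review increments every sub-aspect it matched.
    """
    counts = {name: 0 for name in SUB_ASPECTS}
    for c in classified:
        if c.polarity == Polarity.NEGATIVE:
            for name in c.matched_subaspects:
                counts[name] += 1
    return SubAspectCounts(counts=counts)
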