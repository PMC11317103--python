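"""Domain types shared across the surveillance pipeline.

The framework turns sentiment-labelled restaurant reviews into per-restaurant
food-safety signals: a Causality Assessment Index (CAI, ratio of negative to
positive hygiene-aspect reviews), a Severity Assessment Score (SAS, weighted
sum of negative reviews across eight hygiene sub-aspects) and a five-band
public-health risk grade.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence


class Category(str, enum.Enum):
    """Restaurant category taxonomy (closed five-value set)."""

    FINE_DINING = "FINE_DINING"
    CASUAL_DINING = "CASUAL_DINING"
    BUFFET = "BUFFET"
    QUICK_SERVICE = "QUICK_SERVICE"
    FOOD_TRUCK_DHABA = "FOOD_TRUCK_DHABA"


#: The eight hygiene sub-aspects, derived from the FSSAI inspection checklist
#: plus the explicitly added unintended-health-outcome category.
SUB_ASPECTS: tuple[str, ...] = (
    "CLEANLINESS_DINING",
    "EXTERNAL_OBJECTS",
    "FOOD_HANDLING",
    "FOOD_PACKAGING",
    "PEST_CONTROL",
    "UNDERCOOKED_ROTTEN_SMELLY",
    "UNINTENDED_HEALTH_OUTCOME",
    "UPKEEP_INFRA",
)


class Polarity(str, enum.Enum):
    """Hygiene-aspect sentiment disposition of a single review.

    ``POSITIVE``/``NEGATIVE`` are hygiene-aspect labels produced upstream
    (or by the lexicon fallback); ``NON_HYGIENE`` marks reviews outside the
    hygiene aspect; ``UNLABELED`` marks hygiene reviews with no label.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NON_HYGIENE = "non_hygiene"
    UNLABELED = "unlabeled"


class Grade(str, enum.Enum):
    """Public-health risk grade bands mapped from the SAS."""

    LOW = "LOW"
    SLIGHTLY_HIGHER = "SLIGHTLY_HIGHER"
    HIGH = "HIGH"
    HIGHER = "HIGHER"
    HIGHEST = "HIGHEST"
    NOT_GRADED = "NOT_GRADED"


class Verdict(str, enum.Enum):
    """Outcome of the temporal chance screen."""

    CHANCE = "chance"
    GENUINE = "genuine"


@dataclass(frozen=True)
class ReviewRecord:
    """One consumer review.

    ``hygiene_polarity`` is the upstream sentiment label for the hygiene
    aspect; ``None`` means unlabeled (routed to the fallback labeller or
    skipped, per config).
    """

    restaurant_id: str
    date: _dt.date
    text: str
    hygiene_polarity: Optional[Polarity] = None
    review_id: Optional[str] = None
    rating: Optional[float] = None


@dataclass(frozen=True)
class RestaurantProfile:
    """Listing facts needed for eligibility and geo export."""

    restaurant_id: str
    category: Category
    latitude: float
    longitude: float
    total_review_count: int
    first_review_date: _dt.date

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 180.0):
            raise ValueError(
                f"invalid coordinates for {self.restaurant_id}: "
                f"({self.latitude}, {self.longitude})"
            )


@dataclass(frozen=True)
class TokenSequence:
    """Normalized word tokens of one review text."""

    tokens: tuple[str, ...]

    @property
    def source_length(self) -> int:
        return len(self.tokens)

    def __post_init__(self) -> None:
        if any(t == "" for t in self.tokens):
            raise ValueError("TokenSequence must not contain empty tokens")


@dataclass(frozen=True)
class PatternComparison:
    """Pairwise authorship/duplication metrics for two reviews.

    ``ttr_a``/``ttr_b`` are type-token ratios (``None`` for an empty text);
    ``jaccard`` is intersection-over-union of the unique word sets;
    ``bigram_overlap`` counts distinct adjacent-word pairs shared by both.
    """

    ttr_a: Optional[float]
    ttr_b: Optional[float]
    jaccard: Optional[float]
    common_word_count: int
    union_word_count: int
    bigram_overlap: int
    same_author_flag: bool


@dataclass(frozen=True)
class SubAspectCounts:
    """Per-restaurant counts of negative reviews in each sub-aspect."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SUB_ASPECTS)
        if unknown:
            raise ValueError(f"unknown sub-aspects: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("sub-aspect counts must be non-negative")

    def get(self, name: str) -> int:
        return int(self.counts.get(name, 0))

    def total(self) -> int:
        return sum(int(v) for v in self.counts.values())


@dataclass(frozen=True)
class MonthlySeries:
    """Calendar-month aggregation of one restaurant's review stream."""

    months: tuple[str, ...]  # "YYYY-MM" labels, ordered
    total_reviews: tuple[int, ...]
    positive_hygiene: tuple[int, ...]
    negative_hygiene: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.months)
        if not (len(self.total_reviews) == len(self.positive_hygiene) == len(self.negative_hygiene) == n):
            raise ValueError("all monthly columns must have equal length")
        for t, p, q in zip(self.total_reviews, self.positive_hygiene, self.negative_hygiene):
            if min(t, p, q) < 0:
                raise ValueError("monthly counts must be non-negative")
            if p + q > t:
                raise ValueError("hygiene counts exceed monthly total")


@dataclass(frozen=True)
class TemporalResult:
    statistic: float
    dof: int
    p_value: float
    verdict: Verdict
    spike_months: frozenset[str] = frozenset()
    warnings: tuple[str, ...] = ()


#: Sentinel CAI for a restaurant with negatives but no positives.
CAI_INFINITE = math.inf


@dataclass(frozen=True)
class SignalAssessment:
    """Full signal assessment for one restaurant.

    ``cai`` is ``None`` when not assessable (no hygiene reviews at all) and
    ``math.inf`` when negatives exist but positives are zero.
    """

    restaurant_id: str
    n_negative: int
    n_positive: int
    cai: Optional[float]
    causality: bool
    sas: int
    grade: Grade
    temporal: Optional[TemporalResult] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    subaspect_counts: Optional[SubAspectCounts] = None
    dispositions: Mapping[str, int] = field(default_factory=dict)

    @property
    def cai_display(self) -> str:
        """CAI at the 2-decimal reporting precision ('inf'/'NA' sentinels)."""
        if self.cai is None:
            return "NA"
        if math.isinf(self.cai):
            return "inf"
        return f"{self.cai:.2f}"


@dataclass(frozen=True)
class SurveillanceReport:
    """All assessments for one run plus category aggregates and provenance."""

    assessments: tuple[SignalAssessment, ...]
    category_summary: "object"  # pandas.DataFrame; typed loosely to keep import light
    provenance: Mapping[str, object] = field(default_factory=dict)

    def by_id(self, restaurant_id: str) -> SignalAssessment:
        for a in self.assessments:
            if a.restaurant_id == restaurant_id:
                return a
        raise KeyError(restaurant_id)


def parse_polarity(value: object) -> Polarity:
    """Map a raw table cell to a :class:`Polarity` (blank/NaN → UNLABELED)."""
    if value is None:
        return Polarity.UNLABELED
    if isinstance(value, Polarity):
        return value
    if isinstance(value, float) and math.isnan(value):
        return Polarity.UNLABELED
    s = str(value).strip().lower()
    if s in ("", "nan", "none", "unlabeled"):
        return Polarity.UNLABELED
    if s in ("positive", "pos", "+"):
        return Polarity.POSITIVE
    if s in ("negative", "neg", "-"):
        return Polarity.NEGATIVE
    if s in ("non_hygiene", "non-hygiene", "nonhygiene", "other"):
        return Polarity.NON_HYGIENE
    raise ValueError(f"unrecognized hygiene polarity label: {value!r}")
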