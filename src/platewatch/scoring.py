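"""Causality Assessment Index, Severity Assessment Score and risk grading.

CAI = (number of negative hygiene-aspect reviews) / (number of positive
hygiene-aspect reviews).  A CAI strictly above 1 — more negative than
positive hygiene sentiment after duplicate and chance screening — is taken
to establish a genuine food-safety concern (the causality flag).

Once causality is established, SAS = Σ (negative-review count per
sub-aspect × that sub-aspect's weight), with weights proportional to the
inspection checklist's emphasis, and the score maps to five public-health
risk bands.  Restaurants without causality are not graded.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

from .config import ScoringConfig, DEFAULT_GRADE_BANDS
from .lexicon import ClassifiedReview, tally_subaspects
from .types import (
    Grade,
    Polarity,
    RestaurantProfile,
    SignalAssessment,
    SubAspectCounts,
    SUB_ASPECTS,
    TemporalResult,
)


def compute_cai(n_negative: int, n_positive: int) -> Optional[float]:
    """Ratio of negative to positive hygiene reviews.

    Returns ``math.inf`` when positives are zero but negatives exist, and
    ``None`` (not assessable) when there are no hygiene reviews at all.
    The internal value is exact; display rounding to 2 decimals is the
    reporting layer's job.
    """
    if n_negative < 0 or n_positive < 0:
        raise ValueError("review counts must be non-negative")
    if n_positive == 0:
        return math.inf if n_negative > 0 else None
    return n_negative / n_positive


def causality_flag(cai: Optional[float]) -> bool:
    """True iff CAI > 1 (infinite counts as true; not-assessable as false)."""
    if cai is None:
        return False
    return cai > 1.0


def compute_sas(counts: SubAspectCounts, config: ScoringConfig = ScoringConfig()) -> int:
    """Weighted sum of per-sub-aspect negative review counts."""
    return sum(counts.get(name) * int(config.weights[name]) for name in SUB_ASPECTS)


def grade_sas(score: int, bands: Sequence[int] = DEFAULT_GRADE_BANDS) -> Grade:
    """Map a SAS to its risk band.

    Default bands: ≤5 low, 6–10 slightly higher, 11–15 high, 16–20 higher,
    above 20 highest.
    """
    if score < 0:
        raise ValueError("SAS must be non-negative")
    b1, b2, b3, b4 = bands
    if score <= b1:
        return Grade.LOW
    if score <= b2:
        return Grade.SLIGHTLY_HIGHER
    if score <= b3:
        return Grade.HIGH
    if score <= b4:
        return Grade.HIGHER
    return Grade.HIGHEST


def assess_restaurant(
    profile: RestaurantProfile,
    classified: Sequence[ClassifiedReview],
    temporal: Optional[TemporalResult] = None,
    config: ScoringConfig = ScoringConfig(),
    dispositions: Optional[dict[str, int]] = None,
    excluded: bool = False,
    exclusion_reason: Optional[str] = None,
) -> SignalAssessment:
    """Compose CAI → causality → (SAS, grade) for one restaurant.

    Severity is assessed only upon establishment of causality: restaurants
    with CAI ≤ 1 (or not assessable, or excluded by screening) carry
    ``Grade.NOT_GRADED`` and a zero SAS is not interpreted.
    """
    n_neg = sum(1 for c in classified if c.polarity == Polarity.NEGATIVE)
    n_pos = sum(1 for c in classified if c.polarity == Polarity.POSITIVE)
    if excluded:
        return SignalAssessment(
            restaurant_id=profile.restaurant_id,
            n_negative=n_neg,
            n_positive=n_pos,
            cai=None,
            causality=False,
            sas=0,
            grade=Grade.NOT_GRADED,
            temporal=temporal,
            excluded=True,
            exclusion_reason=exclusion_reason or "excluded by screening",
            dispositions=dict(dispositions or {}),
        )
    cai = compute_cai(n_neg, n_pos)
    causal = causality_flag(cai)
    subcounts = tally_subaspects(classified)
    if causal:
        sas = compute_sas(subcounts, config)
        grade = grade_sas(sas, config.grade_bands)
    else:
        sas, grade = 0, Grade.NOT_GRADED
    return SignalAssessment(
        restaurant_id=profile.restaurant_id,
        n_negative=n_neg,
        n_positive=n_pos,
        cai=cai,
        causality=causal,
        sas=sas,
        grade=grade,
        temporal=temporal,
        subaspect_counts=subcounts,
        dispositions=dict(dispositions or {}),
    )
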