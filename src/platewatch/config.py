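"""Pipeline configuration: thresholds, weights and policies.

All knobs the screening, temporal and scoring stages use live here so a run
is fully described by one config object (serialisable to YAML/JSON), which
the report embeds as provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .types import SUB_ASPECTS

#: Per-negative-review severity weights (points), one per sub-aspect.
#: These follow the checklist-proportional weighting: cleanliness of the
#: dining area 2, external objects in food 3, food handling 2, food
#: packaging 1, pest control 3, undercooked/rotten/smelly food 3,
#: infrastructure upkeep 2, unintended health outcomes 4.  Sum = 20.
DEFAULT_WEIGHTS: dict[str, int] = {
    "CLEANLINESS_DINING": 2,
    "EXTERNAL_OBJECTS": 3,
    "FOOD_HANDLING": 2,
    "FOOD_PACKAGING": 1,
    "PEST_CONTROL": 3,
    "UNDERCOOKED_ROTTEN_SMELLY": 3,
    "UNINTENDED_HEALTH_OUTCOME": 4,
    "UPKEEP_INFRA": 2,
}

#: Alternate preset under which the published worked examples for the
#: buffet, quick-service and food-truck columns are internally consistent
#: (cleanliness and upkeep at 1 point instead of 2).  Shipped alongside the
#: default so both readings are testable; never silently merged.
WORKED_EXAMPLE_VARIANT_WEIGHTS: dict[str, int] = {**DEFAULT_WEIGHTS, "CLEANLINESS_DINING": 1, "UPKEEP_INFRA": 1}

WEIGHT_PRESETS: dict[str, dict[str, int]] = {
    "default": DEFAULT_WEIGHTS,
    "worked_example_variant": WORKED_EXAMPLE_VARIANT_WEIGHTS,
}

#: Upper edges of the first four risk bands: <=5 low, 6-10 slightly higher,
#: 11-15 high, 16-20 higher, >20 highest.
DEFAULT_GRADE_BANDS: tuple[int, int, int, int] = (5, 10, 15, 20)


@dataclass(frozen=True)
class TokenizePolicy:
    lowercase: bool = True
    strip_punct: bool = True


@dataclass(frozen=True)
class ScreenConfig:
    """Same-author screening thresholds for within-restaurant review pairs."""

    jaccard_threshold: float = 0.6
    bigram_threshold: int = 3


@dataclass(frozen=True)
class TemporalConfig:
    alpha: float = 0.05
    residual_spike_threshold: float = 2.0
    #: A restaurant is excluded outright when duplicate screening removes
    #: more than this fraction of its hygiene reviews (data-quality failure).
    exclusion_dup_fraction: float = 0.5


@dataclass(frozen=True)
class ScoringConfig:
    weights: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    grade_bands: tuple[int, int, int, int] = DEFAULT_GRADE_BANDS

    def __post_init__(self) -> None:
        missing = set(SUB_ASPECTS) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing sub-aspects: {sorted(missing)}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all sub-aspect weights must be positive")
        if list(self.grade_bands) != sorted(self.grade_bands):
            raise ValueError("grade bands must be non-decreasing")


@dataclass(frozen=True)
class EligibilityConfig:
    min_reviews: int = 1000
    min_age_years: float = 2.0


@dataclass(frozen=True)
class PipelineConfig:
    tokenize: TokenizePolicy = field(default_factory=TokenizePolicy)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    temporal: TemporalConfig = field(default_factory=TemporalConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    #: Assessment window length in months (most recent N months of data).
    window_months: int = 12
    #: When True, unlabeled reviews are run through the lexicon fallback
    #: labeller; when False they are skipped (disposition "unlabeled-skipped").
    fallback_labelling: bool = False
    jitter_min_m: float = 5.0
    jitter_max_m: float = 10.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scoring"]["weights"] = dict(self.scoring.weights)
        d["scoring"]["grade_bands"] = list(self.scoring.grade_bands)
        return d


def _build(d: Mapping) -> PipelineConfig:
    scoring = dict(d.get("scoring", {}))
    weights = scoring.get("weights", "default")
    if isinstance(weights, str):
        try:
            weights = WEIGHT_PRESETS[weights]
        except KeyError:
            raise ValueError(f"unknown weight preset {weights!r}; "
                             f"expected one of {sorted(WEIGHT_PRESETS)} or a mapping")
    bands = tuple(scoring.get("grade_bands", DEFAULT_GRADE_BANDS))
    return PipelineConfig(
        tokenize=TokenizePolicy(**d.get("tokenize", {})),
        screen=ScreenConfig(**d.get("screen", {})),
        temporal=TemporalConfig(**d.get("temporal", {})),
        scoring=ScoringConfig(weights=dict(weights), grade_bands=bands),
        eligibility=EligibilityConfig(**d.get("eligibility", {})),
        window_months=int(d.get("window_months", 12)),
        fallback_labelling=bool(d.get("fallback_labelling", False)),
        jitter_min_m=float(d.get("jitter_min_m", 5.0)),
        jitter_max_m=float(d.get("jitter_max_m", 10.0)),
    )


def load_config(source: Union[str, Path, Mapping, None] = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML/JSON file, a mapping, or defaults."""
    if source is None:
        return PipelineConfig()
    if isinstance(source, Mapping):
        return _build(source)
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build(data or {})
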