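"""Seeded synthetic suburb generator with exact ground truth.

No review corpus accompanies the surveillance framework (raw consumer
reviews are not publishable), so every pipeline stage is exercised against
a synthetic suburb with known ground truth: a few dozen to ~160 restaurants
across the five categories, monthly review streams, a baseline
hygiene-negative proportion of about 10% of monthly volume, and optionally
planted elevated-risk restaurants, spike months, and duplicate clusters.

Texts are template-based — a short sub-aspect trigger phrase embedded in
shuffled neutral filler — so the planted sub-aspect of every negative
review is recoverable exactly by the lexicon classifier, and near-duplicate
clusters are constructed by verbatim copying with optional token mutation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, load_lexicon, match_subaspects
from .types import Category, Polarity, SurveillanceReport, SUB_ASPECTS

#: Neutral filler vocabulary.  None of these words (or their light-stem
#: variants) may match a lexicon trigger; a generator test enforces this.
FILLER_VOCAB: tuple[str, ...] = (
    "we", "went", "there", "last", "month", "and", "the", "overall", "experience",
    "was", "okay", "place", "good", "service", "quick", "nice", "crowd", "evening",
    "lunch", "dinner", "ordered", "menu", "items", "portion", "price", "parking",
    "area", "near", "main", "road", "visit", "again", "friends", "family", "busy",
    "weekend", "sunday", "ambience", "decent", "average", "tried", "starters",
    "dessert", "billing", "counter", "seating", "outdoor", "indoor", "music",
    "loud", "quiet", "corner", "window", "view", "walkable", "distance", "office",
    "colleagues", "birthday", "celebration", "ordering", "waiting", "queue",
    "minutes", "arrived", "plates", "cutlery", "buffet", "spread", "variety",
    "options", "veg", "nonveg", "combo", "thali", "beverages", "juice", "coffee",
    "tea", "weekday", "afternoon", "late", "night", "crowded", "spacious",
)

#: Short (≤ 2-token) generation phrase per sub-aspect, drawn from the default
#: lexicon.  Short phrases keep any two same-aspect reviews below the
#: same-author bigram threshold while remaining exact classifier triggers.
GENERATION_PHRASES: dict[str, tuple[str, ...]] = {
    "CLEANLINESS_DINING": ("dirty", "unclean", "filthy"),
    "EXTERNAL_OBJECTS": ("hair", "stone"),
    "FOOD_HANDLING": ("gloves", "unwashed"),
    "FOOD_PACKAGING": ("leaking",),
    "PEST_CONTROL": ("rat", "fly", "cockroach", "insect"),
    "UNDERCOOKED_ROTTEN_SMELLY": ("stale", "undercooked", "smelly", "rotten"),
    "UNINTENDED_HEALTH_OUTCOME": ("vomit", "acidity", "stomach ache"),
    "UPKEEP_INFRA": ("damp", "ventilated"),
}

#: Kept to two tokens (one bigram) so that two positive reviews sharing a
#: template stay well under the same-author bigram threshold.
POSITIVE_TEMPLATES: tuple[str, ...] = (
    "clean place",
    "fresh food",
    "hygienic place",
    "spotless hall",
    "neat tables",
)

#: Default suburb regime: 93 eligible restaurants in the surveyed category
#: mix, plus ineligible listings to reach 156 profiles in total.
DEFAULT_CATEGORY_MIX: dict[Category, int] = {
    Category.CASUAL_DINING: 63,
    Category.FINE_DINING: 2,
    Category.BUFFET: 4,
    Category.QUICK_SERVICE: 13,
    Category.FOOD_TRUCK_DHABA: 11,
}


@dataclass(frozen=True)
class PlantedEffect:
    """Elevated hygiene-negative regime for one restaurant.

    ``neg_pos_ratio`` is the target ratio of negative to positive hygiene
    rates (3.0 plants a strong 3:1 signal); ``subaspect_profile`` weights the
    sub-aspects the planted negatives complain about (uniform if omitted).
    """

    restaurant_id: str
    neg_pos_ratio: float
    subaspect_profile: Optional[Mapping[str, float]] = None


@dataclass(frozen=True)
class SpikeEvent:
    restaurant_id: str
    month_index: int  # 0-based within the window
    multiplier: float  # ≥ 1, scales the negative rate in that month


@dataclass(frozen=True)
class DuplicateCluster:
    restaurant_id: str
    n_copies: int  # total cluster size including the original
    mutation_rate: float = 0.0


@dataclass(frozen=True)
class SuburbScenario:
    """Study conditions for one synthetic suburb."""

    category_mix: Mapping[Category, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    n_ineligible: int = 63  # listings under the review threshold (156 total by default)
    months: int = 12
    start: _dt.date = _dt.date(2025, 1, 1)
    monthly_volume_mean: float = 45.0  # Poisson mean reviews/restaurant/month
    fixed_monthly_totals: Optional[tuple[int, ...]] = None
    baseline_neg_rate: float = 0.10  # hygiene-negative fraction of monthly volume
    pos_rate: float = 0.12  # hygiene-positive fraction of monthly volume
    planted: tuple[PlantedEffect, ...] = ()
    spikes: tuple[SpikeEvent, ...] = ()
    duplicates: tuple[DuplicateCluster, ...] = ()
    center: tuple[float, float] = (12.891, 77.641)  # suburb centroid, decimal degrees

    def __post_init__(self) -> None:
        if not (0.0 <= self.baseline_neg_rate <= 1.0 and 0.0 <= self.pos_rate <= 1.0):
            raise ValueError("rates must be in [0, 1]")
        if self.baseline_neg_rate + self.pos_rate > 1.0:
            raise ValueError("hygiene rates must sum to at most 1")
        if any(s.multiplier < 1 for s in self.spikes):
            raise ValueError("spike multipliers must be >= 1")
        if any(c.n_copies < 1 for c in self.duplicates):
            raise ValueError("duplicate clusters must have n_copies >= 1")
        if self.months < 1 or self.n_ineligible < 0:
            raise ValueError("infeasible scenario")
        if self.fixed_monthly_totals is not None and len(self.fixed_monthly_totals) != self.months:
            raise ValueError("fixed_monthly_totals length must equal months")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    scenario_id: str
    elevated: dict[str, float]  # restaurant_id -> planted neg:pos ratio
    subaspect_counts: dict[str, dict[str, int]]  # kept (non-duplicate) negatives
    spike_months: dict[str, set[str]]  # restaurant_id -> month labels
    duplicate_ids: dict[str, set[str]]  # restaurant_id -> review_ids expected excluded
    hygiene_counts: dict[str, tuple[int, int]]  # (n_negative, n_positive) pre-duplicate
    eligible_ids: set[str]
    rates: dict[str, tuple[float, float]]  # (neg_rate, pos_rate) per restaurant


def _month_dates(scenario: SuburbScenario) -> list[_dt.date]:
    dates = []
    y, m = scenario.start.year, scenario.start.month
    for _ in range(scenario.months):
        dates.append(_dt.date(y, m, 1))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return dates


def _filler(rng: np.random.Generator, n_lo: int = 8, n_hi: int = 14) -> list[str]:
    n = int(rng.integers(n_lo, n_hi + 1))
    return list(rng.choice(FILLER_VOCAB, size=n, replace=False))


def _negative_text(rng: np.random.Generator, aspect: str) -> str:
    phrases = GENERATION_PHRASES[aspect]
    phrase = str(phrases[int(rng.integers(len(phrases)))])
    words = _filler(rng)
    cut = int(rng.integers(1, len(words)))
    return " ".join(words[:cut] + [phrase] + words[cut:])


def _positive_text(rng: np.random.Generator) -> str:
    tpl = POSITIVE_TEMPLATES[int(rng.integers(len(POSITIVE_TEMPLATES)))]
    words = _filler(rng, 5, 9)
    return " ".join(words + [tpl])


def _mutate(text: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return text
    tokens = text.split()
    out = [
        str(rng.choice(FILLER_VOCAB)) if rng.random() < rate else t
        for t in tokens
    ]
    return " ".join(out)


def generate_scenario(
    scenario: SuburbScenario,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (review table, profile table, ground truth) for a scenario.

    Deterministic for a fixed scenario and seed.  The output frames use the
    same schemas the pipeline readers consume.
    """
    rng = np.random.default_rng(seed)
    month_starts = _month_dates(scenario)
    month_labels = [f"{d.year:04d}-{d.month:02d}" for d in month_starts]
    end = month_starts[-1] + _dt.timedelta(days=27)

    planted = {p.restaurant_id: p for p in scenario.planted}
    spikes: dict[tuple[str, int], float] = {
        (s.restaurant_id, s.month_index): s.multiplier for s in scenario.spikes
    }

    truth = GroundTruth(
        scenario_id=f"suburb-{seed}",
        elevated={p.restaurant_id: p.neg_pos_ratio for p in scenario.planted},
        subaspect_counts={},
        spike_months={},
        duplicate_ids={},
        hygiene_counts={},
        eligible_ids=set(),
        rates={},
    )

    profiles_rows = []
    review_rows = []
    rid_counter = 0

    def make_profile(category: Category, eligible: bool) -> str:
        nonlocal rid_counter
        rid_counter += 1
        rid = f"R{rid_counter:03d}"
        lat = scenario.center[0] + float(rng.normal(0, 0.004))
        lon = scenario.center[1] + float(rng.normal(0, 0.004))
        if eligible:
            total = int(rng.integers(1000, 6000))
            age_days = int(rng.integers(3 * 365, 8 * 365))
        else:
            total = int(rng.integers(50, 1000))
            age_days = int(rng.integers(200, 8 * 365))
        profiles_rows.append({
            "restaurant_id": rid,
            "category": category.value,
            "lat": round(lat, 6),
            "lon": round(lon, 6),
            "total_review_count": total,
            "first_review_date": (scenario.start - _dt.timedelta(days=age_days)).isoformat(),
        })
        if eligible:
            truth.eligible_ids.add(rid)
        return rid

    eligible_ids: list[str] = []
    for category, n in scenario.category_mix.items():
        for _ in range(int(n)):
            eligible_ids.append(make_profile(category, eligible=True))
    categories = list(scenario.category_mix)
    for _ in range(scenario.n_ineligible):
        make_profile(categories[int(rng.integers(len(categories)))], eligible=False)

    for rid in eligible_ids:
        effect = planted.get(rid)
        pos_rate = scenario.pos_rate
        neg_base = effect.neg_pos_ratio * pos_rate if effect else scenario.baseline_neg_rate
        truth.rates[rid] = (neg_base, pos_rate)
        profile_weights = None
        if effect and effect.subaspect_profile:
            names = list(effect.subaspect_profile)
            w = np.array([effect.subaspect_profile[n] for n in names], float)
            profile_weights = (names, w / w.sum())
        sub_counts = {a: 0 for a in SUB_ASPECTS}
        n_neg_total = n_pos_total = 0
        spike_labels: set[str] = set()
        rev_counter = 0
        for mi, m0 in enumerate(month_starts):
            if scenario.fixed_monthly_totals is not None:
                n_month = int(scenario.fixed_monthly_totals[mi])
            else:
                n_month = int(rng.poisson(scenario.monthly_volume_mean))
            neg_rate = neg_base * spikes.get((rid, mi), 1.0)
            neg_rate = min(neg_rate, 1.0 - pos_rate)
            if (rid, mi) in spikes:
                spike_labels.add(month_labels[mi])
            counts = rng.multinomial(n_month, [neg_rate, pos_rate, 1.0 - neg_rate - pos_rate])
            n_neg, n_pos, n_other = (int(c) for c in counts)
            n_neg_total += n_neg
            n_pos_total += n_pos
            days = rng.integers(0, 28, size=n_month)
            kinds = ["neg"] * n_neg + ["pos"] * n_pos + ["other"] * n_other
            for k, day in zip(kinds, days):
                rev_counter += 1
                date = m0 + _dt.timedelta(days=int(day))
                if k == "neg":
                    if profile_weights is not None:
                        names, w = profile_weights
                        aspect = str(rng.choice(names, p=w))
                    else:
                        aspect = SUB_ASPECTS[int(rng.integers(len(SUB_ASPECTS)))]
                    sub_counts[aspect] += 1
                    text, pol = _negative_text(rng, aspect), Polarity.NEGATIVE.value
                elif k == "pos":
                    text, pol = _positive_text(rng), Polarity.POSITIVE.value
                else:
                    text, pol = " ".join(_filler(rng)), Polarity.NON_HYGIENE.value
                review_rows.append({
                    "restaurant_id": rid,
                    "review_id": f"{rid}-{rev_counter:05d}",
                    "date": date.isoformat(),
                    "text": text,
                    "hygiene_polarity": pol,
                })
        truth.subaspect_counts[rid] = sub_counts
        truth.hygiene_counts[rid] = (n_neg_total, n_pos_total)
        truth.spike_months[rid] = spike_labels

    # duplicate clusters: one base negative plus n-1 (near-)copies, all
    # later-dated than the base so the earliest-kept rule removes the copies
    for ci, cluster in enumerate(scenario.duplicates):
        rid = cluster.restaurant_id
        if rid not in truth.eligible_ids:
            raise ValueError(f"duplicate cluster targets unknown/ineligible restaurant {rid}")
        aspect = SUB_ASPECTS[int(rng.integers(len(SUB_ASPECTS)))]
        base_text = _negative_text(rng, aspect)
        base_date = month_starts[int(rng.integers(scenario.months))]
        ids: set[str] = set()
        for k in range(cluster.n_copies):
            review_id = f"{rid}-dup{ci}-{k}"
            text = base_text if k == 0 else _mutate(base_text, cluster.mutation_rate, rng)
            review_rows.append({
                "restaurant_id": rid,
                "review_id": review_id,
                "date": (base_date + _dt.timedelta(days=k)).isoformat(),
                "text": text,
                "hygiene_polarity": Polarity.NEGATIVE.value,
            })
            if k > 0:
                ids.add(review_id)
        truth.duplicate_ids[rid] = truth.duplicate_ids.get(rid, set()) | ids
        # the kept base review contributes to the planted sub-aspect counts
        truth.subaspect_counts[rid][aspect] += 1
        n, p = truth.hygiene_counts[rid]
        truth.hygiene_counts[rid] = (n + cluster.n_copies, p)

    reviews = pd.DataFrame(review_rows)
    profiles = pd.DataFrame(profiles_rows)
    return reviews, profiles, truth


def ground_truth_compare(report: SurveillanceReport, truth: GroundTruth) -> dict[str, float]:
    """Score a surveillance report against what the generator planted.

    Returns sensitivity/specificity of the causality flag against the
    planted elevated regime, the detection rate of planted duplicate copies,
    the recall of planted spike months, and (for mutation-free scenarios)
    the exact-agreement fraction of recovered sub-aspect counts.
    """
    assessed = {a.restaurant_id: a for a in report.assessments}
    if not set(assessed) <= truth.eligible_ids:
        raise ValueError("report contains restaurants unknown to this scenario")

    tp = fn = tn = fp = 0
    for rid, a in assessed.items():
        if a.excluded:
            continue
        if rid in truth.elevated:
            tp += a.causality
            fn += not a.causality
        else:
            fp += a.causality
            tn += not a.causality

    dup_expected = sum(len(v) for v in truth.duplicate_ids.values())
    dup_found = 0
    for rid, ids in truth.duplicate_ids.items():
        a = assessed.get(rid)
        if a is not None:
            dup_found += min(a.dispositions.get("excluded_duplicate", 0), len(ids))

    spikes_expected = sum(len(v) for v in truth.spike_months.values())
    spikes_found = 0
    for rid, labels in truth.spike_months.items():
        a = assessed.get(rid)
        if a is not None and a.temporal is not None:
            spikes_found += len(labels & a.temporal.spike_months)

    exact_sub = total_sub = 0
    for rid, planted in truth.subaspect_counts.items():
        a = assessed.get(rid)
        if a is None or a.subaspect_counts is None or a.excluded:
            continue
        total_sub += 1
        exact_sub += all(a.subaspect_counts.get(k) == v for k, v in planted.items())

    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "causality_sensitivity": _rate(tp, tp + fn),
        "causality_specificity": _rate(tn, tn + fp),
        "causality_false_positive_rate": _rate(fp, fp + tn),
        "duplicate_detection_rate": _rate(dup_found, dup_expected),
        "spike_recall": _rate(spikes_found, spikes_expected),
        "subaspect_exact_fraction": _rate(exact_sub, total_sub),
    }


def check_filler_safety(lexicon: Optional[Lexicon] = None) -> list[str]:
    """Return filler words that collide with the lexicon (must be empty)."""
    lex = lexicon or load_lexicon()
    bad = []
    for w in FILLER_VOCAB:
        names, _ = match_subaspects(w, lex)
        if names:
            bad.append(w)
    return bad
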