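"""End-to-end surveillance pipeline: eligibility → screening → scoring → reporting.

Per restaurant: duplicate screening of its hygiene reviews, the temporal
chance screen, polarity override and sub-aspect classification, then CAI,
SAS and the risk grade.  Every input review ends in exactly one disposition
(non-hygiene, hygiene-positive, hygiene-negative, excluded-duplicate,
unlabeled-skipped, or outside-window), which the report conserves.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .lexicon import (
    ClassifiedReview,
    Lexicon,
    classify_review,
    fallback_label,
    load_lexicon,
    polarity_override,
)
from .scoring import assess_restaurant
from .temporal import aggregate_monthly, temporal_verdict
from .text_metrics import find_duplicates
from .types import (
    Category,
    Grade,
    Polarity,
    RestaurantProfile,
    ReviewRecord,
    SignalAssessment,
    SurveillanceReport,
    parse_polarity,
)

DISPOSITIONS = (
    "non_hygiene",
    "hygiene_positive",
    "hygiene_negative",
    "excluded_duplicate",
    "unlabeled_skipped",
    "outside_window",
)

# meters per degree latitude on the mean-radius sphere (R = 6371 km),
# consistent with the haversine audit of jitter distances
_EARTH_M_PER_DEG = 6_371_000.0 * math.pi / 180.0


# --- input tables ----------------------------------------------------------

def read_reviews(path: Union[str, Path]) -> list[ReviewRecord]:
    """Read a review table (CSV or JSON-lines) into records.

    Required columns: restaurant_id, date (ISO-8601), text; optional:
    hygiene_polarity, review_id, rating.  Schema violations abort with
    row-level diagnostics.
    """
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    return reviews_from_frame(df)


def reviews_from_frame(df: pd.DataFrame) -> list[ReviewRecord]:
    required = {"restaurant_id", "date", "text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"review table missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            date = pd.Timestamp(getattr(row, "date")).date()
            pol = parse_polarity(getattr(row, "hygiene_polarity", None)) if "hygiene_polarity" in df.columns else Polarity.UNLABELED
            records.append(
                ReviewRecord(
                    restaurant_id=str(getattr(row, "restaurant_id")),
                    date=date,
                    text=str(getattr(row, "text")),
                    hygiene_polarity=pol,
                    review_id=str(getattr(row, "review_id")) if "review_id" in df.columns else None,
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"review row {i}: {e}") from e
    return records


def read_profiles(path: Union[str, Path]) -> list[RestaurantProfile]:
    """Read a restaurant profile table (CSV) into records."""
    df = pd.read_csv(path)
    return profiles_from_frame(df)


def profiles_from_frame(df: pd.DataFrame) -> list[RestaurantProfile]:
    required = {"restaurant_id", "category", "lat", "lon", "total_review_count", "first_review_date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(
                RestaurantProfile(
                    restaurant_id=str(row.restaurant_id),
                    category=Category(str(row.category)),
                    latitude=float(row.lat),
                    longitude=float(row.lon),
                    total_review_count=int(row.total_review_count),
                    first_review_date=pd.Timestamp(row.first_review_date).date(),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"profile row {i}: {e}") from e
    return out


# --- eligibility -----------------------------------------------------------

def filter_eligible(
    profiles: Sequence[RestaurantProfile],
    min_reviews: int = 1000,
    min_age_years: float = 2.0,
    reference_date: Optional[_dt.date] = None,
) -> tuple[list[RestaurantProfile], list[tuple[str, str]]]:
    """Keep profiles with enough review volume and listing age.

    Default rule: at least 1000 total reviews and listed for more than two
    years.  Returns the eligible subset plus an exclusion log of
    (restaurant_id, reason) pairs.
    """
    ref = reference_date or _dt.date.today()
    eligible, log = [], []
    for p in profiles:
        if p.total_review_count < min_reviews:
            log.append((p.restaurant_id, f"total reviews {p.total_review_count} < {min_reviews}"))
            continue
        age_years = (ref - p.first_review_date).days / 365.25
        if age_years <= min_age_years:
            log.append((p.restaurant_id, f"listing age {age_years:.1f} y <= {min_age_years} y"))
            continue
        eligible.append(p)
    return eligible, log


# --- per-restaurant assessment ---------------------------------------------

def _assess_one(
    profile: RestaurantProfile,
    reviews: Sequence[ReviewRecord],
    window: tuple[_dt.date, _dt.date],
    lexicon: Lexicon,
    config: PipelineConfig,
) -> SignalAssessment:
    disp = {k: 0 for k in DISPOSITIONS}
    start, end = window
    in_window = []
    for r in reviews:
        if start <= r.date <= end:
            in_window.append(r)
        else:
            disp["outside_window"] += 1

    hygiene: list[ReviewRecord] = []
    classified_nonhyg: list[ClassifiedReview] = []
    for r in in_window:
        pol = r.hygiene_polarity or Polarity.UNLABELED
        if pol == Polarity.UNLABELED:
            if config.fallback_labelling:
                pol = fallback_label(r, lexicon)
            else:
                disp["unlabeled_skipped"] += 1
                continue
        if pol == Polarity.NON_HYGIENE:
            disp["non_hygiene"] += 1
            classified_nonhyg.append(ClassifiedReview(review=r, polarity=Polarity.NON_HYGIENE))
            continue
        if pol != r.hygiene_polarity:
            r = ReviewRecord(
                restaurant_id=r.restaurant_id, date=r.date, text=r.text,
                hygiene_polarity=pol, review_id=r.review_id, rating=r.rating,
            )
        hygiene.append(r)

    # spoilage-cue override on upstream positives, before dedup
    overridden: list[ReviewRecord] = []
    for r in hygiene:
        pol, flipped = polarity_override(r)
        if flipped:
            r = ReviewRecord(
                restaurant_id=r.restaurant_id, date=r.date, text=r.text,
                hygiene_polarity=pol, review_id=r.review_id, rating=r.rating,
            )
        overridden.append(r)

    kept, dups = find_duplicates(overridden, config.screen, config.tokenize)
    disp["excluded_duplicate"] += len(dups)
    dup_fraction = len(dups) / len(overridden) if overridden else 0.0

    classified = [classify_review(r, lexicon) for r in kept]
    for c in classified:
        if c.polarity == Polarity.POSITIVE:
            disp["hygiene_positive"] += 1
        elif c.polarity == Polarity.NEGATIVE:
            disp["hygiene_negative"] += 1

    series = aggregate_monthly(classified + classified_nonhyg, window)
    temporal = temporal_verdict(series, config.temporal)

    if dup_fraction > config.temporal.exclusion_dup_fraction:
        return assess_restaurant(
            profile, classified, temporal, config.scoring, disp,
            excluded=True,
            exclusion_reason=f"duplicate fraction {dup_fraction:.2f} > {config.temporal.exclusion_dup_fraction}",
        )
    return assess_restaurant(profile, classified, temporal, config.scoring, disp)


def run_surveillance(
    reviews: Sequence[ReviewRecord],
    profiles: Sequence[RestaurantProfile],
    config: Optional[PipelineConfig] = None,
    lexicon: Optional[Lexicon] = None,
    reference_date: Optional[_dt.date] = None,
) -> SurveillanceReport:
    """Run the full surveillance pass and return a report.

    Deterministic given the inputs and config.  The assessment window is
    the most recent ``config.window_months`` calendar months ending at the
    latest review date (or ``reference_date``).
    """
    config = config or PipelineConfig()
    lexicon = lexicon or load_lexicon()

    if reference_date is None:
        if not reviews:
            raise ValueError("no reviews and no reference date; cannot fix a window")
        reference_date = max(r.date for r in reviews)
    end = reference_date
    y, m = end.year, end.month
    m -= config.window_months - 1
    while m <= 0:
        y, m = y - 1, m + 12
    start = _dt.date(y, m, 1)
    window = (start, end)

    by_rest: dict[str, list[ReviewRecord]] = {p.restaurant_id: [] for p in profiles}
    unassessed = 0
    eligible, exclusion_log = filter_eligible(
        profiles, config.eligibility.min_reviews, config.eligibility.min_age_years, reference_date
    )
    eligible_ids = {p.restaurant_id for p in eligible}
    for r in reviews:
        if r.restaurant_id in eligible_ids:
            by_rest.setdefault(r.restaurant_id, []).append(r)
        else:
            unassessed += 1

    assessments = tuple(
        _assess_one(p, by_rest.get(p.restaurant_id, []), window, lexicon, config)
        for p in sorted(eligible, key=lambda p: p.restaurant_id)
    )
    summary = summarize_by_category(assessments, profiles)
    provenance = {
        "config": config.to_dict(),
        "window": [start.isoformat(), end.isoformat()],
        "n_profiles": len(profiles),
        "n_eligible": len(eligible),
        "eligibility_exclusions": [list(x) for x in exclusion_log],
        "n_reviews_input": len(reviews),
        "n_reviews_unassessed": unassessed,
        "fallback_labelling": config.fallback_labelling,
    }
    return SurveillanceReport(assessments=assessments, category_summary=summary, provenance=provenance)


# --- aggregation and export ------------------------------------------------

def summarize_by_category(
    assessments: Sequence[SignalAssessment],
    profiles: Sequence[RestaurantProfile],
) -> pd.DataFrame:
    """Category-level aggregates mirroring the published summary layout.

    Means are over assessable, non-excluded restaurants; infinite CAIs are
    left out of the mean (they are flagged, not averaged); mean SAS is over
    graded restaurants only.
    """
    cat_of = {p.restaurant_id: p.category.value for p in profiles}
    rows = []
    for cat in Category:
        cat_assess = [a for a in assessments if cat_of.get(a.restaurant_id) == cat.value]
        qualified = [a for a in cat_assess if not a.excluded]
        finite = [a.cai for a in qualified if a.cai is not None and not math.isinf(a.cai)]
        above1 = [a for a in qualified if a.causality]
        graded = [a for a in qualified if a.grade != Grade.NOT_GRADED]
        rows.append({
            "category": cat.value,
            "n_restaurants": len(cat_assess),
            "n_qualified": len(qualified),
            "n_cai_above_1": len(above1),
            "mean_cai": float(np.mean(finite)) if finite else float("nan"),
            "mean_sas": float(np.mean([a.sas for a in graded])) if graded else float("nan"),
        })
    df = pd.DataFrame(rows)
    assessed = [a for a in assessments if not a.excluded and a.cai is not None]
    n_causal = sum(1 for a in assessed if a.causality)
    df.attrs["fraction_cai_above_1"] = n_causal / len(assessed) if assessed else float("nan")
    return df


def jitter_coordinates(
    lat: float,
    lon: float,
    rng: np.random.Generator,
    min_m: float = 5.0,
    max_m: float = 10.0,
) -> tuple[float, float]:
    """Displace a point by a uniform distance in [min_m, max_m] at a uniform bearing.

    Uses a local equirectangular approximation (meters to degrees with
    latitude-dependent longitude scaling), adequate at the 10 m scale used
    for privacy distortion.
    """
    d = rng.uniform(min_m, max_m)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    dlat = d * math.cos(theta) / _EARTH_M_PER_DEG
    dlon = d * math.sin(theta) / (_EARTH_M_PER_DEG * math.cos(math.radians(lat)))
    return lat + dlat, lon + dlon


def great_circle_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in meters (used to audit the jitter bounds)."""
    r = 6_371_000.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = p2 - p1, math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def export_geojson(
    assessments: Sequence[SignalAssessment],
    profiles: Sequence[RestaurantProfile],
    seed: int,
    jitter_m: tuple[float, float] = (5.0, 10.0),
) -> str:
    """Serialize assessments as an RFC 7946 FeatureCollection string.

    Each restaurant becomes a jittered point whose properties carry the
    category, CAI, SAS and grade.  Restaurants with causality (CAI > 1) are
    styled orange with marker size scaled by SAS; others green.  The output
    is byte-identical across runs with the same seed.
    """
    rng = np.random.default_rng(seed)
    prof = {p.restaurant_id: p for p in profiles}
    features = []
    for a in sorted(assessments, key=lambda a: a.restaurant_id):
        p = prof.get(a.restaurant_id)
        if p is None:
            continue
        lat, lon = jitter_coordinates(p.latitude, p.longitude, rng, *jitter_m)
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [round(lon, 7), round(lat, 7)]},
            "properties": {
                "restaurant_id": a.restaurant_id,
                "category": p.category.value,
                "cai": a.cai_display,
                "causality": a.causality,
                "sas": a.sas,
                "grade": a.grade.value,
                "marker-color": "#e6842a" if a.causality else "#2a9d3a",
                "marker-size": 6 + 2 * a.sas if a.causality else 6,
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    return json.dumps(collection, sort_keys=True, separators=(",", ":")) + "\n"


def assessments_frame(assessments: Sequence[SignalAssessment]) -> pd.DataFrame:
    """Flatten assessments into the per-restaurant output table."""
    rows = []
    for a in assessments:
        row = {
            "restaurant_id": a.restaurant_id,
            "n_negative": a.n_negative,
            "n_positive": a.n_positive,
            "cai": a.cai_display,
            "causality": a.causality,
            "sas": a.sas,
            "grade": a.grade.value,
            "excluded": a.excluded,
            "exclusion_reason": a.exclusion_reason or "",
            "temporal_p": a.temporal.p_value if a.temporal else float("nan"),
            "temporal_verdict": a.temporal.verdict.value if a.temporal else "",
            "spike_months": ";".join(sorted(a.temporal.spike_months)) if a.temporal else "",
        }
        for k, v in a.dispositions.items():
            row[f"disposition_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
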