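"""Temporal chance screening of monthly hygiene-review counts.

A burst of negative hygiene reviews is only a signal if it clusters in time
beyond what the restaurant's overall review volume explains.  The screen is
a one-sample chi-square goodness-of-fit test: the category's monthly counts
are compared against expectations proportional to each month's total review
volume, with months − 1 degrees of freedom.  A small p-value means the
fluctuation is not attributable to chance (verdict "genuine"); months whose
standardized residual exceeds a threshold are annotated as spikes.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import TemporalConfig
from .lexicon import ClassifiedReview
from .types import MonthlySeries, Polarity, TemporalResult, Verdict


def month_label(d: _dt.date) -> str:
    return f"{d.year:04d}-{d.month:02d}"


def _month_range(start: _dt.date, end: _dt.date) -> list[str]:
    labels = []
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        labels.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return labels


def aggregate_monthly(
    reviews: Sequence[ClassifiedReview],
    window: tuple[_dt.date, _dt.date],
) -> MonthlySeries:
    """Bucket classified reviews by calendar month over ``window``.

    Every month of the window appears, including months with zero reviews.
    ``total_reviews`` counts every review in the month regardless of
    disposition; the positive/negative columns count hygiene labels only.
    """
    start, end = window
    if end < start:
        raise ValueError("empty assessment window")
    labels = _month_range(start, end)
    idx = {lab: i for i, lab in enumerate(labels)}
    tot = [0] * len(labels)
    pos = [0] * len(labels)
    neg = [0] * len(labels)
    for c in reviews:
        d = c.review.date
        if not (start <= d <= end):
            continue
        i = idx[month_label(d)]
        tot[i] += 1
        if c.polarity == Polarity.POSITIVE:
            pos[i] += 1
        elif c.polarity == Polarity.NEGATIVE:
            neg[i] += 1
    return MonthlySeries(
        months=tuple(labels),
        total_reviews=tuple(tot),
        positive_hygiene=tuple(pos),
        negative_hygiene=tuple(neg),
    )


def chisq_gof(
    category_counts: Sequence[int],
    totals: Sequence[int],
    config: TemporalConfig = TemporalConfig(),
) -> TemporalResult:
    """Goodness-of-fit of monthly category counts against volume-proportional expectations.

    expected[m] = totals[m] * (sum(counts) / sum(totals)); the statistic is
    the usual Pearson sum of (obs − exp)² / exp with dof = months − 1 and an
    upper-tail p-value.  Expected cells below 1 trigger a small-sample
    warning but the computation proceeds.
    """
    obs = np.asarray(category_counts, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if obs.shape != tot.shape or obs.ndim != 1:
        raise ValueError("category counts and totals must be 1-D and equal length")
    if len(obs) < 2:
        raise ValueError("need at least two months")
    if obs.sum() <= 0:
        raise ValueError("category counts sum to zero; nothing to test")
    if np.any(tot <= 0):
        raise ValueError("monthly totals must all be positive")
    expected = tot * (obs.sum() / tot.sum())
    statistic = float(((obs - expected) ** 2 / expected).sum())
    dof = len(obs) - 1
    p_value = float(stats.chi2.sf(statistic, dof))
    warnings = ()
    if np.any(expected < 1.0):
        warnings = ("expected cell count below 1; chi-square approximation is weak",)
    residuals = (obs - expected) / np.sqrt(expected)
    spikes = frozenset(
        str(i) for i, r in enumerate(residuals) if r > config.residual_spike_threshold
    )
    verdict = Verdict.GENUINE if p_value < config.alpha else Verdict.CHANCE
    return TemporalResult(
        statistic=statistic,
        dof=dof,
        p_value=p_value,
        verdict=verdict,
        spike_months=spikes,
        warnings=warnings,
    )


def temporal_verdict(
    series: MonthlySeries,
    config: TemporalConfig = TemporalConfig(),
) -> TemporalResult:
    """Run the chance screen on a restaurant's negative-hygiene series.

    Verdict is "genuine" when p < alpha (temporal clustering beyond volume),
    "chance" otherwise.  Spike months are those with standardized residual
    above the configured threshold, reported with their calendar labels.
    An all-zero negative series is trivially "chance" with statistic 0.
    """
    neg = np.asarray(series.negative_hygiene, dtype=float)
    months_with_volume = [
        (lab, n, t)
        for lab, n, t in zip(series.months, series.negative_hygiene, series.total_reviews)
        if t > 0
    ]
    if neg.sum() == 0 or len(months_with_volume) < 2:
        return TemporalResult(
            statistic=0.0,
            dof=max(len(months_with_volume) - 1, 0),
            p_value=1.0,
            verdict=Verdict.CHANCE,
        )
    labels = [m[0] for m in months_with_volume]
    counts = [m[1] for m in months_with_volume]
    totals = [m[2] for m in months_with_volume]
    res = chisq_gof(counts, totals, config)
    spikes = frozenset(labels[int(i)] for i in res.spike_months)
    if res.verdict == Verdict.CHANCE:
        spikes = frozenset()  # no spike annotation on chance fluctuations
    return TemporalResult(
        statistic=res.statistic,
        dof=res.dof,
        p_value=res.p_value,
        verdict=res.verdict,
        spike_months=spikes,
        warnings=res.warnings,
    )
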