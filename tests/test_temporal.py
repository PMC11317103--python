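"""Monthly aggregation and the chi-square chance screen."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

from platewatch.config import TemporalConfig
from platewatch.lexicon import ClassifiedReview
from platewatch.temporal import aggregate_monthly, chisq_gof, temporal_verdict
from platewatch.types import MonthlySeries, Polarity, ReviewRecord, Verdict

from .conftest import ILLUSTRATION_NEGATIVE, ILLUSTRATION_POSITIVE, ILLUSTRATION_TOTALS


def gof_oracle(obs, tot):
    """Hand-computed goodness-of-fit statistic by explicit summation."""
    rate = sum(obs) / sum(tot)
    stat = 0.0
    for o, t in zip(obs, tot):
        e = t * rate
        stat += (o - e) ** 2 / e
    return stat


def build_series(totals=ILLUSTRATION_TOTALS, pos=ILLUSTRATION_POSITIVE, neg=ILLUSTRATION_NEGATIVE):
    """Per-review records that aggregate back to the illustration series."""
    reviews = []
    for mi, (t, p, q) in enumerate(zip(totals, pos, neg)):
        month = dt.date(2025, mi + 1, 1)
        kinds = [Polarity.POSITIVE] * p + [Polarity.NEGATIVE] * q + [Polarity.NON_HYGIENE] * (t - p - q)
        for k, pol in enumerate(kinds):
            r = ReviewRecord("R1", month + dt.timedelta(days=k % 28), f"text {mi} {k}", pol)
            reviews.append(ClassifiedReview(review=r, polarity=pol))
    return reviews


class TestAggregateMonthly:
    def test_illustration_series_round_trips(self):
        series = aggregate_monthly(build_series(), (dt.date(2025, 1, 1), dt.date(2025, 8, 31)))
        assert series.total_reviews == ILLUSTRATION_TOTALS
        assert series.positive_hygiene == ILLUSTRATION_POSITIVE
        assert series.negative_hygiene == ILLUSTRATION_NEGATIVE
        # June: 15 negatives of 30 total -> 50%
        assert series.negative_hygiene[5] / series.total_reviews[5] == 0.5

    def test_zero_months_included(self):
        r = ReviewRecord("R1", dt.date(2025, 3, 10), "x", Polarity.POSITIVE)
        series = aggregate_monthly(
            [ClassifiedReview(review=r, polarity=Polarity.POSITIVE)],
            (dt.date(2025, 1, 1), dt.date(2025, 4, 30)),
        )
        assert series.months == ("2025-01", "2025-02", "2025-03", "2025-04")
        assert series.total_reviews == (0, 0, 1, 0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            aggregate_monthly([], (dt.date(2025, 5, 1), dt.date(2025, 1, 1)))


class TestChisqGof:
    def test_positive_series_matches_printed_statistic(self):
        res = chisq_gof(ILLUSTRATION_POSITIVE, ILLUSTRATION_TOTALS)
        assert res.statistic == pytest.approx(5.01, abs=0.01)
        assert res.p_value == pytest.approx(0.658, abs=0.01)
        assert res.dof == 7

    def test_negative_series_matches_hand_oracle(self):
        res = chisq_gof(ILLUSTRATION_NEGATIVE, ILLUSTRATION_TOTALS)
        assert res.statistic == pytest.approx(gof_oracle(ILLUSTRATION_NEGATIVE, ILLUSTRATION_TOTALS))
        assert res.statistic == pytest.approx(34.56, abs=0.01)
        assert res.p_value == pytest.approx(1.35e-5, rel=0.05)

    def test_exact_proportionality_gives_zero(self):
        totals = (50, 40, 60, 30)
        counts = tuple(t // 10 for t in totals)
        res = chisq_gof(counts, totals)
        assert res.statistic == pytest.approx(0.0)
        assert res.verdict == Verdict.CHANCE

    def test_scaling_homogeneity(self):
        base = chisq_gof(ILLUSTRATION_NEGATIVE, ILLUSTRATION_TOTALS).statistic
        doubled = chisq_gof(
            tuple(2 * c for c in ILLUSTRATION_NEGATIVE), tuple(2 * t for t in ILLUSTRATION_TOTALS)
        ).statistic
        assert doubled == pytest.approx(2 * base)

    def test_small_expected_cell_warns_but_computes(self):
        res = chisq_gof((1, 0, 0), (100, 100, 100))
        assert res.warnings
        assert res.statistic > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            chisq_gof((0, 0), (10, 10))
        with pytest.raises(ValueError):
            chisq_gof((1,), (10,))
        with pytest.raises(ValueError):
            chisq_gof((1, 2), (10, 0))


class TestTemporalVerdict:
    def series(self, neg):
        return MonthlySeries(
            months=tuple(f"2025-{m:02d}" for m in range(1, 9)),
            total_reviews=ILLUSTRATION_TOTALS,
            positive_hygiene=ILLUSTRATION_POSITIVE,
            negative_hygiene=neg,
        )

    def test_june_spike_is_genuine_with_spike_month(self):
        res = temporal_verdict(self.series(ILLUSTRATION_NEGATIVE))
        assert res.verdict == Verdict.GENUINE
        assert res.spike_months == frozenset({"2025-06"})

    def test_flat_negatives_are_chance(self):
        flat = tuple(t // 10 for t in ILLUSTRATION_TOTALS)
        res = temporal_verdict(self.series(flat))
        assert res.verdict == Verdict.CHANCE
        assert not res.spike_months

    def test_positive_like_series_is_chance(self):
        # same counts as the positive column, treated as the tested category
        res = temporal_verdict(self.series(ILLUSTRATION_POSITIVE))
        assert res.verdict == Verdict.CHANCE
        assert res.p_value == pytest.approx(0.658, abs=0.01)

    def test_all_zero_negatives_are_chance_with_zero_statistic(self):
        res = temporal_verdict(self.series((0,) * 8))
        assert res.verdict == Verdict.CHANCE
        assert res.statistic == 0.0


def test_type_i_error_calibrated_under_own_null():
    """Distributing the total negatives across months in proportion to
    monthly volume (the screen's null) rejects at ~alpha."""
    rng = np.random.default_rng(2024)
    tot = np.array(ILLUSTRATION_TOTALS)
    probs = tot / tot.sum()
    n_sim = 2000
    rej = 0
    for _ in range(n_sim):
        neg = rng.multinomial(sum(ILLUSTRATION_NEGATIVE), probs)
        rej += chisq_gof(neg, tot).p_value < 0.05
    assert 0.03 <= rej / n_sim <= 0.07


def test_never_anticonservative_under_binomial_null():
    """With independent binomial monthly counts the conditional screen is
    mildly conservative; its rejection rate must stay at or below the band."""
    rng = np.random.default_rng(2025)
    tot = np.array(ILLUSTRATION_TOTALS)
    p = sum(ILLUSTRATION_NEGATIVE) / sum(ILLUSTRATION_TOTALS)
    n_sim, rej = 2000, 0
    for _ in range(n_sim):
        neg = rng.binomial(tot, p)
        if neg.sum() == 0:
            continue
        rej += chisq_gof(neg, tot).p_value < 0.05
    assert rej / n_sim <= 0.07
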