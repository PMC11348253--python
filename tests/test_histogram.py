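"""Interval histograms, the naive estimator and the uniform-noise curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmpda.histogram import (
    denoise,
    estimate_z,
    expected_interaction,
    interval_counts,
    naive_period,
    uniform_z,
    NoiseEstimate,
)
from gmpda.simulate import EventSeries


def brute_force_counts(ts, max_lag):
    counts = np.zeros(max_lag + 1, dtype=int)
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            d = ts[j] - ts[i]
            if 1 <= d <= max_lag:
                counts[d] += 1
    return counts


def test_worked_example_histogram(six_events):
    h = interval_counts(six_events, 60)
    expected = {11: 5, 22: 4, 33: 3, 44: 2, 55: 1}
    for lag in range(1, 61):
        assert h.counts[lag] == expected.get(lag, 0)


def test_single_event_gives_empty_histogram():
    h = interval_counts(EventSeries(np.array([5]), 10), 8)
    assert h.counts.sum() == 0


@given(
    ts=st.lists(st.integers(0, 400), min_size=2, max_size=80, unique=True),
    max_lag=st.integers(1, 500),
)
@settings(max_examples=60, deadline=None)
def test_interval_counts_matches_brute_force(ts, max_lag):
    ts = np.sort(np.array(ts))
    ev = EventSeries(ts, int(ts[-1]) + 1)
    h = interval_counts(ev, max_lag)
    np.testing.assert_array_equal(h.counts, brute_force_counts(ts, max_lag))
    if max_lag >= ts[-1] - ts[0]:
        n = ts.size
        assert h.counts.sum() == n * (n - 1) // 2


@pytest.mark.parametrize(
    "ts, expected",
    [([12, 23, 34, 45, 56, 67], 11.0), ([0, 10, 20, 30], 10.0), ([0, 9, 21, 30], 10.0)],
)
def test_naive_period_mean_consecutive_gap(ts, expected):
    ev = EventSeries(np.array(ts), int(ts[-1]))
    assert naive_period(ev) == pytest.approx(expected)


def test_naive_period_needs_two_events():
    with pytest.raises(ValueError):
        naive_period(EventSeries(np.array([3]), 5))


def test_expected_interaction_linear_decay_properties():
    lags = np.arange(1, 101)
    curve = expected_interaction(2.0, 100, lags)
    assert curve[49] == pytest.approx(1.0)  # z=2, mu=50, n_t=100
    assert curve[-1] == 0.0  # vanishes at mu = n_t
    assert np.all(np.diff(curve) <= 0) and np.all(curve >= 0)


def test_uniform_events_match_closed_form_interaction_curve():
    # Monte-Carlo validation of the linear-decay law for uniform events:
    # the mean pairwise-difference histogram equals z*(1 - mu/N_T) with
    # z = n(n-1)/N_T, within 3 standard errors per lag bin.
    n, n_t, reps = 100, 1000, 500
    rng = np.random.default_rng(0)
    lags = np.arange(1, n_t)
    acc = np.zeros((reps, lags.size))
    for r in range(reps):
        ts = np.sort(rng.choice(np.arange(1, n_t + 1), size=n, replace=False))
        h = interval_counts(EventSeries(ts, n_t), n_t - 1)
        acc[r] = h.counts[1:n_t]
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(reps)
    expected = expected_interaction(uniform_z(n, n_t), n_t, lags)
    within = np.abs(mean - expected) <= 3 * se + 0.05
    assert within.mean() > 0.95


def test_estimate_z_exact_on_linear_input():
    n_t, z_true = 500, 10.0
    lags = np.arange(1, 401)
    counts = np.zeros(401)
    counts[1:] = z_true * (1 - lags / n_t)
    from gmpda.histogram import IntervalHistogram

    hist = IntervalHistogram(counts, 400, n_t, 100)
    est = estimate_z(hist, noise_range=5, l_min=10)
    assert est.z_hat == pytest.approx(z_true)
    empty = IntervalHistogram(np.zeros(401), 400, n_t, 0)
    assert estimate_z(empty, 5, 10).z_hat == 0.0
    with pytest.raises(ValueError):
        estimate_z(hist, noise_range=10, l_min=9)


def test_estimate_z_recovers_uniform_amplitude():
    n, n_t = 500, 5000
    rng = np.random.default_rng(1)
    z_hats = []
    for _ in range(100):
        ts = np.sort(rng.choice(np.arange(1, n_t + 1), size=n, replace=False))
        h = interval_counts(EventSeries(ts, n_t), 400)
        z_hats.append(estimate_z(h, noise_range=5, l_min=10).z_hat)
    target = uniform_z(n, n_t)
    assert abs(np.mean(z_hats) - target) / target < 0.2


def test_denoise_subtracts_and_clips():
    from gmpda.histogram import IntervalHistogram

    counts = np.zeros(68)
    counts[11] = 5
    hist = IntervalHistogram(counts, 67, 67, 6)
    out = denoise(hist, NoiseEstimate(1.0, 67, (1, 5)))
    assert out[11] == pytest.approx(5 - (1 - 11 / 67))
    assert np.all(out >= 0) and np.all(out <= counts)
    # huge z wipes everything; z=0 is the identity
    assert not denoise(hist, NoiseEstimate(1e9, 67, (1, 5))).any()
    np.testing.assert_array_equal(denoise(hist, NoiseEstimate(0.0, 67, (1, 5))), counts)
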