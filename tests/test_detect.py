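"""Candidate extraction, width fitting, subset selection, full pipeline."""

import math

import numpy as np
import pytest

from gmpda.curves import single_period_curve
from gmpda.detect import (
    GmpdaConfig,
    PeriodicityEstimate,
    find_candidates,
    fit_sigmas,
    gmpda_detect,
    select_best,
)
from gmpda.histogram import denoise, estimate_z, interval_counts
from gmpda.simulate import EventSeries, GenerativeSpec, simulate

CFG = GmpdaConfig(model="clock", l_min=10, l_max=350, loss_length=400, max_periods=3)


def _cleaned(ev, cfg=CFG):
    hist = interval_counts(ev, max_lag=min(cfg.loss_length, ev.n_t - 1))
    return denoise(hist, estimate_z(hist, cfg.noise_range, cfg.l_min))


def test_config_validation():
    with pytest.raises(ValueError):
        GmpdaConfig(noise_range=11, l_min=10)
    with pytest.raises(ValueError):
        GmpdaConfig(l_min=50, l_max=20)
    assert GmpdaConfig(l_min=10).sigma0 == 2.0  # int(log(10))


def test_first_candidate_is_prime_period_not_multiple():
    ev = simulate(GenerativeSpec("clock", (50,), (1,), beta=0, events_per_period=300, seed=4))
    cands = find_candidates(_cleaned(ev), CFG, ev.n_t)
    assert cands[0] == 50


def test_all_zero_histogram_gives_no_candidates():
    assert find_candidates(np.zeros(401), CFG, 1000) == []


def test_two_period_candidates_recalled():
    hits = 0
    for seed in range(20):
        spec = GenerativeSpec("clock", (60, 97), (1, 1), beta=0, events_per_period=300, seed=seed)
        ev = simulate(spec)
        cands = find_candidates(_cleaned(ev), CFG, ev.n_t)[:4]
        got60 = any(abs(c - 60) <= 1 for c in cands)
        got97 = any(abs(c - 97) <= 1 for c in cands)
        hits += got60 and got97
    assert hits >= 18  # >= 90% joint recall in the top 4


def test_fit_sigmas_recovers_generating_width():
    n_t = 5000
    cleaned = np.zeros(401)
    window = np.arange(10, 401)
    cleaned[10:401] = single_period_curve("clock", 100.0, 3.0, n_t, window)
    [sig] = fit_sigmas(cleaned, [100], CFG, n_t)
    assert 2.7 <= sig <= 3.3


def test_fit_sigmas_disabled_returns_init():
    cfg = GmpdaConfig(model="clock", l_min=10, curve_fit=False)
    assert fit_sigmas(np.ones(401), [50, 80], cfg, 1000) == [2.0, 2.0]


def test_fit_sigmas_on_flat_window_falls_back():
    [sig] = fit_sigmas(np.zeros(401), [50], CFG, 1000)
    assert sig > 0  # fallback or boundary, never invalid


def test_select_single_candidate_returned_with_loss():
    ev = simulate(GenerativeSpec("clock", (50,), (1,), beta=0, events_per_period=200, seed=0))
    cleaned = _cleaned(ev)
    est = select_best(cleaned, [50], [1.0], CFG, ev.n_t)
    assert est.periods == (50,)
    assert est.loss is not None and est.loss >= 0


def test_select_rejects_redundant_multiple():
    # adding the 2x multiple cannot lower the loss enough to be kept
    ev = simulate(GenerativeSpec("clock", (50,), (1,), beta=0, events_per_period=300, seed=1))
    est = select_best(_cleaned(ev), [50, 100], [1.0, 1.0], CFG, ev.n_t)
    assert est.periods == (50,)


def test_select_two_period_random_walk():
    cfg = GmpdaConfig(model="random_walk", l_min=10, l_max=350, max_periods=4)
    hits = 0
    for seed in range(10):
        mus = (60, 97)
        sigmas = tuple(math.log(m) for m in mus)
        ev = simulate(GenerativeSpec("random_walk", mus, sigmas, beta=0, events_per_period=300, seed=seed))
        est = gmpda_detect(ev, cfg)
        ok = all(any(abs(p - m) <= 0.5 * s for p in est.periods) for m, s in zip(mus, sigmas))
        hits += ok
    assert hits >= 8


def test_detect_noiseless_clock_exact():
    ev = simulate(GenerativeSpec("clock", (50,), (0,), beta=0, events_per_period=100, seed=0))
    est = gmpda_detect(ev, CFG)
    assert est.periods == (50,)


def test_detect_empty_and_tiny_series():
    est = gmpda_detect(EventSeries(np.array([7]), 10), CFG)
    assert est.empty and est.loss is None


def test_detect_deterministic_and_permutation_safe():
    spec = GenerativeSpec("random_walk", (40,), (3,), beta=1, events_per_period=100, seed=9)
    ev = simulate(spec)
    a = gmpda_detect(ev, CFG)
    shuffled = EventSeries.from_unsorted(np.random.default_rng(0).permutation(ev.timestamps), ev.n_t)
    b = gmpda_detect(shuffled, CFG)
    assert a == b


def test_parameter_recovery_clock_sigma_one():
    # sigma*=1, beta=0, n=300: recovered period within +-0.5 in >=95% of runs
    rng = np.random.default_rng(12)
    ok = 0
    runs = 40
    for _ in range(runs):
        mu = int(rng.integers(10, 351))
        ev = simulate(
            GenerativeSpec("clock", (mu,), (1,), beta=0, events_per_period=300, seed=int(rng.integers(0, 2**31)))
        )
        est = gmpda_detect(ev, CFG)
        ok += any(abs(p - mu) <= 0.5 for p in est.periods)
    assert ok / runs >= 0.95


def test_selected_period_never_integer_multiple_of_truth():
    rng = np.random.default_rng(3)
    for _ in range(25):
        mu = int(rng.integers(10, 170))
        ev = simulate(
            GenerativeSpec("clock", (mu,), (0,), beta=0, events_per_period=100, seed=int(rng.integers(0, 2**31)))
        )
        est = gmpda_detect(ev, CFG)
        for p in est.periods:
            ratio = p / mu
            assert not (ratio >= 1.9 and abs(ratio - round(ratio)) < 0.05)


def test_minimum_subset_loss_monotone_in_candidate_pool():
    ev = simulate(GenerativeSpec("clock", (70,), (2,), beta=0.5, events_per_period=200, seed=5))
    cleaned = _cleaned(ev)
    cands = find_candidates(cleaned, CFG, ev.n_t)
    sigmas = fit_sigmas(cleaned, cands, CFG, ev.n_t)
    cfg = GmpdaConfig(model="clock", l_min=10, l_max=350, max_periods=1, curve_fit=False)
    small = select_best(cleaned, cands[:2], sigmas[:2], cfg, ev.n_t)
    full = select_best(cleaned, cands, sigmas, cfg, ev.n_t)
    assert full.loss <= small.loss + 1e-9
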