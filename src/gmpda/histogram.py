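"""All-order inter-event interval histograms and the uniform-noise baseline.

The detection pipeline starts from ``D(mu)``: the number of *forward* ordered
event pairs ``(s_i, s_j)``, ``i < j``, whose difference equals the lag ``mu``.
Intervals between events of different periodicities, between periodic and
noise events, and between noise events ("interaction intervals") contaminate
this histogram. Under a uniformity assumption their expected count decays
linearly in the lag,

    E[zeta(mu)] = z * (1 - mu / N_T),

with ``z = (2 n^2 - (n^2 + n)) / (2 N_T)`` for ``n`` uniform events. The
constant ``z`` is unknown in practice and is estimated from the sub-periodic
lag window ``[1, noise_range]``, which admissible periods cannot reach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import EventSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalHistogram:
    """Counts of all forward pairwise inter-event intervals up to ``max_lag``.

    ``counts`` is lag-indexed: ``counts[mu]`` is ``D(mu)`` for
    ``mu = 1..max_lag``; index 0 is unused and zero.
    """

    counts: np.ndarray
    max_lag: int
    n_t: int
    n_events: int

    @property
    def lags(self) -> np.ndarray:
        return np.arange(1, self.max_lag + 1)


@dataclass(frozen=True)
class NoiseEstimate:
    """Estimated amplitude ``z_hat`` of the linear interaction-interval curve."""

    z_hat: float
    n_t: int
    fit_window: tuple[int, int]


def interval_counts(events: EventSeries, max_lag: int) -> IntervalHistogram:
    """Histogram D(mu) of all forward pairwise differences up to ``max_lag``.

    Iterates over interval orders m = 1, 2, ... and stops as soon as every
    m-th-order difference exceeds ``max_lag``; the total work is proportional
    to the number of pairs actually within range.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    ts = events.timestamps
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    if ts.size < 2:
        logger.warning("fewer than 2 events: empty interval histogram")
        return IntervalHistogram(counts, max_lag, events.n_t, int(ts.size))
    for m in range(1, ts.size):
        diffs = ts[m:] - ts[:-m]
        in_range = diffs[diffs <= max_lag]
        if in_range.size == 0:
            if diffs.min() > max_lag:
                break
            continue
        counts += np.bincount(in_range, minlength=max_lag + 1)
    counts[0] = 0  # duplicate timestamps cannot occur in an EventSeries
    return IntervalHistogram(counts, max_lag, events.n_t, int(ts.size))


def naive_period(events: EventSeries) -> float:
    """Mean consecutive inter-event interval — the single-period estimator.

    Exact for a single noiseless stationary periodicity; biased whenever the
    series mixes several periodicities or contains false positives.
    """
    if len(events) < 2:
        raise ValueError("naive period estimate requires at least 2 events")
    return float(np.mean(np.diff(events.timestamps)))


def expected_interaction(z: float, n_t: int, lags: np.ndarray) -> np.ndarray:
    """Expected interaction-interval counts ``z * (1 - mu/n_t)``, clipped at 0."""
    if z < 0:
        raise ValueError("z must be non-negative")
    lags = np.asarray(lags, dtype=float)
    return np.clip(z * (1.0 - lags / n_t), 0.0, None)


def uniform_z(n_events: int, n_t: int) -> float:
    """Closed-form amplitude z for ``n_events`` uniform events on [1, n_t].

    The ``n(n-1)/2`` forward pairs each hit lag ``mu`` with probability
    ``(2/n_t)(1 - mu/n_t)`` (the factor 2 from folding signed differences
    onto positive lags), so ``z = n(n-1)/n_t``.
    """
    n = n_events
    return n * (n - 1) / float(n_t)


def estimate_z(hist: IntervalHistogram, noise_range: int, l_min: int) -> NoiseEstimate:
    """Infer the interaction amplitude ``z_hat`` from sub-periodic lags.

    Lags in ``[1, noise_range]`` lie below the smallest admissible period
    ``l_min``, so any counts there are interaction intervals; the estimator
    inverts the linear decay pointwise and averages:
    ``z_hat = mean_{mu <= noise_range} D(mu) / (1 - mu/N_T)``.
    """
    if not 1 <= noise_range <= l_min:
        raise ValueError("need 1 <= noise_range <= l_min")
    hi = min(noise_range, hist.max_lag)
    window = np.arange(1, hi + 1)
    d = hist.counts[1 : hi + 1].astype(float)
    if not d.any():
        return NoiseEstimate(0.0, hist.n_t, (1, hi))
    z = float(np.mean(d / (1.0 - window / hist.n_t)))
    return NoiseEstimate(z, hist.n_t, (1, hi))


def denoise(hist: IntervalHistogram, noise: NoiseEstimate) -> np.ndarray:
    """Subtract the estimated interaction curve from D, clipping at zero.

    Returns a lag-indexed vector of length ``max_lag + 1`` (index 0 zero),
    matching the layout of :attr:`IntervalHistogram.counts`.
    """
    cleaned = np.zeros(hist.max_lag + 1, dtype=float)
    cleaned[1:] = np.clip(
        hist.counts[1:] - expected_interaction(noise.z_hat, hist.n_t, hist.lags),
        0.0,
        None,
    )
    return cleaned
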