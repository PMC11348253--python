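"""Classical comparison detectors sharing the event-series input.

Four reference methods, each returning the top-k periods in a range:

* ``fft_periods`` — periodogram of the mean-removed binary series;
* ``acf_fft_periods`` — periodogram of the autocorrelation sequence;
* ``hist_fft_periods`` — periodogram of the all-order interval histogram;
* ``e_periodicity_periods`` — modulus folding: score each candidate period by
  how many inter-event intervals are (near-)integer multiples of it.

The spectral methods share peak selection: restrict power to bins whose
implied period lies in ``[l_min, l_max]``, take local maxima with the
adjacent bins excluded, and pad with the next-highest bins if fewer than k
peaks exist. All four are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .histogram import IntervalHistogram, interval_counts
from .simulate import EventSeries

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Raised when a series is too short or featureless for a detector."""


@dataclass(frozen=True)
class BaselineResult:
    """Top-k periods of one baseline with their (non-increasing) scores."""

    method: str
    periods: tuple[int, ...]
    scores: tuple[float, ...]


def _periodogram_periods(
    signal: np.ndarray, method: str, k: int, l_min: int, l_max: int
) -> BaselineResult:
    """Shared spectral pipeline: zero-padded periodogram + top-k peak picking."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        raise InsufficientDataError(f"{method}: signal is constant, spectrum is DC only")
    # pad heavily so harmonic peaks are sampled near their continuum height
    # (scalloping otherwise breaks the equal-power tie among harmonics)
    nfft = max(4096, 1 << int(np.ceil(np.log2(8 * x.size))))
    power = np.abs(np.fft.rfft(x, nfft)) ** 2
    idx = np.arange(power.size)
    with np.errstate(divide="ignore"):
        periods = np.where(idx > 0, nfft / np.maximum(idx, 1), np.inf)
    valid = np.flatnonzero((periods >= l_min) & (periods <= l_max))
    if valid.size == 0:
        raise InsufficientDataError(f"{method}: no spectral bins in period range")
    # local maxima among valid bins, with the +-1 neighbouring bins excluded
    pv = power[valid]
    prev_p = power[valid - 1]
    next_p = power[np.minimum(valid + 1, power.size - 1)]
    is_peak = (pv >= prev_p) & (pv >= next_p)
    # range ends are open boundaries: a peak whose true maximum lies just
    # outside the admissible period range still counts at the edge bin
    is_peak[0] = pv[0] >= next_p[0]
    is_peak[-1] = pv[-1] >= prev_p[-1]
    peak_idx = valid[is_peak]
    peak_pow = pv[is_peak]
    if peak_idx.size == 0:
        raise InsufficientDataError(f"{method}: no spectral peaks in period range")
    # an impulse train puts (near-)equal power on every harmonic of the
    # fundamental; among peaks within 2% of the maximum prefer the lowest
    # frequency, i.e. the prime (largest) period, then rank by power
    near = peak_pow >= 0.98 * peak_pow.max()
    order = np.concatenate(
        [
            np.sort(peak_idx[near]),
            peak_idx[~near][np.argsort(-peak_pow[~near], kind="stable")],
        ]
    )
    chosen: list[int] = []
    for i in order:
        if len(chosen) >= k:
            break
        if any(abs(i - j) <= 1 for j in chosen):
            continue
        chosen.append(int(i))
    if len(chosen) < k:
        logger.warning("%s: only %d peaks found, padding to k=%d", method, len(chosen), k)
        for i in valid[np.argsort(-pv, kind="stable")]:
            if len(chosen) >= k:
                break
            if int(i) not in chosen:
                chosen.append(int(i))
    out_periods = tuple(int(round(nfft / i)) for i in chosen)
    out_scores = tuple(float(power[i]) for i in chosen)
    return BaselineResult(method, out_periods, out_scores)


def fft_periods(series: EventSeries, k: int, l_min: int = 10, l_max: int = 350) -> BaselineResult:
    """Top-k periods from the power spectrum of the binary series."""
    if series.n_t < 2 * l_min:
        raise InsufficientDataError("series shorter than twice the minimal period")
    return _periodogram_periods(series.to_binary(), "fft", k, l_min, l_max)


def acf_fft_periods(
    series: EventSeries, k: int, l_min: int = 10, l_max: int = 350
) -> BaselineResult:
    """Top-k periods from the spectrum of the autocorrelation sequence.

    The ACF of a periodic impulse train is itself an impulse train, so its
    spectrum concentrates at the true frequency; enough lags are kept
    (up to 10x the maximal period) to resolve long periods.
    """
    if series.n_t < 2 * l_min:
        raise InsufficientDataError("series shorter than twice the minimal period")
    x = series.to_binary().astype(float)
    x = x - x.mean()
    nlags = int(min(series.n_t - 1, 10 * l_max))
    nfft = 1 << int(np.ceil(np.log2(2 * x.size)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    acov = np.fft.irfft(spec)[: nlags + 1]
    return _periodogram_periods(acov[1:], "acf_fft", k, l_min, l_max)


def hist_fft_periods(
    hist: IntervalHistogram, k: int, l_min: int = 10, l_max: int = 350
) -> BaselineResult:
    """Top-k periods from the spectrum of the interval histogram D(mu)."""
    d = hist.counts[1:].astype(float)
    if not np.any(d != d.mean()):
        raise InsufficientDataError("flat interval histogram")
    return _periodogram_periods(d, "hist_fft", k, l_min, l_max)


def e_periodicity_periods(
    events: EventSeries, k: int, l_min: int = 10, l_max: int = 350
) -> BaselineResult:
    """Modulus-folding discrepancy score over candidate periods.

    score(p) counts event pairs whose interval is within +-1 of an integer
    multiple of p, normalized by the number of whole periods in the series
    span. Integer multiples of an already-selected period are suppressed so
    the prime period is reported rather than its harmonics.
    """
    if len(events) < 2:
        raise InsufficientDataError("need at least 2 events")
    ts = events.timestamps
    span = int(ts[-1] - ts[0])
    if span < l_min:
        raise InsufficientDataError("series span below minimal period")
    hist = interval_counts(events, span)
    cs = np.concatenate([[0.0], np.cumsum(hist.counts)])
    p_hi = min(l_max, span)
    ps = np.arange(l_min, p_hi + 1)
    scores = np.zeros(ps.size)
    for i, p in enumerate(ps):
        mult = np.arange(p, span + 1, p)
        lo = np.clip(mult - 1, 0, span + 1)
        hi = np.clip(mult + 2, 0, span + 1)
        scores[i] = np.sum(cs[hi] - cs[lo]) / max(span // p, 1)
    order = np.argsort(-scores, kind="stable")
    chosen: list[int] = []
    chosen_scores: list[float] = []
    for i in order:
        if len(chosen) >= k:
            break
        p = int(ps[i])
        if any(min(p % q, q - p % q) <= 1 and p >= 2 * q - 1 for q in chosen):
            continue  # (near-)integer multiple of an already-selected period
        chosen.append(p)
        chosen_scores.append(float(scores[i]))
    return BaselineResult("e_periodicity", tuple(chosen), tuple(chosen_scores))
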