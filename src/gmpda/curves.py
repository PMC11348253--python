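"""Parametric expected interval-count curves and the mixture loss.

For a single periodicity ``mu`` with jitter ``sigma`` in a series of length
``N_T``, the expected all-order interval histogram is a Gaussian mixture with
components at the integer multiples ``m * mu``:

    G(lag) = sum_m c_m * phi(lag; m*mu, v_m),      c_m = N_T/mu - (m - 1),

where ``phi`` is the normal density. The component variance is ``v_m =
sigma^2`` for the clock model and ``v_m = m * sigma^2`` for the random-walk
model (jitter accumulates step by step). Multi-period curves are sums of
single-period curves.

The fit of a curve to a noise-subtracted histogram is scored by the L1
distance after normalising both to unit mass on the evaluation window; the
loss is scale-free, lies in [0, 2], and is comparable across series of
different lengths and event counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: smallest admissible mixture width — half the sampling resolution
SIGMA_FLOOR = 0.5

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Periods and widths of a candidate Gaussian-mixture explanation."""

    model: str
    mu_hat: tuple[float, ...]
    sigma_hat: tuple[float, ...]
    n_t: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_hat", tuple(float(m) for m in self.mu_hat))
        object.__setattr__(self, "sigma_hat", tuple(float(s) for s in self.sigma_hat))
        if len(self.mu_hat) != len(self.sigma_hat):
            raise ValueError("mu_hat and sigma_hat must have equal length")
        if any(m <= 0 for m in self.mu_hat):
            raise ValueError("periods must be positive")


@dataclass(frozen=True)
class LossValue:
    """Normalized L1 loss over a lag window; 0 iff the shapes match exactly."""

    value: float
    window: tuple[int, int]


def single_period_curve(
    model: str,
    mu: float,
    sigma: float,
    n_t: int,
    lags: np.ndarray,
) -> np.ndarray:
    """Expected interval counts of one periodicity, evaluated at ``lags``."""
    if sigma < SIGMA_FLOOR:
        if sigma == 0:
            logger.warning("sigma=0 replaced by %.1f (sub-sample resolution)", SIGMA_FLOOR)
        sigma = SIGMA_FLOOR
    lags = np.asarray(lags, dtype=float)
    max_lag = float(lags.max())
    out = np.zeros_like(lags)
    m_total = max(int(n_t // mu), 1)
    for m in range(1, m_total + 1):
        var = sigma * sigma if model == "clock" else m * sigma * sigma
        sd = math.sqrt(var)
        center = m * mu
        if center > max_lag + 4.0 * sd:
            break
        c = max(n_t / mu - (m - 1), 0.0)
        if c == 0.0:
            break
        z = (lags - center) / sd
        out += c * _INV_SQRT_2PI / sd * np.exp(-0.5 * z * z)
    return out


def expected_counts(params: MixtureParams, lags: np.ndarray) -> np.ndarray:
    """Mixture curve: sum of single-period curves over all periodicities."""
    lags = np.asarray(lags, dtype=float)
    out = np.zeros_like(lags)
    for mu, sigma in zip(params.mu_hat, params.sigma_hat):
        out += single_period_curve(params.model, mu, sigma, params.n_t, lags)
    return out


def l1_normalized(a: np.ndarray, b: np.ndarray) -> float:
    """L1 distance between two non-negative vectors after unit-sum scaling."""
    sa, sb = float(a.sum()), float(b.sum())
    if sa <= 0:
        raise ValueError("empirical histogram has no mass on the window")
    an = a / sa
    bn = b / sb if sb > 0 else np.zeros_like(b)
    return float(np.abs(an - bn).sum())


def loss(cleaned: np.ndarray, params: MixtureParams, window: np.ndarray) -> LossValue:
    """Normalized L1 loss between a cleaned histogram and the mixture curve.

    ``cleaned`` must be lag-indexed (``cleaned[mu]`` = count at lag ``mu``);
    ``window`` is the integer lag range over which the loss is taken.
    """
    window = np.asarray(window)
    emp = np.asarray(cleaned, dtype=float)[window]
    model_curve = expected_counts(params, window)
    value = l1_normalized(emp, model_curve)
    return LossValue(value, (int(window[0]), int(window[-1])))
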