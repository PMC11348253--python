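"""The Gaussian Mixture Periodicity Detection Algorithm (GMPDA).

Pipeline on an event series:

1. build the all-order interval histogram ``D(mu)``;
2. estimate the uniform-noise interaction curve from sub-periodic lags and
   subtract it;
3. extract candidate periods from the cleaned histogram by comb-folding
   (integral convolution): the score of a lag ``q`` averages the smoothed
   histogram over the multiples of ``q``, so the prime period outscores its
   integer multiples, which match fewer peaks;
4. refine the mixture width ``sigma`` per candidate by bounded least squares
   against the single-period curve (optional, ``curve_fit``);
5. search subsets of candidates of size 1..max_periods exhaustively for the
   subset whose mixture curve minimises the normalized L1 loss; a larger
   subset is accepted only if it improves the loss by more than
   ``loss_tol_change``;
6. re-fit the widths jointly on the winning subset and report the final loss.

The algorithm is deterministic given the input series and configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize_scalar

from . import curves
from .curves import SIGMA_FLOOR, l1_normalized, single_period_curve
from .histogram import denoise, estimate_z, interval_counts
from .simulate import EventSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GmpdaConfig:
    """Tunable parameters of the detection algorithm.

    ``l_min``/``l_max`` bound the admissible periods, ``loss_length`` the lag
    range of the histogram and loss, ``noise_range`` (< ``l_min``) the
    sub-periodic window used to estimate the interaction curve. ``sigma_init``
    defaults to ``int(log(l_min))`` (at least 1), the width assumed before
    curve fitting.
    """

    model: str = "clock"
    l_min: int = 5
    l_max: int = 350
    loss_length: int = 400
    max_periods: int = 5
    max_candidates: int = 15
    max_iterations: int = 5
    noise_range: int = 5
    loss_tol_change: float = 0.01
    curve_fit: bool = True
    sigma_init: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.noise_range <= self.l_min <= self.l_max <= self.loss_length):
            raise ValueError("require noise_range <= l_min <= l_max <= loss_length")
        if self.max_periods < 1 or self.max_candidates < 1 or self.max_iterations < 1:
            raise ValueError("max_periods, max_candidates, max_iterations must be >= 1")

    @property
    def sigma0(self) -> float:
        if self.sigma_init is not None:
            return float(self.sigma_init)
        return float(max(1, int(math.log(self.l_min))))


@dataclass(frozen=True)
class PeriodicityEstimate:
    """Detected periods, fitted widths, final loss and the model used."""

    periods: tuple[int, ...]
    sigmas: tuple[float, ...]
    loss: float | None
    model: str
    candidates_considered: tuple[int, ...] = field(default=())

    @property
    def empty(self) -> bool:
        return not self.periods


def _loss_window(cfg: GmpdaConfig, n_t: int, vec_len: int) -> np.ndarray:
    hi = min(cfg.loss_length, n_t - 1, vec_len - 1)
    return np.arange(cfg.l_min, hi + 1)


def _comb_scores(cleaned: np.ndarray, cfg: GmpdaConfig, n_t: int) -> tuple[np.ndarray, np.ndarray]:
    """Comb-fold score for every admissible lag.

    score(q) = mean over multiples m*q <= loss window of the box-smoothed
    cleaned histogram at m*q, smoothing half-width w(q) = max(1, round(log q)).
    """
    length = min(cfg.loss_length, len(cleaned) - 1)
    cs = np.concatenate([[0.0], np.cumsum(cleaned[: length + 1])])
    q_hi = min(cfg.l_max, length)
    qs = np.arange(cfg.l_min, q_hi + 1)
    scores = np.zeros(qs.size)
    for i, q in enumerate(qs):
        w = max(1, round(math.log(q)))
        mult = np.arange(q, length + 1, q)
        lo = np.clip(mult - w, 0, length + 1)
        hi = np.clip(mult + w + 1, 0, length + 1)
        scores[i] = np.sum((cs[hi] - cs[lo]) / (2 * w + 1)) / mult.size
    return qs, scores


def _local_maxima(scores: np.ndarray) -> np.ndarray:
    """Indices that are not below either neighbour (plateau edges count)."""
    left = np.r_[True, scores[1:] >= scores[:-1]]
    right = np.r_[scores[:-1] >= scores[1:], True]
    return np.flatnonzero(left & right & (scores > 0))


def find_candidates(cleaned: np.ndarray, cfg: GmpdaConfig, n_t: int) -> list[int]:
    """Candidate periods from iterative comb-folding with residual subtraction.

    Runs up to ``max_iterations`` sweeps. Each sweep scores all lags on the
    current residual, accepts the highest-scoring local maxima (up to
    ``ceil(max_candidates / max_iterations)`` per sweep, ``max_candidates``
    in total), and subtracts each accepted candidate's amplitude-scaled
    single-period curve from the residual so later sweeps surface weaker
    periodicities. Candidates are returned strongest-first.
    """
    residual = np.asarray(cleaned, dtype=float).copy()
    if not residual.any():
        return []
    per_sweep = max(1, math.ceil(cfg.max_candidates / cfg.max_iterations))
    window = _loss_window(cfg, n_t, residual.size)
    cands: list[int] = []
    for _ in range(cfg.max_iterations):
        qs, scores = _comb_scores(residual, cfg, n_t)
        peaks = _local_maxima(scores)
        if peaks.size == 0:
            break
        top = scores[peaks].max()
        order = peaks[np.argsort(-scores[peaks], kind="stable")]
        accepted: list[int] = []
        for idx in order:
            if len(cands) + len(accepted) >= cfg.max_candidates or len(accepted) >= per_sweep:
                break
            q = int(qs[idx])
            if scores[idx] < 0.05 * top:
                break
            if q in cands or q in accepted:
                continue
            accepted.append(q)
        if not accepted:
            break
        for q in accepted:
            curve = single_period_curve(cfg.model, q, cfg.sigma0, n_t, np.arange(residual.size, dtype=float))
            denom = float(curve @ curve)
            scale = max(float(curve[window] @ residual[window]) / denom, 0.0) if denom > 0 else 0.0
            residual = np.clip(residual - scale * curve, 0.0, None)
        cands.extend(accepted)
        if len(cands) >= cfg.max_candidates:
            break
    return cands


def _fit_one_sigma(cleaned_w: np.ndarray, window: np.ndarray, mu: int, cfg: GmpdaConfig, n_t: int) -> float:
    """Bounded 1-D least squares for the width of a single-period curve."""
    lo, hi = SIGMA_FLOOR, max(mu / 2.0, SIGMA_FLOOR + 0.1)

    def sse(s: float) -> float:
        return float(
            np.sum((single_period_curve(cfg.model, mu, s, n_t, window) - cleaned_w) ** 2)
        )

    try:
        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 0.02})
        if res.success and math.isfinite(res.fun):
            return float(res.x)
    except Exception:  # pragma: no cover - optimizer failure is non-fatal
        pass
    logger.warning("sigma fit failed for mu=%d; falling back to sigma_init", mu)
    return cfg.sigma0


def fit_sigmas(cleaned: np.ndarray, candidates: list[int], cfg: GmpdaConfig, n_t: int) -> list[float]:
    """Per-candidate mixture widths (``sigma_init`` when fitting is off)."""
    if not candidates:
        raise ValueError("no candidates to fit")
    if not cfg.curve_fit:
        return [cfg.sigma0 for _ in candidates]
    window = _loss_window(cfg, n_t, len(cleaned))
    cleaned_w = np.asarray(cleaned, dtype=float)[window]
    return [_fit_one_sigma(cleaned_w, window, mu, cfg, n_t) for mu in candidates]


def select_best(
    cleaned: np.ndarray,
    candidates: list[int],
    sigmas: list[float],
    cfg: GmpdaConfig,
    n_t: int,
) -> PeriodicityEstimate:
    """Exhaustive subset search over candidates, greedy across subset sizes.

    For each size k the best subset (lowest normalized L1 loss) is found by
    evaluating all combinations; size k+1 replaces size k only when it lowers
    the loss by more than ``loss_tol_change``. When curve fitting is on, the
    widths of the winning subset are re-fitted coordinate-wise against the
    full mixture before the final loss is computed.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    window = _loss_window(cfg, n_t, len(cleaned))
    target = np.asarray(cleaned, dtype=float)[window]
    if target.sum() <= 0:
        return PeriodicityEstimate((), (), None, cfg.model, tuple(candidates))
    target_n = target / target.sum()
    curve_mat = np.stack(
        [single_period_curve(cfg.model, q, s, n_t, window) for q, s in zip(candidates, sigmas)]
    )
    n_c = len(candidates)
    best_subset: tuple[int, ...] | None = None
    best_loss = math.inf
    for k in range(1, min(cfg.max_periods, n_c) + 1):
        combos = np.array(list(combinations(range(n_c), k)))
        mix = curve_mat[combos].sum(axis=1)
        sums = mix.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            mix_n = np.where(sums > 0, mix / sums, 0.0)
        losses = np.abs(mix_n - target_n).sum(axis=1)
        i_best = int(np.argmin(losses))
        loss_k = float(losses[i_best])
        if best_subset is None or loss_k < best_loss - cfg.loss_tol_change:
            best_subset = tuple(combos[i_best])
            best_loss = loss_k
    assert best_subset is not None
    sel_mu = [candidates[i] for i in best_subset]
    sel_sigma = [sigmas[i] for i in best_subset]

    # the comb-fold candidate grid is coarse; descend on the integer period
    # grid (steps of +-1) against the loss before the final width refit
    sel_curves = [curve_mat[i].copy() for i in best_subset]
    for _ in range(5):
        moved = False
        for j, mu in enumerate(sel_mu):
            others = sum(sel_curves[i] for i in range(len(sel_mu)) if i != j) if len(sel_mu) > 1 else 0.0
            best_here = l1_normalized(target, others + sel_curves[j])
            for step in (-1, 1):
                mu_new = mu + step
                if not (cfg.l_min <= mu_new <= cfg.l_max) or mu_new in sel_mu:
                    continue
                cand_curve = single_period_curve(cfg.model, mu_new, sel_sigma[j], n_t, window)
                val = l1_normalized(target, others + cand_curve)
                if val < best_here - 1e-12:
                    sel_mu[j], sel_curves[j], best_here = mu_new, cand_curve, val
                    moved = True
        if not moved:
            break
    best_loss = l1_normalized(target, sum(sel_curves))

    if cfg.curve_fit and len(sel_mu) >= 1:
        # joint refinement: one coordinate-wise pass over the subset widths
        for j, mu in enumerate(sel_mu):
            others = sum(sel_curves[i] for i in range(len(sel_mu)) if i != j) if len(sel_mu) > 1 else 0.0

            def mix_loss(s: float) -> float:
                mix = others + single_period_curve(cfg.model, mu, s, n_t, window)
                return l1_normalized(target, mix)

            lo, hi = SIGMA_FLOOR, max(mu / 2.0, SIGMA_FLOOR + 0.1)
            try:
                res = minimize_scalar(mix_loss, bounds=(lo, hi), method="bounded", options={"xatol": 0.02})
                if res.success and res.fun <= best_loss + 1e-12:
                    sel_sigma[j] = float(res.x)
                    sel_curves[j] = single_period_curve(cfg.model, mu, sel_sigma[j], n_t, window)
                    best_loss = float(res.fun)
            except Exception:  # pragma: no cover
                logger.warning("joint sigma refinement failed for mu=%d", mu)
        mix = sum(sel_curves)
        best_loss = l1_normalized(target, mix)

    return PeriodicityEstimate(
        periods=tuple(int(m) for m in sel_mu),
        sigmas=tuple(float(s) for s in sel_sigma),
        loss=float(best_loss),
        model=cfg.model,
        candidates_considered=tuple(candidates),
    )


def gmpda_detect(events: EventSeries, cfg: GmpdaConfig) -> PeriodicityEstimate:
    """Run the full detection pipeline on an event series.

    Returns an empty estimate (no periods, loss ``None``) when the series has
    fewer than two events or no candidate periods emerge from the histogram.
    """
    if len(events) < 2:
        return PeriodicityEstimate((), (), None, cfg.model, ())
    max_lag = max(min(cfg.loss_length, events.n_t - 1), cfg.l_min)
    hist = interval_counts(events, max_lag)
    noise = estimate_z(hist, cfg.noise_range, cfg.l_min)
    cleaned = denoise(hist, noise)
    cands = find_candidates(cleaned, cfg, events.n_t)
    if not cands:
        return PeriodicityEstimate((), (), None, cfg.model, ())
    sigmas = fit_sigmas(cleaned, cands, cfg, events.n_t)
    return select_best(cleaned, cands, sigmas, cfg, events.n_t)
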