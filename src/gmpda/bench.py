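"""Benchmark harness: accuracy scoring, grid sweeps, and the reference loss.

A detected period is *correct* when it lies within ``mu* +- 0.5 sigma*`` of a
true period (exact match required when ``sigma* = 0``). Cell accuracy is the
fraction of true periodicities recovered across replicates. The reference
loss calibrates significance: it is a low quantile of the detection loss on
purely non-periodic (uniform) event series, so a periodic series scoring
below it is unlikely to be noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import baselines
from .detect import GmpdaConfig, gmpda_detect
from .histogram import interval_counts
from .simulate import EventSeries, GenerativeSpec, reseed, simulate

logger = logging.getLogger(__name__)

#: detector period search range used throughout the benchmarks
BENCH_L_MIN = 10
BENCH_L_MAX = 350


def is_correct(mu_pred: float, mu_true: float, sigma_true: float) -> bool:
    """Half-width acceptance: |pred - true| <= 0.5 * sigma (exact if sigma=0)."""
    if sigma_true < 0:
        raise ValueError("sigma_true must be non-negative")
    if sigma_true == 0:
        return round(mu_pred) == round(mu_true)
    return abs(mu_pred - mu_true) <= 0.5 * sigma_true


def score_estimate(pred: Sequence[float], truths: Sequence[tuple[float, float]]) -> int:
    """Number of true periodicities recovered, greedy one-to-one matching.

    Prediction-truth pairs are matched closest-first; each prediction and
    each truth is used at most once, so two predictions near one truth count
    once.
    """
    pairs = sorted(
        ((abs(p - mu), i, j) for i, p in enumerate(pred) for j, (mu, _) in enumerate(truths)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_p: set[int] = set()
    used_t: set[int] = set()
    n_correct = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        if is_correct(pred[i], *truths[j]):
            n_correct += 1
    return n_correct


@dataclass(frozen=True)
class BenchmarkCell:
    """Aggregated accuracy of one algorithm in one grid cell."""

    model: str
    sigma_rule: str
    beta: float
    n: int
    n_periods: int
    algorithm: str
    replicates: int
    accuracy: float
    seed: int


def bench_config(model: str, n_periods: int, curve_fit: bool = True) -> GmpdaConfig:
    """Detection configuration used in the benchmark sweeps.

    Searches periods on [10, 350] for up to ``n_periods + 2`` periodicities.
    """
    return GmpdaConfig(
        model=model,
        l_min=BENCH_L_MIN,
        l_max=BENCH_L_MAX,
        loss_length=400,
        max_periods=n_periods + 2,
        max_candidates=15,
        max_iterations=5,
        noise_range=5,
        loss_tol_change=0.01,
        curve_fit=curve_fit,
    )


def _run_gmpda(events: EventSeries, spec: GenerativeSpec, curve_fit: bool = True) -> list[float]:
    est = gmpda_detect(events, bench_config(spec.model, spec.n_periods, curve_fit))
    return list(est.periods)


def _run_baseline(name: str, events: EventSeries, spec: GenerativeSpec) -> list[float]:
    k = spec.n_periods
    if name == "fft":
        return list(baselines.fft_periods(events, k, BENCH_L_MIN, BENCH_L_MAX).periods)
    if name == "acf":
        return list(baselines.acf_fft_periods(events, k, BENCH_L_MIN, BENCH_L_MAX).periods)
    if name == "hist":
        hist = interval_counts(events, max_lag=min(400, events.n_t - 1))
        return list(baselines.hist_fft_periods(hist, k, BENCH_L_MIN, BENCH_L_MAX).periods)
    if name == "eper":
        return list(baselines.e_periodicity_periods(events, k, BENCH_L_MIN, BENCH_L_MAX).periods)
    raise ValueError(f"unknown algorithm {name!r}")


ALGORITHMS: dict[str, Callable[[EventSeries, GenerativeSpec], list[float]]] = {
    "gmpda": lambda ev, sp: _run_gmpda(ev, sp, curve_fit=True),
    "gmpda_nofit": lambda ev, sp: _run_gmpda(ev, sp, curve_fit=False),
    "fft": lambda ev, sp: _run_baseline("fft", ev, sp),
    "acf": lambda ev, sp: _run_baseline("acf", ev, sp),
    "hist": lambda ev, sp: _run_baseline("hist", ev, sp),
    "eper": lambda ev, sp: _run_baseline("eper", ev, sp),
}


def _cell_key(spec: GenerativeSpec) -> tuple:
    return (spec.model, spec.sigma_rule, spec.beta, spec.events_per_period, spec.n_periods)


def run_benchmark(
    grid: Sequence[GenerativeSpec],
    algorithms: Sequence[str],
    reps_per_cell: int = 20,
    seed: int = 0,
) -> list[BenchmarkCell]:
    """Simulate each grid cell and score every algorithm on it.

    At most ``reps_per_cell`` replicate specs are used per cell; replicate
    seeds derive deterministically from (master seed, cell index, replicate
    index). Individual run failures contribute zero correct periods and never
    abort the sweep.
    """
    if reps_per_cell < 1:
        raise ValueError("reps_per_cell must be >= 1")
    cells: dict[tuple, list[GenerativeSpec]] = {}
    for spec in grid:
        cells.setdefault(_cell_key(spec), []).append(spec)
    results: list[BenchmarkCell] = []
    for c_idx, (key, specs) in enumerate(sorted(cells.items(), key=lambda kv: repr(kv[0]))):
        model, rule, beta, n, n_per = key
        # canonical replicate order so results do not depend on grid order
        specs = sorted(specs, key=lambda sp: (sp.seed, sp.periods))
        reps = specs[:reps_per_cell]
        correct = {a: 0 for a in algorithms}
        total = 0
        for r_idx, spec in enumerate(reps):
            child = np.random.SeedSequence([seed, c_idx, r_idx]).generate_state(1)[0] % (2**31)
            spec = reseed(spec, child)
            try:
                events = simulate(spec)
            except Exception:
                logger.exception("simulation failed for %s", spec)
                total += spec.n_periods
                continue
            truths = list(zip(spec.periods, spec.sigmas))
            total += len(truths)
            for algo in algorithms:
                try:
                    pred = ALGORITHMS[algo](events, spec)
                    correct[algo] += score_estimate(pred, truths)
                except Exception:
                    logger.debug("%s failed on %s", algo, spec, exc_info=True)
        for algo in algorithms:
            results.append(
                BenchmarkCell(
                    model=model,
                    sigma_rule=str(rule),
                    beta=float(beta),
                    n=int(n),
                    n_periods=int(n_per),
                    algorithm=algo,
                    replicates=len(reps),
                    accuracy=correct[algo] / total if total else 0.0,
                    seed=seed,
                )
            )
    return results


def cells_to_frame(cells: Sequence[BenchmarkCell]) -> pd.DataFrame:
    """Tidy data frame (one row per cell x algorithm) for export."""
    return pd.DataFrame([c.__dict__ for c in cells])


DEFAULT_REFERENCE_COUNTS = (10, 30, 50, 100, 200, 400)
DEFAULT_REFERENCE_LENGTHS = (500, 1000, 2000, 4000, 8000, 16000)


def sleep_bout_config(curve_fit: bool = True) -> GmpdaConfig:
    """Detection preset used for the sleep-bout application and reference loss."""
    return GmpdaConfig(
        model="random_walk",
        l_min=5,
        l_max=200,
        loss_length=400,
        max_periods=5,
        max_candidates=15,
        max_iterations=5,
        noise_range=5,
        loss_tol_change=0.1,
        curve_fit=curve_fit,
    )


def reference_loss(
    event_counts: Sequence[int] = DEFAULT_REFERENCE_COUNTS,
    lengths: Sequence[int] = DEFAULT_REFERENCE_LENGTHS,
    reps: int = 100,
    quantile: float = 0.01,
    cfg: GmpdaConfig | None = None,
    seed: int = 0,
    return_losses: bool = False,
):
    """Quantile of the detection loss on purely uniform (non-periodic) series.

    For every (event count, series length) combination, ``reps`` series of
    uniform random events are generated and the detection loss collected;
    the requested quantile of the pooled distribution is returned. Runs with
    an undefined loss (degenerate series) are skipped.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = cfg or sleep_bout_config()
    losses: list[float] = []
    for i, count in enumerate(event_counts):
        for j, length in enumerate(lengths):
            for r in range(reps):
                child = np.random.SeedSequence([seed, i, j, r]).generate_state(1)[0]
                rng = np.random.default_rng(child)
                ts = np.unique(rng.integers(1, length + 1, size=count))
                if ts.size < 2:
                    continue
                events = EventSeries(ts, int(length))
                est = gmpda_detect(events, cfg)
                if est.loss is None or not math.isfinite(est.loss):
                    logger.debug("undefined loss for count=%d length=%d", count, length)
                    continue
                losses.append(est.loss)
    if not losses:
        raise RuntimeError("no defined losses collected")
    q = float(np.quantile(losses, quantile))
    if return_losses:
        return q, losses
    return q
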