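"""Generative models for periodic event time series.

Two generative schemes produce binary event series with `P` overlapping
periodicities plus uniform false-positive noise:

* **Clock model** — a pacemaker places the *i*-th event of periodicity ``mu``
  at ``alpha + i*mu + eps`` with ``eps ~ N(0, sigma^2)``: jitter does not
  accumulate, so the m-step interval variance is constant in ``m``.
* **Random-walk model** — each event is offset from the previous one by
  ``mu + eps`` with i.i.d. ``eps ~ N(0, sigma^2)``: the m-step interval has
  variance ``m * sigma^2`` (linear growth, Markov property).

Noise is parameterised by the rate ``beta``: ``round(beta * n_periodic)``
false-positive timestamps drawn uniformly on ``[0, N_T]`` are unioned with the
periodic events, so ``beta = 2`` means a signal-to-noise ratio of 1:2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Model = Literal["clock", "random_walk"]

SIGMA_RULES = ("1", "log", "mu/16", "mu/8", "mu/4", "mu/3")

#: parameter grids of the single-period benchmark sweep
SINGLE_GRID = {
    "sigma_rules": ("1", "log", "mu/16", "mu/8", "mu/4", "mu/3"),
    "ns": (10, 30, 50, 100, 300, 500),
    "betas": (0.0, 0.1, 0.5, 0.7, 1.0, 2.0, 4.0, 8.0),
    "replicates": 100,
}

#: parameter grids of the two- and three-period sweeps
MULTI_GRID = {
    "sigma_rules": ("1", "log", "mu/16", "mu/8"),
    "ns": (50, 100, 300, 500),
    "betas": (0.0, 0.1, 0.5, 0.7, 1.0),
    "replicates": 100,
}

MU_RANGE = (10, 350)


class InvalidSpecError(ValueError):
    """Raised for non-finite, negative or inconsistent generative parameters."""


class DegenerateSeriesError(ValueError):
    """Raised when a generated series collapses onto a single timestamp."""


@dataclass(frozen=True)
class EventSeries:
    """A binary event series, stored as its sorted event timestamps.

    Parameters
    ----------
    timestamps
        Strictly increasing non-negative integer event times ``s_i``.
    n_t
        Length ``N_T`` of the underlying binary series; every timestamp lies
        in ``[0, n_t]``.
    """

    timestamps: np.ndarray
    n_t: int

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        object.__setattr__(self, "timestamps", ts)
        if ts.ndim != 1:
            raise InvalidSpecError("timestamps must be one-dimensional")
        if ts.size and (np.any(np.diff(ts) <= 0)):
            raise InvalidSpecError("timestamps must be strictly increasing")
        if ts.size and (ts[0] < 0 or ts[-1] > self.n_t):
            raise InvalidSpecError("timestamps must lie in [0, n_t]")
        if self.n_t < 1:
            raise InvalidSpecError("n_t must be positive")

    @classmethod
    def from_unsorted(cls, timestamps: Iterable[int], n_t: int | None = None) -> "EventSeries":
        """Sort, deduplicate and wrap raw timestamps; infer ``n_t`` if absent."""
        ts = np.unique(np.asarray(list(timestamps), dtype=np.int64))
        ts = ts[ts >= 0]
        if n_t is None:
            if ts.size == 0:
                raise DegenerateSeriesError("empty series and no n_t given")
            n_t = int(ts[-1]) if ts[-1] > 0 else 1
        return cls(ts, int(n_t))

    def to_binary(self) -> np.ndarray:
        """Binary representation ``X_t`` of length ``n_t + 1`` (index = time)."""
        x = np.zeros(self.n_t + 1, dtype=np.int8)
        x[self.timestamps] = 1
        return x

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class GenerativeSpec:
    """Parameters of the generative function producing an :class:`EventSeries`.

    ``periods``, ``sigmas`` and ``alphas`` are per-periodicity and must have
    equal length ``P``. ``beta`` is the false-positive rate (noise events per
    periodic event), ``events_per_period`` the number ``n`` of events each
    periodicity contributes. ``sigma_rule`` is an optional label recording how
    the sigmas were derived from the periods (benchmark bookkeeping only).
    """

    model: Model
    periods: tuple[float, ...]
    sigmas: tuple[float, ...]
    alphas: tuple[int, ...] = ()
    beta: float = 0.0
    events_per_period: int = 100
    seed: int = 0
    sigma_rule: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(float(m) for m in self.periods))
        object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))
        alphas = self.alphas or tuple(0 for _ in self.periods)
        object.__setattr__(self, "alphas", tuple(int(a) for a in alphas))
        if self.model not in ("clock", "random_walk"):
            raise InvalidSpecError(f"unknown model {self.model!r}")
        if not self.periods:
            raise InvalidSpecError("at least one periodicity is required")
        if not (len(self.periods) == len(self.sigmas) == len(self.alphas)):
            raise InvalidSpecError("periods, sigmas and alphas must have equal length")
        vals = self.periods + self.sigmas + (self.beta,)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidSpecError("parameters must be finite")
        if any(m <= 0 for m in self.periods):
            raise InvalidSpecError("periods must be positive")
        if any(s < 0 for s in self.sigmas) or self.beta < 0:
            raise InvalidSpecError("sigmas and beta must be non-negative")
        if any(a < 0 for a in self.alphas):
            raise InvalidSpecError("alphas must be non-negative")
        if self.events_per_period < 1:
            raise InvalidSpecError("events_per_period must be >= 1")

    @property
    def n_periods(self) -> int:
        return len(self.periods)


def resolve_sigma(rule: str, mu: float) -> float:
    """Map a sigma rule label (``"1"``, ``"log"``, ``"mu/16"``, ...) to a value."""
    if rule == "1":
        return 1.0
    if rule == "log":
        return math.log(mu)
    if rule.startswith("mu/"):
        return mu / float(rule[3:])
    raise InvalidSpecError(f"unknown sigma rule {rule!r}")


def simulate(spec: GenerativeSpec) -> EventSeries:
    """Draw one event series from the generative model.

    For each periodicity ``p`` exactly ``n = events_per_period`` periodic
    events are generated by the model recurrence; ``round(beta * total)``
    uniform noise timestamps on ``[0, N_T]`` are then unioned in. ``N_T`` is
    the largest periodic timestamp, so ``n ≈ N_T / mu`` holds for each
    periodicity, matching the count weights of the expected-interval curves.
    Timestamps are rounded to integers and deduplicated.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.events_per_period
    periodic: list[np.ndarray] = []
    for mu, sigma, alpha in zip(spec.periods, spec.sigmas, spec.alphas):
        eps = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
        if spec.model == "clock":
            s = alpha + np.arange(1, n + 1) * mu + eps
        else:  # random walk: accumulate increments mu + eps from s_0 = alpha
            s = alpha + np.cumsum(mu + eps)
        periodic.append(np.rint(s).astype(np.int64))
    per = np.concatenate(periodic)
    n_dropped = int(np.sum(per < 0))
    if n_dropped:
        logger.warning("dropping %d negative timestamps", n_dropped)
        per = per[per >= 0]
    if per.size == 0 or per.max() <= per.min():
        raise DegenerateSeriesError("all periodic events collapsed onto one timestamp")
    n_t = int(per.max())
    n_noise = int(round(spec.beta * per.size))
    if n_noise:
        noise = rng.integers(0, n_t + 1, size=n_noise)
        per = np.concatenate([per, noise])
    ts = np.unique(per)
    n_collisions = n_noise + len(spec.periods) * n - n_dropped - ts.size
    if n_collisions:
        logger.debug("%d timestamp collisions collapsed", n_collisions)
    return EventSeries(ts, n_t)


def _draw_periods(rng: np.random.Generator, n_periods: int) -> tuple[int, ...]:
    """Draw integer periods in [10, 350] whose pairwise separation exceeds
    log of the larger period (keeps overlapping mixtures distinguishable)."""
    lo, hi = MU_RANGE
    while True:
        mus = sorted(int(m) for m in rng.integers(lo, hi + 1, size=n_periods))
        ok = all(
            mus[j] - mus[i] > math.log(max(mus[i], mus[j]))
            for i in range(n_periods)
            for j in range(i + 1, n_periods)
        )
        if ok:
            return tuple(mus)


def grid_specs(
    model: Model,
    n_periods: int,
    sigma_rules: Sequence[str],
    ns: Sequence[int],
    betas: Sequence[float],
    replicates: int,
    seed: int = 0,
) -> list[GenerativeSpec]:
    """Cartesian benchmark grid of generative specs with drawn random periods.

    For every (sigma_rule, n, beta) cell, ``replicates`` specs are created,
    each with freshly drawn integer periods and per-period sigmas resolved
    from the rule. Spec seeds derive deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    specs: list[GenerativeSpec] = []
    for rule in sigma_rules:
        for n in ns:
            for beta in betas:
                for _ in range(replicates):
                    mus = _draw_periods(rng, n_periods)
                    sigmas = tuple(resolve_sigma(rule, m) for m in mus)
                    specs.append(
                        GenerativeSpec(
                            model=model,
                            periods=mus,
                            sigmas=sigmas,
                            beta=float(beta),
                            events_per_period=int(n),
                            seed=int(rng.integers(0, 2**31)),
                            sigma_rule=rule,
                        )
                    )
    return specs


def build_test_grid(
    kind: Literal["single", "multi2", "multi3"],
    model: Model = "clock",
    seed: int = 0,
) -> list[GenerativeSpec]:
    """The full benchmark grids: 28,800 specs (single) or 8,000 (multi2/multi3)."""
    if kind == "single":
        return grid_specs(model, 1, seed=seed, **SINGLE_GRID)
    if kind in ("multi2", "multi3"):
        return grid_specs(model, 2 if kind == "multi2" else 3, seed=seed, **MULTI_GRID)
    raise InvalidSpecError(f"unknown grid kind {kind!r}")


def reseed(spec: GenerativeSpec, seed: int) -> GenerativeSpec:
    """Copy of ``spec`` with a different random seed."""
    return replace(spec, seed=int(seed))
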