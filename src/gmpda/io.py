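"""Readers and writers for event series and detection results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .detect import PeriodicityEstimate
from .simulate import EventSeries


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as an event series."""


def read_events(path: str | Path, format: Literal["timestamps", "binary"] = "timestamps") -> EventSeries:
    """Load an event series from CSV/TSV.

    ``timestamps`` format: one non-negative integer timestamp per row (an
    optional ``timestamp`` header is accepted). ``binary`` format: rows
    ``t,x`` with ``x`` in {0, 1}; events are the rows with ``x = 1``.
    Timestamps are sorted and deduplicated; ``N_T`` is the largest time seen.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ParseError(f"{path}: empty file, no events")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    first = text.splitlines()[0].split(sep)[0].strip()
    header = 0 if not first.lstrip("-").isdigit() else None
    df = pd.read_csv(path, sep=sep, header=header)
    if format == "timestamps":
        col = df.iloc[:, 0]
        if not np.issubdtype(col.dtype, np.integer):
            bad = col[~col.astype(str).str.fullmatch(r"\d+")].index
            line = int(bad[0]) + 1 + (1 if header == 0 else 0) if len(bad) else "?"
            raise ParseError(f"{path}: non-integer or negative timestamp at line {line}")
        ts = col.to_numpy(dtype=np.int64)
        if (ts < 0).any():
            line = int(np.flatnonzero(ts < 0)[0]) + 1 + (1 if header == 0 else 0)
            raise ParseError(f"{path}: negative timestamp at line {line}")
        return EventSeries.from_unsorted(ts)
    if format == "binary":
        if df.shape[1] < 2:
            raise ParseError(f"{path}: binary format needs two columns t,x")
        t = df.iloc[:, 0].to_numpy(dtype=np.int64)
        x = df.iloc[:, 1].to_numpy()
        if not set(np.unique(x)) <= {0, 1}:
            raise ParseError(f"{path}: binary column must contain only 0/1")
        ts = t[x == 1]
        if ts.size == 0:
            raise ParseError(f"{path}: no events (all x = 0)")
        return EventSeries.from_unsorted(ts, n_t=int(t.max()))
    raise ParseError(f"unknown format {format!r}")


def write_events(events: EventSeries, path: str | Path, format: Literal["timestamps", "binary"] = "timestamps") -> None:
    """Write an event series as CSV (timestamp column, or ``t,x`` rows)."""
    path = Path(path)
    if format == "timestamps":
        pd.DataFrame({"timestamp": events.timestamps}).to_csv(path, index=False)
    else:
        x = events.to_binary()
        pd.DataFrame({"t": np.arange(x.size), "x": x}).to_csv(path, index=False)


def write_result(estimate: PeriodicityEstimate, path: str | Path, config: dict | None = None) -> None:
    """Serialize a detection result to JSON (round-trips losslessly)."""
    doc = {
        "periods": list(estimate.periods),
        "sigmas": list(estimate.sigmas),
        "loss": estimate.loss,
        "model": estimate.model,
        "candidates": list(estimate.candidates_considered),
        "config": config or {},
        "version": __version__,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path) -> PeriodicityEstimate:
    """Load a detection result previously written by :func:`write_result`."""
    doc = json.loads(Path(path).read_text())
    return PeriodicityEstimate(
        periods=tuple(doc["periods"]),
        sigmas=tuple(doc["sigmas"]),
        loss=doc["loss"],
        model=doc["model"],
        candidates_considered=tuple(doc.get("candidates", ())),
    )
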