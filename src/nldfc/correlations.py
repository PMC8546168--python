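"""Event-based and full-series correlation estimators.

Five estimators of inter-regional coupling are provided.  ``pearson_full``
is the conventional whole-series Pearson correlation and is symmetric by
construction.  The four event-based estimators correlate only the signal
inside source/target event windows; because each region has its own set of
source events, the resulting matrices are generally *asymmetric* — entry
(i, j) uses region i's events, entry (j, i) uses region j's.

``event_correlation_average`` (correlating the mean source waveform with
the mean target waveform) is the default estimator for matrix assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import (DEFAULT_POST, DEFAULT_PRE, DEFAULT_THRESHOLD, EventStack,
                     average_event, detect_events, extract_events)
from .signal_io import RoiTimeSeries
from . import events as _events

logger = logging.getLogger(__name__)

EVENT_METHODS = ("event_single", "event_mean", "event_concat", "event_average")
METHODS = ("pearson_full",) + EVENT_METHODS

_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FcMatrix:
    """An ``N x N`` functional-connectivity matrix with provenance.

    ``values[i, j]`` is the estimate with region i as source and region j
    as target; NaN marks undefined entries.  ``event_counts[i]`` is the
    number of usable source events of region i (0 for ``pearson_full``).
    """

    values: np.ndarray
    method: str
    labels: tuple[str, ...]
    params: dict = field(default_factory=dict)
    event_counts: tuple[int, ...] = ()
    n_undefined: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.max() > 1 + 1e-9 or finite.min() < -1 - 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_full(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Whole-series Pearson correlation; exactly symmetric in (i, j)."""
    return _pearson(x_i, x_j)


def event_correlation_single(source_stack: EventStack, target_stack: EventStack,
                             k: int) -> float:
    """Correlation of the k-th source event with its target event.

    Returns NaN (flagged undefined) when either segment is constant over
    the window.
    """
    if not 0 <= k < source_stack.n_events:
        raise IndexError(f"event index {k} out of range")
    s = source_stack.segments[k]
    t = target_stack.segments[k]
    if s.std() == 0 or t.std() == 0:
        return float("nan")
    return _pearson(s, t)


def event_correlation_mean(source_stack: EventStack,
                           target_stack: EventStack) -> tuple[float, int]:
    """Mean of the per-event correlations over usable (non-constant) events.

    Returns ``(r_bar, n_used)``; ``r_bar`` is NaN when no event is usable.
    """
    if source_stack.n_events < 1:
        raise ValueError("need at least one event")
    rs = [event_correlation_single(source_stack, target_stack, k)
          for k in range(source_stack.n_events)]
    rs = np.asarray(rs)
    ok = np.isfinite(rs)
    n_used = int(ok.sum())
    if n_used == 0:
        logger.warning("all %d per-event correlations undefined", rs.size)
        return float("nan"), 0
    if n_used < rs.size:
        logger.info("excluded %d undefined per-event correlation(s)",
                    rs.size - n_used)
    return float(rs[ok].mean()), n_used


def event_correlation_concat(source_stack: EventStack,
                             target_stack: EventStack) -> float:
    """Correlation of row-major concatenations of all source/target events."""
    if source_stack.n_events < 1:
        raise ValueError("need at least one event")
    return _pearson(source_stack.segments.ravel(), target_stack.segments.ravel())


def event_correlation_average(source_stack: EventStack,
                              target_stack: EventStack) -> float:
    """Correlation of the average source event with the average target event."""
    return _pearson(average_event(source_stack), average_event(target_stack))


def fisher_z(r) -> np.ndarray | float:
    """Fisher z-transform, ``arctanh(r)``, with |r| clipped to 1 - 1e-7."""
    r = np.clip(r, -_CLIP, _CLIP)
    return np.arctanh(r)


def fc_matrix(series: RoiTimeSeries, method: str = "event_average",
              threshold: float = DEFAULT_THRESHOLD,
              pre: int = DEFAULT_PRE, post: int = DEFAULT_POST,
              event_index: int = 0) -> FcMatrix:
    """Assemble the full N x N FC matrix under the chosen estimator.

    For event methods, row i is built from region i's source events; a
    region with zero usable events yields a NaN row (and a warning).
    ``event_index`` selects k for ``method="event_single"``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    series = _events._ensure_zscored(series)
    N = series.n_regions
    if N < 2:
        raise ValueError("need at least 2 regions for an FC matrix")
    params = {"threshold": threshold, "pre": pre, "post": post}
    values = np.full((N, N), np.nan)
    n_undef = 0

    if method == "pearson_full":
        values = np.corrcoef(series.data.T)
        np.fill_diagonal(values, 1.0)
        values = (values + values.T) / 2.0  # exact symmetry
        return FcMatrix(values, method, series.labels, params,
                        event_counts=(0,) * N)

    stacks = _event_stacks(series, threshold, pre, post)
    counts = tuple(stacks[i][i].n_events for i in range(N))
    for i in range(N):
        if counts[i] == 0:
            logger.warning("region %s has no events; source row undefined",
                           series.labels[i])
            n_undef += N
            continue
        src = stacks[i][i]
        for j in range(N):
            tgt = stacks[i][j]
            try:
                if method == "event_single":
                    r = event_correlation_single(src, tgt, event_index)
                elif method == "event_mean":
                    r, _ = event_correlation_mean(src, tgt)
                elif method == "event_concat":
                    r = event_correlation_concat(src, tgt)
                else:
                    r = event_correlation_average(src, tgt)
            except ValueError:
                r = float("nan")
            if not np.isfinite(r):
                n_undef += 1
            values[i, j] = r
    return FcMatrix(values, method, series.labels, params,
                    event_counts=counts, n_undefined=n_undef)


def seed_map(series: RoiTimeSeries, source_region: str,
             method: str = "event_average",
             threshold: float = DEFAULT_THRESHOLD,
             pre: int = DEFAULT_PRE, post: int = DEFAULT_POST) -> dict[str, float]:
    """One-source-vs-many-targets map (a single FC-matrix row).

    Streams over target columns so voxel-level target sets do not require
    materialising the full N x N matrix.
    """
    series = _events._ensure_zscored(series)
    ev = detect_events(series, source_region, threshold, pre, post)
    if ev.n_events == 0:
        raise ValueError(f"region {source_region!r} has no events")
    src = extract_events(series, source_region, ev.crossing_times, pre, post)
    out: dict[str, float] = {}
    for label in series.labels:
        tgt = extract_events(series, source_region, src.crossing_times,
                             pre, post, target_region=label)
        try:
            if method == "pearson_full":
                r = pearson_full(series.column(source_region), series.column(label))
            elif method == "event_mean":
                r, _ = event_correlation_mean(src, tgt)
            elif method == "event_concat":
                r = event_correlation_concat(src, tgt)
            else:
                r = event_correlation_average(src, tgt)
        except ValueError:
            r = float("nan")
        out[label] = r
    return out


def _event_stacks(series: RoiTimeSeries, threshold: float, pre: int,
                  post: int) -> list[list[EventStack]]:
    """stacks[i][j] = events of region j cut at region i's source times."""
    N = series.n_regions
    stacks: list[list[EventStack]] = []
    for i, src_label in enumerate(series.labels):
        ev = detect_events(series, src_label, threshold, pre, post)
        row = []
        for j, tgt_label in enumerate(series.labels):
            row.append(extract_events(series, src_label, ev.crossing_times,
                                      pre, post,
                                      target_region=tgt_label))
        stacks.append(row)
    return stacks
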