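"""Inter-regional temporal lag estimation.

Two estimators, both in TR units:

* ``pearson_delay`` — the lag at which the full-series lagged
  cross-covariance ``C_ij(tau) = (1/T) sum_t x_i(t + tau) x_j(t)`` has its
  extremum, refined to sub-sample resolution with a three-point parabola.
  The reversal identity ``C_ij(-tau) = C_ji(tau)`` holds exactly by
  construction, which makes the resulting delay matrix exactly
  antisymmetric.

* ``event_delay`` — for each source event of region i, find the closest
  peak of region j's signal within a window of ``[-6, +8]`` TRs of the
  crossing, fit parabolas to both the source and target peaks, and take
  the difference of the refined peak times.  A target peak at the window
  edge yields a lag clamped to exactly -6 or +6, unrefined.

Sign conventions differ between the two (each follows its own
definition): ``pearson_delay(i, j) > 0`` means region i's pattern is
shifted *later* than j's under the cross-covariance indexing above, while
``event_delay(i, j) > 0`` means the *target* (j) peaks after the source
(i).  Every result carries its convention string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .events import DEFAULT_POST, DEFAULT_PRE, DEFAULT_THRESHOLD, detect_events
from .signal_io import RoiTimeSeries
from . import events as _events

logger = logging.getLogger(__name__)

#: Default event-delay search window in TRs around the source crossing.
DEFAULT_WINDOW = (-6, 8)
#: Edge-clamped lag values (asymmetric with the search window, by design).
DEFAULT_CLAMP = (-6.0, 6.0)

PEARSON_SIGN_CONVENTION = ("positive tau(i,j): region i's activity is shifted "
                           "later than region j's (C_ij(tau) indexing)")
EVENT_SIGN_CONVENTION = ("positive tau(i,j): target region j peaks after "
                         "source region i")


@dataclass(frozen=True)
class LaggedCovariance:
    """Cross-covariance ``C_ij(tau)`` on the integer lag grid ``-L..L``."""

    lags: np.ndarray
    values: np.ndarray

    def at(self, lag: int) -> float:
        idx = int(lag) + (len(self.lags) - 1) // 2
        return float(self.values[idx])


@dataclass(frozen=True)
class EventDelayResult:
    """Per-event and averaged event-based lags for one (source, target) pair."""

    per_event: np.ndarray
    mean: float
    n_edge_clamped: int
    convention: str = EVENT_SIGN_CONVENTION


@dataclass(frozen=True)
class DelayMatrix:
    """``N x N`` matrix of lags in TR units.

    ``pearson_lag`` matrices are exactly antisymmetric; ``event_lag``
    matrices generally are not, because each row uses its own source
    events.
    """

    values: np.ndarray
    method: str
    labels: tuple[str, ...]
    tr: float
    per_event: dict | None = None
    convention: str = ""


def lagged_crosscov(x_i: np.ndarray, x_j: np.ndarray, max_lag: int) -> LaggedCovariance:
    """Lagged cross-covariance of two z-scored series, lags ``-L..L``.

    For ``tau >= 0`` the sum runs over the overlapping samples and is
    divided by the full length T (so ``C_ii(0) = 1`` for population-SD
    z-scored input); negative lags are defined through the reversal
    identity ``C_ij(-tau) := C_ji(tau)``.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    T = len(x_i)
    if len(x_j) != T:
        raise ValueError("series must have equal length")
    L = int(max_lag)
    if not 0 < L < T / 2:
        raise ValueError(f"max_lag must satisfy 0 < L < T/2 = {T / 2:g}")
    values = np.empty(2 * L + 1)
    for tau in range(L + 1):
        # C_ij(tau): x_i shifted tau samples forward against x_j
        values[L + tau] = np.dot(x_i[tau:], x_j[:T - tau]) / T
        # C_ij(-tau) = C_ji(tau)
        values[L - tau] = np.dot(x_j[tau:], x_i[:T - tau]) / T
    return LaggedCovariance(lags=np.arange(-L, L + 1), values=values)


def parabolic_vertex(y_minus: float, y_0: float, y_plus: float) -> float:
    """Sub-sample offset of the vertex of the parabola through three points.

    The points sit at abscissae -1, 0, +1.  Returns
    ``0.5 * (y_minus - y_plus) / (y_minus - 2 y_0 + y_plus)``, clamped to
    ``[-1, 1]``; a near-degenerate denominator (|.| < 1e-12) yields 0.
    """
    denom = y_minus - 2.0 * y_0 + y_plus
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (y_minus - y_plus) / denom, -1.0, 1.0))


def pearson_delay(x_i: np.ndarray, x_j: np.ndarray, max_lag: int,
                  positive_only: bool = False) -> float:
    """Sub-sample lag of the extremum of the lagged cross-covariance.

    By default the extremum of |C| is used, so anticorrelated propagation
    is captured; ``positive_only=True`` restores the maximum of C itself.
    Extrema at the search bounds are returned unrefined at ``+-max_lag``.
    """
    cov = lagged_crosscov(x_i, x_j, max_lag)
    score = cov.values if positive_only else np.abs(cov.values)
    if np.all(cov.values == 0):
        logger.warning("pearson_delay: all-zero cross-covariance")
        return float("nan")
    m = int(np.argmax(score))
    lag = int(cov.lags[m])
    if m == 0 or m == len(score) - 1:
        return float(lag)
    delta = parabolic_vertex(cov.values[m - 1], cov.values[m], cov.values[m + 1])
    return lag + delta


@dataclass(frozen=True)
class PeakResult:
    """Outcome of a windowed peak search: sample index and edge flag."""

    index: int
    edge: str | None = None  # None | "left" | "right"


#: Minimum peak prominence (SD units) for a local maximum to count as a
#: candidate target peak.  Peaks of any *amplitude* qualify — including
#: sub-threshold ones — but ripples less prominent than this are treated
#: as numerical noise, not peaks.
DEFAULT_MIN_PROMINENCE = 0.5


def find_target_peak(x_j: np.ndarray, t_source: int,
                     window: tuple[int, int] = DEFAULT_WINDOW,
                     polarity: str = "positive",
                     reference: int | None = None,
                     min_prominence: float = DEFAULT_MIN_PROMINENCE) -> PeakResult:
    """Closest peak of ``x_j`` to the source event within the search window.

    The window is anchored at ``t_source`` (the threshold crossing);
    closeness is measured to ``reference`` — by default the crossing
    itself, but the event-delay routine passes the source *peak*, which
    the target search is centred on.  Candidate peaks are interior local
    maxima (for ``polarity="negative"``, local minima — de-activation
    events) with prominence >= ``min_prominence`` SD; a plateau
    contributes its leftmost sample.  The candidate minimising the
    distance to the reference wins; ties go to the earlier peak.  With no
    interior extremum the window's best sample is used, and if that sits
    on a window edge the result is flagged ``"left"`` or ``"right"`` for
    the caller's clamping rule.  ``min_prominence=0`` restores the bare
    strict-local-maximum rule.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    if reference is None:
        reference = t_source
    y = np.asarray(x_j, dtype=float)
    if polarity == "negative":
        y = -y
    T = len(y)
    lo = max(0, t_source + window[0])
    hi = min(T - 1, t_source + window[1])
    if lo > hi:
        raise ValueError("search window does not intersect the series")
    seg = y[lo:hi + 1]
    # interior local maxima; strict rise from the left, non-rise to the
    # right, so a plateau yields its leftmost sample
    cand = [t for t in range(1, len(seg) - 1)
            if seg[t] > seg[t - 1] and seg[t] >= seg[t + 1]]
    if cand and min_prominence > 0:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # plateau-left candidates get prominence 0; they are filtered out
            _warnings.simplefilter("ignore")
            prom = _sig.peak_prominences(seg, cand)[0]
        cand = [t for t, p in zip(cand, prom) if p >= min_prominence]
    cand = [lo + t for t in cand]
    if cand:
        best = min(cand, key=lambda t: (abs(t - reference), t))
        return PeakResult(index=best)
    m = lo + int(np.argmax(seg))
    if m == lo:
        return PeakResult(index=m, edge="left")
    if m == hi:
        return PeakResult(index=m, edge="right")
    return PeakResult(index=m)


def _refined_peak_time(x: np.ndarray, idx: int, lo: int, hi: int) -> float:
    """Peak position plus parabolic offset; offset 0 at window/series edges."""
    if idx <= max(lo, 0) or idx >= min(hi, len(x) - 1):
        return float(idx)
    delta = parabolic_vertex(x[idx - 1], x[idx], x[idx + 1])
    return idx + delta


def event_delay(x_i: np.ndarray, x_j: np.ndarray, source_times,
                pre: int = DEFAULT_PRE, post: int = DEFAULT_POST,
                window: tuple[int, int] = DEFAULT_WINDOW,
                clamp: tuple[float, float] = DEFAULT_CLAMP,
                polarity: str = "positive",
                min_prominence: float = DEFAULT_MIN_PROMINENCE) -> EventDelayResult:
    """Per-event lags between source events of ``x_i`` and peaks of ``x_j``.

    For each source crossing t: the source peak is the maximum of ``x_i``
    within the event window ``[t - pre, t + post]`` (parabola-refined
    unless it sits at the window edge); the target peak is the closest
    peak of ``x_j`` in ``[t + window[0], t + window[1]]``.  The lag is the
    difference of the refined peak times.  Edge-flagged target peaks give
    lags clamped to exactly ``clamp[0]`` or ``clamp[1]``.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    times = list(source_times)
    if not times:
        logger.warning("event_delay: no source events")
        return EventDelayResult(per_event=np.empty(0), mean=float("nan"),
                                n_edge_clamped=0)
    taus = []
    n_clamped = 0
    for t in times:
        s_lo, s_hi = t - pre, t + post
        p_s = s_lo + int(np.argmax(x_i[s_lo:s_hi + 1]))
        t_s = _refined_peak_time(x_i, p_s, s_lo, s_hi)
        peak = find_target_peak(x_j, t, window, polarity, reference=p_s,
                                min_prominence=min_prominence)
        if peak.edge is not None:
            taus.append(clamp[0] if peak.edge == "left" else clamp[1])
            n_clamped += 1
            continue
        w_lo = max(0, t + window[0])
        w_hi = min(len(x_j) - 1, t + window[1])
        x_ref = -x_j if polarity == "negative" else x_j
        t_t = _refined_peak_time(x_ref, peak.index, w_lo, w_hi)
        taus.append(t_t - t_s)
    per_event = np.asarray(taus, dtype=float)
    return EventDelayResult(per_event=per_event, mean=float(per_event.mean()),
                            n_edge_clamped=n_clamped)


def average_event_delay(x_i: np.ndarray, x_j: np.ndarray, source_times,
                        pre: int = DEFAULT_PRE, post: int = DEFAULT_POST,
                        window: tuple[int, int] = DEFAULT_WINDOW,
                        clamp: tuple[float, float] = DEFAULT_CLAMP,
                        min_prominence: float = DEFAULT_MIN_PROMINENCE) -> float:
    """Delay between the *average* source event and the average target event.

    Only events whose full target search window fits inside the scan
    contribute to the averages.  Peak finding and parabolic refinement
    then proceed exactly as for a single event, on the mean waveforms.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    T = len(x_i)
    times = [t for t in source_times
             if t - pre >= 0 and t + post <= T - 1
             and t + window[0] >= 0 and t + window[1] <= T - 1]
    if not times:
        logger.warning("average_event_delay: no fully-windowed events")
        return float("nan")
    src = np.mean([x_i[t - pre: t + post + 1] for t in times], axis=0)
    tgt = np.mean([x_j[t + window[0]: t + window[1] + 1] for t in times], axis=0)
    p_s = int(np.argmax(src))
    t_s = _refined_peak_time(src, p_s, 0, len(src) - 1) - pre
    peak = find_target_peak(tgt, -window[0], window,
                            reference=-window[0] + (p_s - pre),
                            min_prominence=min_prominence)
    if peak.edge is not None:
        return clamp[0] if peak.edge == "left" else clamp[1]
    t_t = _refined_peak_time(tgt, peak.index, 0, len(tgt) - 1) + window[0]
    return t_t - t_s


def delay_matrix(series: RoiTimeSeries, method: str = "event_lag",
                 max_lag: int = 10,
                 threshold: float = DEFAULT_THRESHOLD,
                 pre: int = DEFAULT_PRE, post: int = DEFAULT_POST,
                 window: tuple[int, int] = DEFAULT_WINDOW,
                 clamp: tuple[float, float] = DEFAULT_CLAMP,
                 min_prominence: float = DEFAULT_MIN_PROMINENCE,
                 store_per_event: bool = False) -> DelayMatrix:
    """Pairwise delay matrix under either estimator.

    ``pearson_lag`` fills the lower triangle with the negated upper
    triangle so the antisymmetry of the cross-covariance definition is
    exact in the output.  ``event_lag`` computes every ordered pair from
    that row's own source events; rows of regions without events are NaN.
    """
    series = _events._ensure_zscored(series)
    N = series.n_regions
    values = np.zeros((N, N))
    per_event: dict | None = {} if (store_per_event and method == "event_lag") else None

    if method == "pearson_lag":
        for i in range(N):
            for j in range(i + 1, N):
                tau = pearson_delay(series.data[:, i], series.data[:, j], max_lag)
                values[i, j] = tau
                values[j, i] = -tau
        return DelayMatrix(values, method, series.labels, series.tr,
                           convention=PEARSON_SIGN_CONVENTION)
    if method != "event_lag":
        raise ValueError("method must be 'pearson_lag' or 'event_lag'")

    eventsets = [detect_events(series, lab, threshold, pre, post)
                 for lab in series.labels]
    for i in range(N):
        if eventsets[i].n_events == 0:
            logger.warning("region %s has no events; delay row undefined",
                           series.labels[i])
            values[i, :] = np.nan
            continue
        for j in range(N):
            res = event_delay(series.data[:, i], series.data[:, j],
                              eventsets[i].crossing_times, pre, post,
                              window, clamp, min_prominence=min_prominence)
            values[i, j] = res.mean
            if per_event is not None:
                per_event[(series.labels[i], series.labels[j])] = res.per_event
    return DelayMatrix(values, method, series.labels, series.tr,
                       per_event=per_event, convention=EVENT_SIGN_CONVENTION)
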