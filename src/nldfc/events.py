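"""Detection and extraction of large-amplitude BOLD events.

An *event* is the stretch of signal around an upward crossing of an
amplitude threshold (in SD units of the z-scored signal).  The crossing
sample is the first sample at or above threshold: ``x[t-1] < theta <=
x[t]``.  Source events come from the seed region; target events are cut
from every other region at the *same* sample indices, which is what makes
the downstream correlation measures directional.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .signal_io import RoiTimeSeries, zscore

logger = logging.getLogger(__name__)

#: Default event window in TRs: 2 before the crossing, 4 after.
DEFAULT_PRE = 2
DEFAULT_POST = 4
DEFAULT_THRESHOLD = 1.0


@dataclass(frozen=True)
class EventSet:
    """Source-event timing for one region.

    ``crossing_times`` are strictly increasing 0-based sample indices of
    upward threshold crossings for which the full ``[t-pre, t+post]``
    window fits inside the scan.  ``dropped`` counts crossings discarded
    at the scan boundaries.
    """

    region: str
    crossing_times: tuple[int, ...]
    threshold: float
    pre: int
    post: int
    dropped: int = 0

    def __post_init__(self) -> None:
        times = tuple(int(t) for t in self.crossing_times)
        object.__setattr__(self, "crossing_times", times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("crossing times must be strictly increasing")
        if self.pre < 0 or self.post < 1:
            raise ValueError("pre must be >= 0 and post >= 1 TRs")

    @property
    def n_events(self) -> int:
        return len(self.crossing_times)

    def to_json(self) -> str:
        return json.dumps({
            "region": self.region,
            "threshold": self.threshold,
            "pre": self.pre,
            "post": self.post,
            "times": list(self.crossing_times),
            "dropped": self.dropped,
        })

    @classmethod
    def from_json(cls, text: str) -> "EventSet":
        d = json.loads(text)
        return cls(region=d["region"], crossing_times=tuple(d["times"]),
                   threshold=d["threshold"], pre=d["pre"], post=d["post"],
                   dropped=d.get("dropped", 0))


@dataclass(frozen=True)
class EventStack:
    """``K x W`` matrix of event segments, ``W = pre + post + 1``.

    ``kind`` is ``"source"`` when the rows come from the seed region
    itself (each row then reaches threshold at column ``pre``) and
    ``"target"`` when they were cut from another region at the seed's
    crossing times.
    """

    segments: np.ndarray
    kind: str
    source_region: str
    target_region: str
    pre: int
    post: int
    crossing_times: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seg = np.atleast_2d(np.asarray(self.segments, dtype=float))
        object.__setattr__(self, "segments", seg)
        if self.kind not in ("source", "target"):
            raise ValueError("kind must be 'source' or 'target'")
        if seg.size and seg.shape[1] != self.pre + self.post + 1:
            raise ValueError("segment width must equal pre + post + 1")

    @property
    def n_events(self) -> int:
        return self.segments.shape[0] if self.segments.size else 0

    @property
    def width(self) -> int:
        return self.pre + self.post + 1


def window_trs_from_seconds(pre_seconds: float, post_seconds: float,
                            tr: float) -> tuple[int, int]:
    """Convert a window given in seconds to TR counts (floor rounding)."""
    return math.floor(pre_seconds / tr), math.floor(post_seconds / tr)


def detect_crossings(x: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Return 0-based indices of upward threshold crossings of *x*.

    A crossing is the first sample at/above threshold:
    ``x[t-1] < threshold <= x[t]``, so the earliest possible crossing is
    ``t = 1``.  *x* is expected to be z-scored; the threshold is in SD
    units and must be positive.  An empty result is valid.
    """
    x = np.asarray(x, dtype=float)
    if not threshold > 0:
        raise ValueError("threshold must be > 0 SD")
    return np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1


def detect_events(series: RoiTimeSeries, region: str,
                  threshold: float = DEFAULT_THRESHOLD,
                  pre: int = DEFAULT_PRE, post: int = DEFAULT_POST) -> EventSet:
    """Detect a region's source events, keeping only full-window crossings."""
    series = _ensure_zscored(series)
    x = series.column(region)
    times = detect_crossings(x, threshold)
    T = series.n_timepoints
    keep = times[(times >= pre) & (times <= T - 1 - post)]
    dropped = len(times) - len(keep)
    if dropped:
        logger.info("region %s: dropped %d boundary crossing(s)", region, dropped)
    return EventSet(region=region, crossing_times=tuple(int(t) for t in keep),
                    threshold=threshold, pre=pre, post=post, dropped=dropped)


def extract_events(series: RoiTimeSeries, source_region: str,
                   crossing_times, pre: int, post: int,
                   target_region: str | None = None) -> EventStack:
    """Cut event segments from a region at the given crossing times.

    When ``target_region`` is ``None`` (or equal to ``source_region``)
    the rows are source events; otherwise they are target events cut from
    ``target_region`` at the source's times.  Crossings whose window does
    not fit inside ``[0, T-1]`` are dropped; the surviving times are
    recorded on the stack so target extraction reuses them verbatim.
    """
    series = _ensure_zscored(series)
    region = target_region if target_region is not None else source_region
    x = series.column(region)  # raises KeyError for unknown labels
    series.column(source_region)
    T = series.n_timepoints
    times = np.asarray(list(crossing_times), dtype=int)
    keep = times[(times >= pre) & (times <= T - 1 - post)]
    n_dropped = len(times) - len(keep)
    if n_dropped:
        logger.info("extract_events(%s): dropped %d out-of-bounds crossing(s)",
                    region, n_dropped)
    W = pre + post + 1
    if len(keep):
        segments = np.stack([x[t - pre: t + post + 1] for t in keep])
    else:
        segments = np.empty((0, W))
    kind = "source" if region == source_region else "target"
    return EventStack(segments=segments, kind=kind,
                      source_region=source_region, target_region=region,
                      pre=pre, post=post,
                      crossing_times=tuple(int(t) for t in keep))


def average_event(stack: EventStack) -> np.ndarray:
    """Column-wise mean waveform of an event stack (requires K >= 1)."""
    if stack.n_events == 0:
        raise ValueError("no events: cannot average an empty stack")
    return stack.segments.mean(axis=0)


def _ensure_zscored(series: RoiTimeSeries) -> RoiTimeSeries:
    if series.zscored:
        return series
    logger.info("input not flagged z-scored; z-scoring before thresholding")
    return zscore(series)
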