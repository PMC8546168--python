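"""Directed co-activation measures.

Two complementary views of directionality:

* correlation asymmetry — the event-correlation matrix minus its
  transpose, ``D(i, j) = r_E(i, j) - r_E(j, i)``, summed per pair, per
  region or globally;
* the shared-event ratio — the fraction of one region's source events at
  which the other region is simultaneously above threshold, in the spirit
  of point-process co-activation counting.

A thresholded-graph summary (clustering coefficient, characteristic path
length) is included for network-level inspection of any FC matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .correlations import FcMatrix
from .events import EventSet
from .signal_io import RoiTimeSeries
from . import events as _events

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AsymmetryResult:
    """Pairwise, per-region and global correlation asymmetry.

    ``pairwise`` is exactly antisymmetric (``D = -D.T``); consequently the
    per-region sums add to zero and the global sum over the complete
    matrix is zero.  Directional structure lives in the individual
    entries and in per-region contrasts, not in the complete-sum totals.
    """

    pairwise: np.ndarray
    per_region: np.ndarray
    global_sum: float
    labels: tuple[str, ...]
    n_excluded: int = 0


def asymmetry(fc: FcMatrix) -> AsymmetryResult:
    """Correlation asymmetry of an (event-method) FC matrix.

    Pairs with a missing (NaN) value in either direction are excluded
    from all sums; their count is reported.  A symmetric input yields
    zeros everywhere.
    """
    v = fc.values
    D = v - v.T
    missing = ~np.isfinite(D)
    n_excluded = int(np.count_nonzero(missing & ~np.eye(len(v), dtype=bool))) // 2
    if n_excluded:
        logger.warning("asymmetry: %d pair(s) excluded as undefined", n_excluded)
    Dz = np.where(missing, 0.0, D)
    per_region = Dz.sum(axis=1)
    # sum antisymmetric pairs together so the complete-matrix total is an
    # exact zero, not a summation-order residual
    global_sum = float((Dz + Dz.T).sum()) / 2.0
    return AsymmetryResult(pairwise=np.where(missing, np.nan, D),
                           per_region=per_region,
                           global_sum=global_sum,
                           labels=fc.labels, n_excluded=n_excluded)


def shared_event_ratio(series: RoiTimeSeries, source: str, target: str,
                       threshold: float = 1.0,
                       eventset: EventSet | None = None,
                       tolerance: int = 0) -> float:
    """Fraction of *source* events at which *target* is also above threshold.

    An event of the source region counts as shared when the target signal
    is at/above threshold at the source's crossing sample (or within
    ``tolerance`` TRs of it).  Not symmetric in (source, target).
    """
    series = _events._ensure_zscored(series)
    if eventset is None:
        eventset = _events.detect_events(series, source, threshold)
    if eventset.n_events == 0:
        logger.warning("shared_event_ratio: region %s has no events", source)
        return float("nan")
    x_t = series.column(target)
    T = len(x_t)
    n_shared = 0
    for t in eventset.crossing_times:
        lo, hi = max(0, t - tolerance), min(T - 1, t + tolerance)
        if np.any(x_t[lo:hi + 1] >= threshold):
            n_shared += 1
    return n_shared / eventset.n_events


def shared_event_matrix(series: RoiTimeSeries, threshold: float = 1.0,
                        tolerance: int = 0) -> FcMatrix:
    """N x N matrix of shared-event ratios (row = source, column = target)."""
    series = _events._ensure_zscored(series)
    N = series.n_regions
    values = np.full((N, N), np.nan)
    counts = []
    for i, src in enumerate(series.labels):
        ev = _events.detect_events(series, src, threshold)
        counts.append(ev.n_events)
        for j, tgt in enumerate(series.labels):
            values[i, j] = shared_event_ratio(series, src, tgt, threshold,
                                              eventset=ev, tolerance=tolerance)
    # ratios live in [0, 1]; reuse the FcMatrix container for I/O symmetry
    return FcMatrix(values, "event_mean", series.labels,
                    {"threshold": threshold, "tolerance": tolerance,
                     "kind": "shared_event_ratio"},
                    event_counts=tuple(counts))


def graph_summary(fc: FcMatrix, edge_threshold: float,
                  symmetrize: str = "max") -> dict:
    """Binary-graph metrics of the thresholded, symmetrised FC matrix.

    An undirected edge (i, j) exists when the symmetrised absolute
    correlation is >= ``edge_threshold``.  Symmetrisation takes the
    element-wise max of |values| and its transpose (``symmetrize="max"``)
    or their mean (``"mean"``).  Path length is averaged over connected
    pairs only; the disconnected-pair count is reported.
    """
    if not -1 < edge_threshold < 1:
        raise ValueError("edge_threshold must lie in (-1, 1)")
    a = np.abs(fc.values)
    a = np.where(np.isfinite(a), a, -np.inf)
    if symmetrize == "max":
        w = np.maximum(a, a.T)
    elif symmetrize == "mean":
        w = (a + a.T) / 2.0
    else:
        raise ValueError("symmetrize must be 'max' or 'mean'")
    np.fill_diagonal(w, -np.inf)
    adj = w >= edge_threshold
    G = nx.from_numpy_array(adj.astype(int))
    G.remove_edges_from([(u, v) for u, v, d in G.edges(data=True)
                         if d.get("weight", 1) == 0])
    n = G.number_of_nodes()
    report: dict = {"n_nodes": n, "n_edges": G.number_of_edges(),
                    "edge_threshold": edge_threshold}
    if G.number_of_edges() == 0:
        logger.warning("graph_summary: empty graph at threshold %.3g",
                       edge_threshold)
        report.update(avg_path_length=None, clustering_coefficient=None,
                      n_disconnected_pairs=n * (n - 1) // 2)
        return report
    report["clustering_coefficient"] = nx.average_clustering(G)
    dists = [d for _, targets in nx.all_pairs_shortest_path_length(G)
             for t, d in targets.items() if d > 0]
    n_connected_pairs = len(dists) // 2
    report["avg_path_length"] = float(np.mean(dists)) if dists else None
    report["n_disconnected_pairs"] = n * (n - 1) // 2 - n_connected_pairs
    return report
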