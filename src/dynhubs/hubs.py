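"""Hub detection from time-varying connectivity.

Each time point's connectivity matrix becomes an undirected graph by
proportional thresholding (the top ``density`` fraction of edges, ties at
the cutoff retained, then binarized), the standard practice for keeping
edge density comparable across time points and subjects. Normalized
betweenness centrality (BC) is computed per node and time point,

    BC_n = 2 / ((N-1)(N-2)) * sum over unordered pairs (h, j), h,j != n of
           sigma_hj(n) / sigma_hj,

where sigma_hj counts shortest paths between h and j and sigma_hj(n) those
through n; pairs with no connecting path contribute 0. Two thresholds then
define hubs:

* **TH1** (candidate hubs): across-node mean of time-averaged BC plus one
  across-node sample SD; nodes strictly above are candidates.
* **TH2** (active hubs): per candidate, its own time-mean BC plus one
  across-time sample SD; the candidate is *active* at the time points where
  its BC strictly exceeds TH2.

Connectivity values for graph construction come in three modes:

* ``"local"`` (default) — windowed jackknife pseudo-correlation:
  r_full + (T-1) * (moving average of the JC deviation from its time
  mean). This is an unbiased estimate of the *time-local* Pearson
  correlation (the classical jackknife pseudo-value, averaged over a
  short window to tame single-sample noise), so graphs retain the static
  network scaffold while tracking connectivity-state dynamics with the
  correct sign.
* ``"normalized"`` — the per-edge z-scored JC series as-is (its z-scores
  rise with instantaneous positive coupling); every edge then has mean 0
  and SD 1 over time, which erases all static structure from the graphs.
* ``"raw"`` — the raw JC negated (the JC definition negates the static
  correlation level), i.e. the leave-one-out Pearson correlation; graphs
  are then essentially static, since a single deleted time point moves
  the correlation only by O(1/T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import igraph as ig
import numpy as np

from .errors import InvalidInputError
from .regions import RegionTable
from .tvc import TVCStack


@dataclass(frozen=True)
class AdjacencyStack:
    """Binary T x N x N adjacency stack at a fixed edge density."""

    adjacency: np.ndarray  # T x N x N, uint8
    density: float


@dataclass(frozen=True)
class BCTimeSeries:
    """Normalized betweenness centrality, nodes x time, each value in [0, 1]."""

    values: np.ndarray  # N x T

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def t_total(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BCSummary:
    """Node/global/RSN BC aggregates and the candidate-hub threshold TH1."""

    bc_avg: np.ndarray  # length N
    bc_global: float
    bc_rsn: dict[str, float]
    th1: float
    region_table: RegionTable


@dataclass(frozen=True)
class HubActivity:
    """Candidate-hub set, per-candidate TH2 and the binary activity matrix.

    `candidates` are 0-based node positions; `activity[n, t] == 1` iff node
    n is a candidate and its BC at t strictly exceeds its TH2.
    """

    candidates: tuple[int, ...]
    th2: dict[int, float]
    activity: np.ndarray  # N x T, uint8

    @property
    def t_total(self) -> int:
        return self.activity.shape[1]


GRAPH_VALUE_MODES = ("local", "normalized", "raw")


def _edge_value_series(
    stack: TVCStack, values: str, window: int, dynamic_gain: float = 0.5
) -> np.ndarray:
    """T x n_edges connectivity-value series on the upper triangle.

    For the "local" mode the windowed pseudo-value deviation is an
    unbiased but noisy estimate of the time-local departure from the
    static correlation; it enters shrunk by `dynamic_gain` toward the
    static value, trading a little dynamic amplitude for a much cleaner
    network scaffold.
    """
    n = stack.n_regions
    iu = np.triu_indices(n, k=1)
    raw = stack.raw[:, iu[0], iu[1]]  # T x E
    if values == "normalized":
        series = stack.normalized[:, iu[0], iu[1]]
    elif values == "raw":
        # the JC definition negates the static correlation level
        series = -raw
    elif values == "local":
        mean_raw = raw.mean(axis=0)
        r_full = -mean_raw
        series = r_full[None, :] + (
            dynamic_gain * (stack.t_total - 1)
        ) * (raw - mean_raw)
    else:
        raise InvalidInputError(
            f"values must be one of {GRAPH_VALUE_MODES}, got {values!r}"
        )
    return _smooth_time(series, window)


def _smooth_time(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over time (axis 0); window shrinks at the
    boundaries. window=1 is the identity."""
    if window <= 1:
        return values
    t_total = values.shape[0]
    half = window // 2
    cum = np.cumsum(values, axis=0)
    out = np.empty_like(values)
    for t in range(t_total):
        lo = max(0, t - half)
        hi = min(t_total - 1, t + half)
        seg = cum[hi] - (cum[lo - 1] if lo > 0 else 0)
        out[t] = seg / (hi - lo + 1)
    return out


def binarize_stack(
    stack: TVCStack,
    density: float = 0.15,
    values: str = "local",
    smoothing_window: int = 21,
    dynamic_gain: float = 0.5,
) -> AdjacencyStack:
    """Proportional-threshold each time slice into a binary graph.

    Per time point, edges are ranked by connectivity value (see module
    docstring for the three `values` modes) and the top `density` fraction
    retained (k = round(density * N(N-1)/2), at least 1); all edges tied
    with the cutoff value are kept. Emits a warning (and keeps the slice)
    if a slice ends up with no edges.

    Before ranking, the value series of every edge is averaged over a
    centered `smoothing_window` of time points (default 21). A single
    deleted time point perturbs the jackknife correlation by an amount
    dominated by that one sample's co-fluctuation, so unsmoothed per-point
    values rank edges almost entirely by single-sample noise; the moving
    average estimates the time-local coupling instead while staying
    shorter than typical connectivity-state dwell times.
    `smoothing_window=1` gives the literal per-point graphs.
    """
    if not (0 < density < 1):
        raise InvalidInputError("density must lie strictly between 0 and 1")
    if smoothing_window < 1:
        raise InvalidInputError("smoothing_window must be >= 1")
    t_total, n = stack.raw.shape[0], stack.raw.shape[1]
    iu = np.triu_indices(n, k=1)
    n_edges = iu[0].size
    k = max(1, int(np.floor(density * n_edges + 0.5)))
    adjacency = np.zeros((t_total, n, n), dtype=np.uint8)
    series = _edge_value_series(stack, values, smoothing_window, dynamic_gain)
    for t in range(t_total):
        vals = series[t]
        if k < 1:
            warnings.warn(f"time point {t}: density {density} retains no edges")
            continue
        cutoff = np.partition(vals, n_edges - k)[n_edges - k]
        keep = vals >= cutoff
        a = adjacency[t]
        a[iu[0][keep], iu[1][keep]] = 1
        a |= a.T
    return AdjacencyStack(adjacency=adjacency, density=density)


def betweenness_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Normalized BC of every node of one binary undirected graph.

    Values lie in [0, 1]; unordered node pairs excluding the node itself,
    disconnected pairs contribute 0. N >= 3 required (the normalization is
    undefined below that).
    """
    a = np.asarray(adjacency)
    n = a.shape[0]
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidInputError("adjacency must be square")
    if n < 3:
        raise InvalidInputError("betweenness normalization needs N >= 3")
    if np.any(a != a.T) or np.any(np.diag(a) != 0):
        raise InvalidInputError("adjacency must be symmetric with zero diagonal")
    edges = np.argwhere(np.triu(a, k=1) > 0)
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    bc = np.asarray(g.betweenness(directed=False), dtype=float)
    return bc * (2.0 / ((n - 1) * (n - 2)))


def weighted_betweenness_centrality(values: np.ndarray) -> np.ndarray:
    """Weighted-graph variant: shortest paths on lengths 1/value over
    strictly positive connectivity values (non-default mode)."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    if n < 3:
        raise InvalidInputError("betweenness normalization needs N >= 3")
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if v[i, j] > 0:
                edges.append((i, j))
                weights.append(1.0 / v[i, j])
    g = ig.Graph(n=n, edges=edges, directed=False)
    bc = np.asarray(g.betweenness(weights=weights, directed=False), dtype=float)
    return bc * (2.0 / ((n - 1) * (n - 2)))


def bc_time_series(adjstack: AdjacencyStack) -> BCTimeSeries:
    """BC of every node at every time point (column t = slice t's BC)."""
    t_total = adjstack.adjacency.shape[0]
    n = adjstack.adjacency.shape[1]
    values = np.empty((n, t_total))
    for t in range(t_total):
        values[:, t] = betweenness_centrality(adjstack.adjacency[t])
    return BCTimeSeries(values=values)


def summarize_bc(bcts: BCTimeSeries, region_table: RegionTable) -> BCSummary:
    """Time-averaged, global and per-RSN BC plus the TH1 threshold.

    TH1 = across-node mean of bc_avg + across-node sample SD (ddof=1).
    """
    if bcts.n_regions != region_table.n_regions:
        raise InvalidInputError(
            f"BC has {bcts.n_regions} nodes but region table has "
            f"{region_table.n_regions} regions"
        )
    if bcts.t_total < 2:
        raise InvalidInputError("BC summary needs T >= 2 time points")
    bc_avg = bcts.values.mean(axis=1)
    bc_global = float(bc_avg.mean())
    bc_rsn = {
        label: float(bc_avg[region_table.members(label)].mean())
        for label in region_table.rsn_labels
    }
    th1 = float(bc_avg.mean() + bc_avg.std(ddof=1))
    return BCSummary(
        bc_avg=bc_avg,
        bc_global=bc_global,
        bc_rsn=bc_rsn,
        th1=th1,
        region_table=region_table,
    )


def find_candidate_hubs(summary: BCSummary, multiplier: float = 1.0) -> tuple[int, ...]:
    """Nodes whose time-averaged BC strictly exceeds mean + multiplier * SD.

    With the default multiplier this is exactly the TH1 rule; larger
    multipliers give strictly stricter candidate sets. Returns sorted
    0-based node positions.
    """
    bc_avg = summary.bc_avg
    threshold = float(bc_avg.mean() + multiplier * bc_avg.std(ddof=1))
    return tuple(int(i) for i in np.flatnonzero(bc_avg > threshold))


def find_active_hubs(
    bcts: BCTimeSeries, candidates: Iterable[int]
) -> HubActivity:
    """Binary activity of candidate hubs over time (TH2 rule).

    TH2(n) = time-mean of BC_n + across-time sample SD (ddof=1); node n is
    active at t iff it is a candidate and BC_n(t) > TH2(n) strictly.
    """
    if bcts.t_total < 2:
        raise InvalidInputError("active-hub detection needs T >= 2 time points")
    candidates = tuple(sorted(int(c) for c in candidates))
    if candidates and (candidates[0] < 0 or candidates[-1] >= bcts.n_regions):
        raise InvalidInputError("candidate indices out of range")
    activity = np.zeros(bcts.values.shape, dtype=np.uint8)
    th2: dict[int, float] = {}
    for n in candidates:
        series = bcts.values[n]
        thr = float(series.mean() + series.std(ddof=1))
        th2[n] = thr
        activity[n] = (series > thr).astype(np.uint8)
    return HubActivity(candidates=candidates, th2=th2, activity=activity)


def consensus_candidates(
    candidate_sets: Sequence[Iterable[int]], fraction: float = 0.5
) -> tuple[int, ...]:
    """Group-level candidate map: nodes that are candidates in strictly more
    than `fraction` of the subjects."""
    if not candidate_sets:
        return ()
    if not (0 <= fraction < 1):
        raise InvalidInputError("consensus fraction must lie in [0, 1)")
    counts: dict[int, int] = {}
    for cs in candidate_sets:
        for n in set(int(c) for c in cs):
            counts[n] = counts.get(n, 0) + 1
    cut = fraction * len(candidate_sets)
    return tuple(sorted(n for n, c in counts.items() if c > cut))
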