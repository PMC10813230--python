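"""Spatial and temporal organization of active hubs.

Four complementary views of a subject's binary activity matrix A (nodes x
time, from :class:`dynhubs.hubs.HubActivity`):

* **SND** — subnetwork distribution: the share of active-hub events
  (node-time pairs with A = 1) falling in each RSN.
* **SO** — spatial overlap: Jaccard index between the active-hub sets of
  two time points; time points with an empty active set are invalid-masked
  (their Jaccard is 0/0).
* clustering of the SO matrix — agglomerative average-linkage on the
  distance d = 1 - SO, cut at a configurable height (default 0.90 on the
  distance scale), recovers the recurring ("quasi-periodic") spatial
  patterns; singleton clusters are permitted.
* **TO** — temporal overlap: for a candidate pair, the fraction of all
  time points at which both are simultaneously active; the diagonal holds
  each candidate's own active-time fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InvalidInputError, UndefinedResultError
from .hubs import HubActivity
from .regions import RegionTable


@dataclass(frozen=True)
class SNDVector:
    """Active-hub share per RSN; sums to 1 unless `empty` (no events)."""

    proportions: dict[str, float]
    empty: bool


@dataclass(frozen=True)
class SpatialOverlapMatrix:
    """T x T Jaccard overlap of active-hub sets, with a validity mask."""

    so: np.ndarray  # T x T in [0, 1]
    valid_mask: np.ndarray  # length T, bool


@dataclass(frozen=True)
class ClusterResult:
    """Flat clustering of the valid time points' spatial patterns."""

    labels: np.ndarray  # cluster id per valid time point
    valid_timepoints: np.ndarray  # indices of valid time points
    linkage_tree: np.ndarray  # scipy linkage matrix
    cut_height: float
    n_clusters: int
    singleton_count: int


@dataclass(frozen=True)
class TemporalOverlapMatrix:
    """Pairwise co-activity fractions over the candidate hubs."""

    to: np.ndarray  # C x C in [0, 1]
    candidates: tuple[int, ...]  # 0-based node positions, row/col order


def subnetwork_distribution(
    activity: HubActivity | Sequence[HubActivity], region_table: RegionTable
) -> SNDVector:
    """Share of active-hub events per RSN.

    Accepts one subject's activity or a sequence of them; for a sequence
    the event counts are pooled over subjects before normalizing.
    """
    acts = [activity] if isinstance(activity, HubActivity) else list(activity)
    if not acts:
        raise InvalidInputError("no activity matrices given")
    n = region_table.n_regions
    counts = np.zeros(n)
    for a in acts:
        if a.activity.shape[0] != n:
            raise InvalidInputError("activity size does not match region table")
        counts += a.activity.sum(axis=1)
    total = counts.sum()
    labels = region_table.rsn_labels
    if total == 0:
        return SNDVector(proportions={r: 0.0 for r in labels}, empty=True)
    props = {
        r: float(counts[region_table.members(r)].sum() / total) for r in labels
    }
    return SNDVector(proportions=props, empty=False)


def spatial_overlap(activity: HubActivity) -> SpatialOverlapMatrix:
    """Jaccard overlap between active-hub sets of every pair of time points.

    Pairs whose union is empty get 0; time points with an empty active set
    are marked invalid in the mask.
    """
    a = activity.activity.astype(np.int64)
    inter = a.T @ a  # T x T
    sizes = a.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        so = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    valid = sizes > 0
    return SpatialOverlapMatrix(so=so, valid_mask=valid)


def mean_spatial_overlap(som: SpatialOverlapMatrix) -> float:
    """Mean SO over the strict upper triangle of the valid time points."""
    idx = np.flatnonzero(som.valid_mask)
    if idx.size < 2:
        raise UndefinedResultError(
            f"mean spatial overlap needs >= 2 valid time points, got {idx.size}"
        )
    sub = som.so[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def cluster_spatial_patterns(
    som: SpatialOverlapMatrix,
    cut_height: float = 0.90,
    cut_scale: str = "distance",
) -> ClusterResult:
    """Average-linkage clustering of spatial patterns on d = 1 - SO.

    `cut_scale` selects whether `cut_height` is a distance (default; the
    tree is cut at that merge height) or a similarity (the cut becomes
    1 - cut_height). Invalid time points are excluded; singletons count
    as clusters. The default cut of 0.90 follows the threshold the hub
    literature reports, interpreted on the distance scale: cutting at
    similarity 0.90 instead would shatter realistic activity patterns
    into near-singletons (see the methods note).
    """
    if cut_scale not in ("distance", "similarity"):
        raise InvalidInputError("cut_scale must be 'distance' or 'similarity'")
    if not (0 < cut_height < 1):
        raise InvalidInputError("cut_height must lie strictly between 0 and 1")
    idx = np.flatnonzero(som.valid_mask)
    if idx.size < 2:
        raise UndefinedResultError(
            f"clustering needs >= 2 valid time points, got {idx.size}"
        )
    d = 1.0 - som.so[np.ix_(idx, idx)]
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    tree = linkage(condensed, method="average")
    cut = cut_height if cut_scale == "distance" else 1.0 - cut_height
    labels = fcluster(tree, t=cut, criterion="distance")
    uniq, counts = np.unique(labels, return_counts=True)
    return ClusterResult(
        labels=labels,
        valid_timepoints=idx,
        linkage_tree=tree,
        cut_height=float(cut),
        n_clusters=int(uniq.size),
        singleton_count=int((counts == 1).sum()),
    )


def temporal_overlap(activity: HubActivity) -> TemporalOverlapMatrix:
    """Fraction of all time points at which candidate pairs are co-active.

    The diagonal holds each candidate's own active-time fraction; the
    denominator is always the full recording length.
    """
    if not activity.candidates:
        raise InvalidInputError("temporal overlap needs >= 1 candidate hub")
    rows = activity.activity[list(activity.candidates)].astype(np.int64)
    t_total = activity.t_total
    inter = rows @ rows.T
    return TemporalOverlapMatrix(
        to=inter / t_total, candidates=activity.candidates
    )


def top_pairs(
    tom: TemporalOverlapMatrix,
    k: int | None = None,
    fraction: float | None = None,
) -> list[tuple[int, int, float]]:
    """Off-diagonal candidate pairs ranked by temporal overlap.

    Returns (node_i, node_j, to) with node_i < node_j (0-based positions),
    sorted by descending overlap; ties broken by (smaller i, smaller j).
    Exactly one of `k` / `fraction` selects how many pairs to keep
    (fraction f keeps ceil(f * n_pairs)).
    """
    c = len(tom.candidates)
    if c < 2:
        raise InvalidInputError("need at least one off-diagonal candidate pair")
    pairs = []
    for a in range(c):
        for b in range(a + 1, c):
            pairs.append(
                (tom.candidates[a], tom.candidates[b], float(tom.to[a, b]))
            )
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    if (k is None) == (fraction is None):
        raise InvalidInputError("give exactly one of k or fraction")
    if fraction is not None:
        if not (0 < fraction <= 1):
            raise InvalidInputError("fraction must lie in (0, 1]")
        k = int(np.ceil(fraction * len(pairs)))
    return pairs[: int(k)]
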