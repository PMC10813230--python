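"""Time-varying connectivity via jackknife correlation (JC).

The JC estimate of the coupling of two signals x, y *at* time point t is
the negative of their Pearson correlation computed with time point t
deleted. Deleting a point that carries strong positive co-fluctuation
lowers the leave-one-out correlation, so the sign flip makes the JC series
rise exactly at the moments an edge is strongly engaged; the static
correlation level enters only as a (negated) offset, which the per-edge
z-scoring removes.

For an N-region recording the full stack is a T x N x N array per subject,
stored both raw and per-edge z-scored over time ("normalized").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, InvalidInputError
from .synthetic import ParcellatedTimeSeries

# Absolute floor below which a leave-one-out variance counts as zero,
# relative to the series' mean square.
_VAR_RTOL = 1e-12


@dataclass(frozen=True)
class TVCStack:
    """Per-time-point symmetric JC connectivity matrices.

    `raw[t]` holds the JC values (Pearson correlation with point t deleted,
    negated); `normalized[t]` holds the per-edge z-score of the raw series
    over time (mean 0, sample SD 1 per edge; all-zero for constant edges).
    Diagonals are 0 by convention.
    """

    raw: np.ndarray  # T x N x N
    normalized: np.ndarray  # T x N x N
    t_total: int

    @property
    def n_regions(self) -> int:
        return self.raw.shape[1]


def _loo_moments(x: np.ndarray):
    """Leave-one-out sums for one series: returns (S, SS) full sums."""
    return x.sum(), (x * x).sum()


def jackknife_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raw JC series of two signals.

    Element t is the NEGATIVE of the Pearson correlation of x and y with
    time point t deleted. Raises :class:`DegenerateSignalError` if any
    deleted-point subseries is constant, :class:`InvalidInputError` if
    T < 3 or shapes differ.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidInputError("x and y must have equal length")
    t_total = x.size
    if t_total < 3:
        raise InvalidInputError(f"JC needs T >= 3 time points, got {t_total}")
    sx, sxx = _loo_moments(x)
    sy, syy = _loo_moments(y)
    sxy = (x * y).sum()
    m = t_total - 1
    # Deleted-point sums, vectorized over t.
    sx_t = sx - x
    sy_t = sy - y
    var_x = (sxx - x * x) - sx_t * sx_t / m
    var_y = (syy - y * y) - sy_t * sy_t / m
    cov = (sxy - x * y) - sx_t * sy_t / m
    tol_x = _VAR_RTOL * max(1.0, sxx)
    tol_y = _VAR_RTOL * max(1.0, syy)
    bad = np.flatnonzero((var_x <= tol_x) | (var_y <= tol_y))
    if bad.size:
        t = int(bad[0])
        raise DegenerateSignalError(
            f"zero variance after deleting time point {t}", timepoint=t
        )
    return -cov / np.sqrt(var_x * var_y)


def _normalize_stack(raw: np.ndarray) -> np.ndarray:
    """Per-edge z-score over time; constant edges map to all-zero series."""
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - mean) / sd
    return np.where(np.broadcast_to(sd == 0, raw.shape), 0.0, z)


def tvc_stack(ts: ParcellatedTimeSeries) -> TVCStack:
    """Compute the full raw + normalized JC stack for one subject.

    Vectorized over all unordered region pairs; equivalent to calling
    :func:`jackknife_correlation` per pair. Degenerate edges raise
    :class:`DegenerateSignalError` naming the edge and time point.
    """
    x = np.asarray(ts.data, dtype=float)
    t_total, n = x.shape
    if t_total < 3:
        raise InvalidInputError(f"JC needs T >= 3 time points, got {t_total}")
    m = t_total - 1
    s = x.sum(axis=0)  # N
    ss = (x * x).sum(axis=0)  # N
    gram = x.T @ x  # N x N
    raw = np.empty((t_total, n, n))
    tol = _VAR_RTOL * np.maximum(1.0, ss)
    for t in range(t_total):
        xt = x[t]
        s_t = s - xt
        var_t = (ss - xt * xt) - s_t * s_t / m
        bad = np.flatnonzero(var_t <= tol)
        if bad.size:
            j = int(bad[0])
            raise DegenerateSignalError(
                f"region {j + 1} ({ts.region_table.region_name[j]}): zero variance "
                f"after deleting time point {t}",
                edge=(j,),
                timepoint=t,
            )
        cov_t = (gram - np.outer(xt, xt)) - np.outer(s_t, s_t) / m
        denom = np.sqrt(np.outer(var_t, var_t))
        raw[t] = -cov_t / denom
        np.fill_diagonal(raw[t], 0.0)
    normalized = _normalize_stack(raw)
    # Restore exact symmetry and zero diagonals after z-scoring.
    normalized = 0.5 * (normalized + normalized.transpose(0, 2, 1))
    for t in range(t_total):
        np.fill_diagonal(normalized[t], 0.0)
    return TVCStack(raw=raw, normalized=normalized, t_total=t_total)
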