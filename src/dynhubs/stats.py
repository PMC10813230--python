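"""Group comparison of derived metrics.

Independent two-sample t-tests (Student pooled-variance by default, Welch
behind a flag) with Benjamini-Hochberg step-up FDR adjustment. The BH
procedure is implemented from its definition: with ordered p-values
p_(1) <= ... <= p_(m), the adjusted value for rank i is
min_{j >= i} (m * p_(j) / j), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedResultError


@dataclass(frozen=True)
class GroupStatsResult:
    """One group comparison: test statistic, raw and FDR-adjusted p-value."""

    metric_name: str
    level: str  # 'global' | 'rsn' | 'node'
    unit: str  # which RSN / node, or 'whole-brain'
    group_means: tuple[float, float]  # (NC, SZ)
    t_statistic: float
    p_value: float
    p_fdr: float
    significant: bool


def independent_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_variance: bool = True,
) -> tuple[float, float]:
    """Two-sided independent two-sample t-test.

    Student's pooled-variance test by default; Welch when
    `equal_variance=False`. Both samples need >= 2 values. Zero variance in
    both samples with equal means makes the statistic undefined.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each sample needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("samples must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise UndefinedResultError(
                "t-test undefined: zero variance in both samples with equal means"
            )
        # Degenerate but directional: infinite separation.
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), 0.0
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (hand implementation).

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; invariant to
    input order and monotone in the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # Running minimum from the largest rank down.
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def compare_groups(
    values_nc: dict[str, Sequence[float]],
    values_sz: dict[str, Sequence[float]],
    metric_name: str,
    level: str,
    alpha: float = 0.05,
    equal_variance: bool = True,
    adjust: bool | None = None,
) -> list[GroupStatsResult]:
    """Compare per-subject metric values between groups, unit by unit.

    `values_nc` / `values_sz` map unit label (e.g. RSN name, or
    'whole-brain') to that group's per-subject values. All units form one
    FDR family when `adjust` is true (default: adjust iff more than one
    unit). Significance is judged on the adjusted value when adjusted,
    else on the raw p.
    """
    units = list(values_nc)
    if set(units) != set(values_sz):
        raise InvalidInputError("groups carry different unit labels")
    if adjust is None:
        adjust = len(units) > 1
    raw = []
    for u in units:
        t, p = independent_t_test(values_nc[u], values_sz[u], equal_variance)
        raw.append((u, t, p))
    p_adj = bh_fdr([r[2] for r in raw]) if adjust else np.array([r[2] for r in raw])
    out = []
    for (u, t, p), pf in zip(raw, p_adj):
        out.append(
            GroupStatsResult(
                metric_name=metric_name,
                level=level,
                unit=u,
                group_means=(
                    float(np.mean(values_nc[u])),
                    float(np.mean(values_sz[u])),
                ),
                t_statistic=t,
                p_value=p,
                p_fdr=float(pf),
                significant=bool(pf < alpha),
            )
        )
    return out
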