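"""Independent reference implementations used only by the tests.

Each oracle is deliberately naive — per-point loops, exhaustive path
enumeration, textbook formulas — and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.special import betainc
from scipy.stats import pearsonr


def naive_jackknife(x, y):
    """Leave-one-out Pearson loop: element t = -corr(x, y with t deleted)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.empty(x.size)
    for t in range(x.size):
        xt = np.delete(x, t)
        yt = np.delete(y, t)
        out[t] = -pearsonr(xt, yt).statistic
    return out


def brute_force_bc(adjacency):
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    g = nx.from_numpy_array(a)
    bc = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            try:
                paths = list(nx.all_shortest_paths(g, h, j))
            except nx.NetworkXNoPath:
                continue
            sigma = len(paths)
            for node in range(n):
                if node in (h, j):
                    continue
                through = sum(1 for p in paths if node in p[1:-1])
                bc[node] += through / sigma
    return bc * 2.0 / ((n - 1) * (n - 2))


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t and two-sided p (incomplete beta)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return float(t), float(p)


def bh_oracle(p):
    """Step-up BH by direct definition: adj_i = min_{p_j >= p_i} m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        vals = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(vals))
    return out
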