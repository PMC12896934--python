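"""Independent reference implementations used only to check the package.

Each oracle re-derives a statistic from first principles (closed forms,
exact big-integer combinatorics, brute-force enumeration) without calling
the code path it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import stats


def welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Welch t-test: t statistic plus Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (y.mean() - x.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini–Hochberg step-up with monotonization."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        idx = order[pos]
        running_min = min(running_min, p[idx] * m / (pos + 1))
        adj[idx] = running_min
    return adj


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r from the covariance formula; p from t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, 2.0 * stats.t.sf(abs(t), n - 2)


def tukey_pairwise_p(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tukey(-Kramer) pairwise p via one-way ANOVA MSE + studentized range."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (n_total - k)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            se = math.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
            q = abs(a.mean() - b.mean()) / se
            out[(names[i], names[j])] = float(
                stats.studentized_range.sf(q, k, n_total - k)
            )
    return out


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) for Hypergeometric(N, K, n) in rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return acc


def node_degrees(edges: list[tuple[str, str]], nodes: set[str]) -> dict[str, int]:
    """Degree of every node in the induced subgraph, by direct edge counting."""
    canon = {tuple(sorted(e)) for e in edges if e[0] != e[1]}
    deg = {v: 0 for v in nodes}
    for a, b in canon:
        if a in nodes and b in nodes:
            deg[a] += 1
            deg[b] += 1
    return deg
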