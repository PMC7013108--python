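"""Independent reference implementations used only by the tests.

These deliberately use the most transparent algorithm available (quadratic
brute force, closed forms) so they stay independent of the production code
paths they verify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_edges(
    intervals: pd.DataFrame,
    window: tuple,
    min_overlap: float = 1.0,
) -> tuple[set, dict]:
    """All-pairs interval intersection per box, O(n^2).

    Returns the edge set (frozenset pairs) and the per-pair total overlap
    seconds over qualifying intersections.
    """
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    edges: set = set()
    seconds: dict = {}
    t0 = intervals["t_start"].clip(lower=w0)
    t1 = intervals["t_end"].clip(upper=w1)
    keep = t0 < t1
    sub = pd.DataFrame(
        {
            "tag": intervals.loc[keep, "tag_id"],
            "box": intervals.loc[keep, "box_id"],
            "t0": t0[keep],
            "t1": t1[keep],
        }
    ).reset_index(drop=True)
    for i in range(len(sub)):
        for j in range(i + 1, len(sub)):
            if sub.at[i, "box"] != sub.at[j, "box"] or sub.at[i, "tag"] == sub.at[j, "tag"]:
                continue
            ov = (
                min(sub.at[i, "t1"], sub.at[j, "t1"])
                - max(sub.at[i, "t0"], sub.at[j, "t0"])
            ).total_seconds()
            if ov >= min_overlap:
                pair = frozenset((sub.at[i, "tag"], sub.at[j, "tag"]))
                edges.add(pair)
                seconds[pair] = seconds.get(pair, 0.0) + ov
    return edges, seconds


def rank_then_pearson(x, y) -> float:
    """Spearman rho computed literally: mid-rank both vectors, Pearson them."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sv = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def pairwise_dispersion(resid) -> float:
    """Wilcoxon-score Jaeckel dispersion via the pairwise-difference identity."""
    e = np.asarray(resid, dtype=float)
    n = e.size
    i, j = np.triu_indices(n, 1)
    return float(np.sqrt(12.0) / (2.0 * (n + 1)) * np.abs(e[i] - e[j]).sum())


def classical_drop_f(X: np.ndarray, y: np.ndarray, col: int) -> tuple[float, float]:
    """Ordinary least-squares drop-one-column F test (with intercept)."""
    from scipy.stats import f as fdist

    n = y.size
    X1 = np.column_stack([np.ones(n), X])
    Xr = np.column_stack([np.ones(n), np.delete(X, col, axis=1)])

    def rss(M):
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        r = y - M @ beta
        return float(r @ r)

    rss_full, rss_red = rss(X1), rss(Xr)
    df2 = n - X1.shape[1]
    fstat = (rss_red - rss_full) / (rss_full / df2)
    return fstat, float(fdist.sf(fstat, 1, df2))
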