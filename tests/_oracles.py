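"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: quantile
normalization by explicit sort/average/reassign, and a profiled
grid-search maximum-likelihood fit for the two-component mixture.
"""

from __future__ import annotations

import numpy as np


def quantile_normalize_bruteforce(values: np.ndarray) -> np.ndarray:
    """Sort each column, average rank-wise, reassign by rank (midrank ties)."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(p, dtype=int)
        ranks[order] = np.arange(p)
        for i in range(p):
            tied = np.flatnonzero(col == col[i])
            out[i, j] = reference[np.sort(ranks[tied])].mean()
    return out


def gmm_grid_search_mle(
    x: np.ndarray,
    step: float = 0.1,
    profile_iters: int = 40,
    var_floor: float = 1e-4,
) -> tuple[float, float]:
    """Profiled grid-search MLE for the two component means.

    The low mean scans [q05, q40] and the high mean [q60, q95] of the data
    on a regular grid; at each grid point the weights and variances are
    profiled out by fixed-mean EM iterations, and the pair with the best
    profiled log likelihood wins.  Independent of the package's EM (the
    means being checked come from exhaustive search, never from EM mean
    updates).
    """
    x = np.asarray(x, dtype=float)
    q05, q40, q60, q95 = np.quantile(x, [0.05, 0.40, 0.60, 0.95])
    m1s = np.arange(q05, q40 + step, step)
    m2s = np.arange(q60, q95 + step, step)
    M1, M2 = np.meshgrid(m1s, m2s, indexing="ij")
    m1, m2 = M1.ravel(), M2.ravel()
    g = m1.size
    w = np.full(g, 0.5)
    v1 = np.full(g, x.var())
    v2 = v1.copy()
    lse = None
    for _ in range(profile_iters):
        l1 = (
            np.log(w)[:, None]
            - 0.5 * np.log(2 * np.pi * v1)[:, None]
            - 0.5 * (x[None, :] - m1[:, None]) ** 2 / v1[:, None]
        )
        l2 = (
            np.log(1 - w)[:, None]
            - 0.5 * np.log(2 * np.pi * v2)[:, None]
            - 0.5 * (x[None, :] - m2[:, None]) ** 2 / v2[:, None]
        )
        mx = np.maximum(l1, l2)
        lse = mx + np.log(np.exp(l1 - mx) + np.exp(l2 - mx))
        r1 = np.exp(l1 - lse)
        n1 = np.maximum(r1.sum(axis=1), 1e-9)
        n2 = np.maximum((1 - r1).sum(axis=1), 1e-9)
        w = np.clip(n1 / x.size, 1e-6, 1 - 1e-6)
        v1 = np.maximum((r1 * (x[None, :] - m1[:, None]) ** 2).sum(axis=1) / n1, var_floor)
        v2 = np.maximum(((1 - r1) * (x[None, :] - m2[:, None]) ** 2).sum(axis=1) / n2, var_floor)
    best = int(np.argmax(lse.sum(axis=1)))
    return float(m1[best]), float(m2[best])


def signature_confusion(truth_table, selected_table) -> tuple[int, int, int]:
    """(tp, fp, fn) of selected vs planted signed marker sets, direction-aware."""
    tp = fp = fn = 0
    for subtype in truth_table.subtypes:
        true_up = set(truth_table.up.get(subtype, ()))
        true_down = set(truth_table.down.get(subtype, ()))
        sel_up = set(selected_table.up.get(subtype, ()))
        sel_down = set(selected_table.down.get(subtype, ()))
        tp += len(true_up & sel_up) + len(true_down & sel_down)
        fp += len(sel_up - true_up) + len(sel_down - true_down)
        fn += len(true_up - sel_up) + len(true_down - sel_down)
    return tp, fp, fn
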