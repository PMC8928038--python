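"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: splits are found by
exhaustive enumeration, AUC by counting concordant pairs, SSE by direct
summation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def sse(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    if len(z) == 0:
        return 0.0
    return float(((z - z.mean()) ** 2).sum())


def exhaustive_best_bipartition(values: pd.Series, z: np.ndarray, min_leaf: int = 1):
    """Best categorical bipartition by trying all 2^(L-1) - 1 of them.

    Returns (gain, frozenset(one side)) or None.
    """
    z = np.asarray(z, dtype=float)
    levels = sorted(values.unique(), key=str)
    base = sse(z)
    best = None
    for r in range(1, len(levels)):
        for combo in itertools.combinations(levels, r):
            mask = values.isin(combo).to_numpy()
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            gain = base - sse(z[mask]) - sse(z[~mask])
            if best is None or gain > best[0] + 1e-12:
                best = (gain, frozenset(combo))
    return best


def exhaustive_best_threshold(values: pd.Series, z: np.ndarray,
                              level_order, min_leaf: int = 1):
    """Best ordinal threshold split by trying every cut in declared order."""
    z = np.asarray(z, dtype=float)
    base = sse(z)
    best = None
    for k in range(len(level_order) - 1):
        left = set(level_order[:k + 1])
        mask = values.isin(left).to_numpy()
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            continue
        gain = base - sse(z[mask]) - sse(z[~mask])
        if best is None or gain > best[0] + 1e-12:
            best = (gain, frozenset(left))
    return best


def exhaustive_best_split_all(X: pd.DataFrame, z: np.ndarray,
                              ordinal=frozenset(), level_orders=None,
                              min_leaf: int = 1):
    """Globally best single split over all covariates, by enumeration.

    Returns (gain, variable, frozenset(satisfying side)) or None.
    """
    level_orders = level_orders or {}
    best = None
    for col in X.columns:
        if col in ordinal:
            res = exhaustive_best_threshold(
                X[col], z, level_orders.get(col, sorted(X[col].unique(), key=str)),
                min_leaf)
        else:
            res = exhaustive_best_bipartition(X[col], z, min_leaf)
        if res is not None and (best is None or res[0] > best[0] + 1e-12):
            best = (res[0], col, res[1])
    return best


def pair_count_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the fraction of concordant (positive, negative) pairs,
    counting ties as half."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(conc) / total


def yates_chi2(k1: int, n1: int, k2: int, n2: int) -> float:
    """Textbook continuity-corrected 2x2 chi-square, Sum (|O-E|-0.5)^2/E."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    return float((adj ** 2 / exp).sum())
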