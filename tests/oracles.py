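"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (loops, closed forms, exhaustive
scans) and shares no code with the package under test.
"""
from __future__ import annotations

import math
from typing import Dict, Sequence

import numpy as np


def allocation_oracle(n: int, proportions: Dict[str, float]) -> Dict[str, int]:
    """Largest-remainder apportionment, written independently."""
    quotas = {c: n * p for c, p in proportions.items()}
    out = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = n - sum(out.values())
    order = sorted(
        proportions, key=lambda c: (-(quotas[c] - math.floor(quotas[c])), c)
    )
    for c in order[:leftover]:
        out[c] += 1
    return out


def ols_slope_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Closed-form OLS slope with intercept: sum((x-xb)(y-yb)) / sum((x-xb)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xb, yb = x.mean(), y.mean()
    return float(((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum())


def average_ranks_oracle(values: Sequence[float]) -> np.ndarray:
    """Average ranks with mean-rank ties, by exhaustive pairwise counting."""
    v = np.asarray(values, dtype=float)
    ranks = np.empty(len(v))
    for i, vi in enumerate(v):
        less = int((v < vi).sum())
        equal = int((v == vi).sum())
        # mean of the rank positions occupied by the tied block
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    rx = average_ranks_oracle(x)
    ry = average_ranks_oracle(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx * rx).sum() * (ry * ry).sum()))


def spike_filter_oracle(
    reads: np.ndarray, min_reads: float, min_sample_fraction: float
) -> np.ndarray:
    """Row-wise keep mask for the spike coverage filter."""
    n_samples = reads.shape[1]
    needed = math.ceil(min_sample_fraction * n_samples)
    keep = np.zeros(reads.shape[0], dtype=bool)
    for i in range(reads.shape[0]):
        count = sum(1 for v in reads[i] if v >= min_reads)
        keep[i] = count >= needed
    return keep


def fit_filter_oracle(rows: Sequence[dict], alpha: float) -> list:
    """Row-by-row scan of the significance filter."""
    kept = []
    for i, r in enumerate(rows):
        if not r["converged"]:
            continue
        if not (r["p_k"] < alpha):
            continue
        if not r["c_was_fixed"] and not (r["p_C"] < alpha):
            continue
        kept.append(i)
    return kept


def decay_sse(
    C: float, k: float, z: float, x: np.ndarray, y: np.ndarray, background_mode: str
) -> float:
    if background_mode == "log_offset":
        pred = np.log2(C) - k * x / math.log(2) + z
    else:
        pred = np.log2(C * np.exp(-k * x) + z)
    return float(((pred - y) ** 2).sum())


def grid_search_sse(
    x: np.ndarray,
    y: np.ndarray,
    z: float,
    background_mode: str = "log_offset",
    n_grid: int = 400,
) -> float:
    """Minimum SSE over a log-spaced (C, k) grid around the data's scale."""
    c_grid = np.logspace(-3, 3, n_grid) * max(2.0 ** np.max(y), 1e-6)
    k_grid = np.logspace(-4, 2, n_grid)
    best = math.inf
    for C in c_grid:
        if background_mode == "log_offset":
            pred = np.log2(C) - np.outer(k_grid, x) / math.log(2) + z
        else:
            pred = np.log2(C * np.exp(-np.outer(k_grid, x)) + z)
        sse = ((pred - y) ** 2).sum(axis=1)
        m = float(sse.min())
        if m < best:
            best = m
    return best
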