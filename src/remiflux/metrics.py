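"""Benchmark metrics: uncentered correlation, relative deviation, summaries.

Fluxes are compared with the uncentered Pearson correlation r = v1.v2 /
(|v1||v2|) because flux vectors are not mean-centered, and with the average
percentage error built from per-reaction relative deviations
d_r = (x - y)/(|x| + |y|).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "uncentered_pearson",
    "relative_deviation",
    "average_percentage_error",
    "summarize_scores",
    "align_fluxes",
    "flux_comparison",
]


def uncentered_pearson(v1: Sequence[float], v2: Sequence[float]) -> float:
    """r = (v1 . v2) / (||v1|| ||v2||), in [-1, 1]; errors on a zero vector."""
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("vectors must be 1-D, equal length, nonempty")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("uncentered Pearson undefined for an all-zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def relative_deviation(x: float, y: float) -> float:
    """d_r = (x - y) / (|x| + |y|) in [-1, 1]; defined as 0 when x = y = 0."""
    if x == 0 and y == 0:
        return 0.0
    return (x - y) / (abs(x) + abs(y))


def average_percentage_error(d_pred: Sequence[float], d_exp: Sequence[float]) -> float:
    """e = mean |d_pred_i - d_exp_i| over aligned relative deviations."""
    a = np.asarray(d_pred, dtype=float)
    b = np.asarray(d_exp, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("deviation vectors must be 1-D, equal length, nonempty")
    return float(np.mean(np.abs(a - b)))


def summarize_scores(values: Sequence[float]) -> dict[str, float]:
    """Mean and population (divisor-n) standard deviation of a score list."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty score list")
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0))}


def align_fluxes(
    predicted: Mapping[str, float],
    measured: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Align two flux maps on shared reaction ids.

    Returns (predicted vector, measured vector, shared ids, unmatched ids).
    """
    shared = sorted(set(predicted) & set(measured))
    unmatched = sorted(set(predicted) ^ set(measured))
    if not shared:
        raise ValueError("no shared reaction ids between predicted and measured fluxes")
    vp = np.array([predicted[r] for r in shared], dtype=float)
    vm = np.array([measured[r] for r in shared], dtype=float)
    return vp, vm, shared, unmatched


def flux_comparison(
    predicted_cond1: Mapping[str, float],
    predicted_cond2: Mapping[str, float],
    measured_cond1: Mapping[str, float],
    measured_cond2: Mapping[str, float],
) -> pd.Series:
    """Full benchmark of a condition pair against measured fluxes.

    Reports the uncentered Pearson correlation per condition and the average
    percentage error of the predicted relative deviations (condition 1 vs 2)
    against the measured ones, over the reactions shared by all four maps.
    """
    shared = sorted(set(predicted_cond1) & set(predicted_cond2)
                    & set(measured_cond1) & set(measured_cond2))
    if not shared:
        raise ValueError("no reaction shared by all four flux maps")
    p1 = [predicted_cond1[r] for r in shared]
    p2 = [predicted_cond2[r] for r in shared]
    m1 = [measured_cond1[r] for r in shared]
    m2 = [measured_cond2[r] for r in shared]
    d_pred = [relative_deviation(a, b) for a, b in zip(p1, p2)]
    d_exp = [relative_deviation(a, b) for a, b in zip(m1, m2)]
    return pd.Series({
        "r_cond1": uncentered_pearson(p1, m1),
        "r_cond2": uncentered_pearson(p2, m2),
        "avg_pct_error": average_percentage_error(d_pred, d_exp),
        "n_reactions": len(shared),
    })
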