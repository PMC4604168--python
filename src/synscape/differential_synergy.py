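"""Permutation-based two-class differential synergy (SAM-style).

Given a (combination x cell line) matrix of Bliss scores and a two-class
partition of the lines (e.g. BRAF-inhibitor-resistant vs sensitive), each
combination gets a moderated difference statistic

    d = (mean_A - mean_B) / (s + s0),

where s is the pooled (equal-variance) standard error of the group-mean
difference and s0 a fudge constant damping combinations whose tiny
variance would otherwise inflate d.  s0 defaults to the median of the
per-combination standard errors — a deterministic simplification of the
classic coefficient-of-variation grid search with similar asymptotic
behaviour.

False-discovery rates come from label permutations: for each observed |d|
threshold, q = (1 + median over permutations of the number of permuted |d|
values above the threshold) / (number of observed |d| values above it),
then monotonized so q never increases with |d|.  The add-one pseudo-count
is the usual "the observed labelling is itself a permutation" convention;
it keeps a fully null matrix from producing spurious calls while leaving
genuinely shifted combinations (whose permuted statistics collapse) with
q well below any practical FDR target.  When the number of distinct label
assignments is no larger than the requested permutation count, the null is
enumerated exhaustively and the result is seed-independent.
"""

from __future__ import annotations

import logging
from itertools import combinations as _combinations
from math import comb

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_FDR = 0.1


def _group_stats(values: np.ndarray, mask: np.ndarray):
    a = values[mask]
    b = values[~mask]
    return a.mean(), b.mean(), a.var(ddof=1), b.var(ddof=1), a.size, b.size


def pooled_se(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Equal-variance pooled standard error of the group-mean difference."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float(np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def d_statistic(group_a, group_b, s0: float) -> float:
    """Moderated difference statistic (mean_A - mean_B) / (s + s0).

    With s0 = 0 this is exactly the equal-variance two-sample t statistic.
    Each group needs at least two values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    return float((a.mean() - b.mean()) / (pooled_se(a, b) + s0))


def choose_s0(all_se) -> float:
    """Fudge constant: median of the per-combination pooled standard errors."""
    se = np.asarray(all_se, dtype=float)
    if se.size == 0:
        raise ValueError("need at least one combination")
    return float(np.median(se))


def _d_for_masks(x: np.ndarray, masks: np.ndarray, s0: float) -> np.ndarray:
    """Vectorised d for every row of ``x`` under every boolean column mask.

    ``x`` is (m combinations x n lines); ``masks`` is (P x n) with True
    marking group A.  Returns (m x P).
    """
    na = masks.sum(axis=1).astype(float)  # (P,)
    nb = masks.shape[1] - na
    mt = masks.T.astype(float)  # (n, P)
    sum_a = x @ mt  # (m, P)
    sum_b = x.sum(axis=1, keepdims=True) - sum_a
    ssq_a = (x**2) @ mt
    ssq_b = (x**2).sum(axis=1, keepdims=True) - ssq_a
    mean_a = sum_a / na
    mean_b = sum_b / nb
    var_a = (ssq_a - na * mean_a**2) / (na - 1)
    var_b = (ssq_b - nb * mean_b**2) / (nb - 1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / na + 1.0 / nb))
    return (mean_a - mean_b) / (se + s0)


def _permutation_masks(
    n: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean (P x n) group-A masks; exhaustive when feasible."""
    n_distinct = comb(n, n_a)
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(_combinations(range(n), n_a)):
            masks[i, list(idx)] = True
        return masks, True
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_a, replace=False)] = True
    return masks, False


def permutation_fdr(
    matrix: pd.DataFrame,
    group_a: list[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr_target: float = DEFAULT_FDR,
    s0: float | None = None,
) -> pd.DataFrame:
    """Differential synergy with permutation-estimated FDR.

    ``matrix`` has one row per combination and one column per cell line;
    ``group_a`` lists the columns of the focal subgroup (e.g. the resistant
    lines).  Returns one row per combination sorted by |d| descending, with
    ``d_stat``, ``mean_diff`` (group-mean Bliss difference in points),
    ``q_value`` and ``significant`` (q <= ``fdr_target``).  Deterministic
    given ``seed``; exhaustive label enumeration replaces sampling whenever
    the design allows it.
    """
    cols = list(matrix.columns)
    group_a = list(group_a)
    unknown = [c for c in group_a if c not in cols]
    if unknown:
        raise ValueError(f"group_a columns not in matrix: {unknown}")
    n_a = len(group_a)
    n_b = len(cols) - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"both groups need >= 2 lines (got {n_a} vs {n_b})"
        )

    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values")
    obs_mask = np.array([c in set(group_a) for c in cols])

    # observed statistics and s0 from the observed labelling
    if s0 is None:
        ses = np.array(
            [pooled_se(row[obs_mask], row[~obs_mask]) for row in x]
        )
        s0 = choose_s0(ses)
    d_obs = _d_for_masks(x, obs_mask[None, :], s0)[:, 0]
    mean_diff = x[:, obs_mask].mean(axis=1) - x[:, ~obs_mask].mean(axis=1)

    rng = np.random.default_rng(seed)
    masks, exhaustive = _permutation_masks(len(cols), n_a, n_perm, rng)
    d_perm = np.abs(_d_for_masks(x, masks, s0))  # (m, P)

    order = np.argsort(-np.abs(d_obs), kind="stable")
    thresholds = np.abs(d_obs)[order]  # descending
    # exceedance count per permutation at every observed threshold
    m = d_perm.shape[0]
    counts = np.empty((m, d_perm.shape[1]), dtype=np.int64)
    asc = thresholds[::-1]
    for p in range(d_perm.shape[1]):
        col = np.sort(d_perm[:, p])
        counts[:, p] = (m - np.searchsorted(col, asc, side="left"))[::-1]
    v_med = np.median(counts, axis=1)  # (m,)
    r_obs = np.arange(1, len(thresholds) + 1)
    q_raw = np.minimum((1.0 + v_med) / r_obs, 1.0)
    # monotone non-increasing in |d|: running min from the weakest row up
    q_sorted = np.minimum.accumulate(q_raw[::-1])[::-1]

    out = pd.DataFrame(
        {
            "pair": matrix.index[order],
            "d_stat": d_obs[order],
            "mean_diff": mean_diff[order],
            "q_value": q_sorted,
        }
    )
    out["significant"] = out["q_value"] <= fdr_target
    out.attrs["s0"] = float(s0)
    out.attrs["exhaustive"] = exhaustive
    out.attrs["n_perm"] = int(masks.shape[0])
    return out
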