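"""Receptor regression and dominance analysis of community degree maps.

Each brainstem community's cortical weighted-degree profile is modelled by
multiple linear regression on z-scored receptor/transporter density maps.
Dominance analysis partitions the full model's adjusted R^2 into
per-predictor contributions: a predictor's total dominance is the
level-weighted (Shapley) average of the increase in adjusted R^2 it brings
when added to a submodel, over all 2^p - 1 submodels.  With the empty model
valued at 0, the dominances sum exactly to the full model's adjusted R^2;
normalizing by that total gives percent contributions comparable across
models.

All 2^p - 1 submodel fits are solved on sufficient statistics (the
correlation matrix of predictors and response), never on raw data, which
makes the exhaustive p = 18 enumeration (262,143 submodels) routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .hubs import AnnotationMap, DegreeMap

__all__ = [
    "DEFAULT_RECEPTOR_NAMES",
    "DominanceResult",
    "fit_receptor_model",
    "dominance_analysis",
]

# 18 receptor/transporter maps across 9 neurotransmitter systems
DEFAULT_RECEPTOR_NAMES = (
    "D2", "DAT", "NET",
    "5-HT1A", "5-HT1B", "5-HT2A", "5-HT4", "5-HT6", "5-HTT",
    "A4B2", "M1", "VAChT",
    "mGluR5", "NMDA", "GABAA", "H3", "CB1", "MOR",
)


def _as_design(response, predictors) -> tuple[np.ndarray, np.ndarray, list[str]]:
    y = response.values if isinstance(response, DegreeMap) else np.asarray(response, float)
    if isinstance(predictors, np.ndarray):
        x = np.asarray(predictors, float)
        names = [f"x{j}" for j in range(x.shape[1])]
    else:
        x = np.column_stack([p.values for p in predictors])
        names = [p.name for p in predictors]
    if x.shape[0] != y.shape[0]:
        raise ValueError("response and predictors have different node counts")
    return y, x, names


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be z-scored")
    return (a - a.mean(axis=0)) / sd


def _adjusted(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_receptor_model(response, predictors) -> dict:
    """OLS (with intercept) of a degree map on z-scored annotation maps.

    Returns total R^2, adjusted R^2 and standardized coefficients.  A
    rank-deficient design is rejected with the offending predictors named.
    """
    y, x, names = _as_design(response, predictors)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    xz, yz = _zscore(x), _zscore(y)
    rank = np.linalg.matrix_rank(xz)
    if rank < p:
        # QR with pivoting: columns beyond the numerical rank are collinear
        from scipy.linalg import qr
        _, r, piv = qr(xz, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design is rank deficient; collinear predictors: {bad}")
    beta, _, _, _ = np.linalg.lstsq(xz, yz, rcond=None)
    resid = yz - xz @ beta
    r2 = 1.0 - float(resid @ resid) / float(yz @ yz)
    return {"r2": r2, "r2_adj": _adjusted(r2, n, p),
            "coefficients": dict(zip(names, beta)), "n": n, "p": p}


@dataclass
class DominanceResult:
    """Per-predictor total dominance; sums to the full model's adjusted R^2."""

    predictors: list[str]
    dominance: np.ndarray = field(repr=False)
    total_r2_adj: float = 0.0

    @property
    def percent_contribution(self) -> np.ndarray:
        if self.total_r2_adj == 0:
            raise ValueError("percent contribution undefined when total fit is 0")
        return self.dominance / self.total_r2_adj

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.predictors, self.dominance))


def _all_subset_r2(c_xx: np.ndarray, c_xy: np.ndarray, n: int) -> np.ndarray:
    """Adjusted R^2 for every predictor subset, indexed by bitmask.

    Solved from the correlation sufficient statistics:
    R^2(S) = r_yS' C_SS^{-1} r_Sy for z-scored data.
    """
    p = c_xy.size
    r2adj = np.zeros(1 << p)
    for size in range(1, p + 1):
        for combo in combinations(range(p), size):
            idx = np.array(combo)
            mask = 0
            for j in combo:
                mask |= 1 << j
            sub = c_xx[np.ix_(idx, idx)]
            r2 = float(c_xy[idx] @ np.linalg.solve(sub, c_xy[idx]))
            r2adj[mask] = _adjusted(r2, n, size)
    return r2adj


def dominance_analysis(response, predictors,
                       max_p_exhaustive: int = 18) -> DominanceResult:
    """Exhaustive dominance analysis (Shapley decomposition of adjusted R^2).

    For each predictor the incremental adjusted R^2 over subsets of the other
    predictors is averaged within each subset size, then across sizes.  The
    enumeration is exact; designs with more than ``max_p_exhaustive``
    predictors are rejected rather than approximated by sampling.
    """
    y, x, names = _as_design(response, predictors)
    n, p = x.shape
    if p > max_p_exhaustive:
        raise ValueError(f"{p} predictors exceed the exhaustive limit "
                         f"({max_p_exhaustive}); refusing to approximate")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    xz, yz = _zscore(x), _zscore(y)
    c_xx = (xz.T @ xz) / n
    c_xy = (xz.T @ yz) / n
    r2adj = _all_subset_r2(c_xx, c_xy, n)

    masks = np.arange(1 << p, dtype=np.int64)
    sizes = np.bitwise_count(masks).astype(np.int64)
    from math import comb
    dominance = np.empty(p)
    for i in range(p):
        without = (masks >> i) & 1 == 0
        m = masks[without]
        delta = r2adj[m | (1 << i)] - r2adj[m]
        by_size = np.bincount(sizes[without], weights=delta, minlength=p)[:p]
        weights = np.array([comb(p - 1, k) for k in range(p)], float)
        dominance[i] = float(np.mean(by_size / weights))
    total = float(r2adj[-1])
    return DominanceResult(predictors=names, dominance=dominance,
                           total_r2_adj=total)
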