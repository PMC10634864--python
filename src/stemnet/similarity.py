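"""Residualized connectivity profiles and cross-structure similarity matrices.

Both cortex and brainstem couple to the brainstem through one dominant
weighted-degree pattern.  To expose structure beyond it, that pattern (the
brainstem-to-cortex weighted-degree vector) is regressed out of every
region's brainstem connectivity profile by ordinary least squares with an
intercept.  Spearman correlations of the residual profiles then yield

* a brainstem x brainstem similarity matrix (columns: each nucleus's residual
  cortical profile) feeding community detection, and
* a cortex x cortex similarity matrix (rows: each region's residual brainstem
  profile) feeding gradient embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import ConnectivityMatrix
from .hubs import weighted_degree
from .nodes import NodeTable

__all__ = [
    "ResidualProfileMatrix",
    "SimilarityMatrix",
    "residualize_profiles",
    "profile_similarity",
    "degree_profile_correlations",
]


@dataclass
class ResidualProfileMatrix:
    """Rows: regions (cortex by default); columns: brainstem nuclei.

    ``regressor`` is the brainstem weighted-degree vector that was removed
    from every row.
    """

    values: np.ndarray = field(repr=False)
    regressor: np.ndarray = field(repr=False)
    row_idx: np.ndarray = field(repr=False, default=None)
    col_idx: np.ndarray = field(repr=False, default=None)


@dataclass
class SimilarityMatrix:
    """Spearman-correlation similarity matrix along one axis."""

    values: np.ndarray = field(repr=False)
    axis: str = "brainstem"  # or "cortex"
    node_idx: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v


def residualize_profiles(fc: ConnectivityMatrix, nodes: NodeTable,
                         rows: str = "cortex") -> ResidualProfileMatrix:
    """Regress the dominant brainstem degree pattern out of every profile.

    For each row region, its brainstem-connectivity profile ``y`` (length 58)
    is fit as ``y = a + b d`` where ``d`` is the brainstem-to-cortex weighted
    degree (one fixed vector, computed from this FC matrix, shared by all
    rows); the residuals are returned.  ``rows='all'`` includes brainstem
    rows, residualized identically.
    """
    ctx, bs = nodes.cortex_idx, nodes.brainstem_idx
    d = weighted_degree(fc, seed_idx=ctx, target_idx=bs).values
    if np.ptp(d) == 0:
        raise ValueError("brainstem degree regressor is constant; regression undefined")
    if rows == "cortex":
        row_idx = ctx
    elif rows == "all":
        row_idx = np.concatenate([ctx, bs])
    else:
        raise ValueError(f"rows must be 'cortex' or 'all', got {rows!r}")
    y = fc.values[np.ix_(row_idx, bs)]
    dc = d - d.mean()
    beta = (y @ dc) / (dc @ dc)
    resid = (y - y.mean(axis=1, keepdims=True)) - np.outer(beta, dc)
    return ResidualProfileMatrix(values=resid, regressor=d,
                                 row_idx=row_idx, col_idx=bs)


def degree_profile_correlations(fc: ConnectivityMatrix,
                                nodes: NodeTable) -> np.ndarray:
    """Spearman r of every node's brainstem profile with the brainstem
    degree map (the dominant-pattern diagnostic; one value per node,
    self-connections excluded for brainstem rows)."""
    ctx, bs = nodes.cortex_idx, nodes.brainstem_idx
    d = weighted_degree(fc, seed_idx=ctx, target_idx=bs).values
    out = np.empty(len(nodes))
    for pos, i in enumerate(np.concatenate([ctx, bs])):
        profile = fc.values[i, bs]
        mask = bs != i
        out[pos] = stats.spearmanr(profile[mask], d[mask])[0]
    return out


def profile_similarity(res: ResidualProfileMatrix,
                       axis: str = "brainstem") -> SimilarityMatrix:
    """Spearman correlation matrix of residual profiles along one axis.

    ``axis='brainstem'`` correlates columns (each nucleus's residual cortical
    profile); ``axis='cortex'`` correlates rows (each region's residual
    brainstem profile).  Diagonal is set to 1 exactly.
    """
    v = res.values
    if not np.isfinite(v).all():
        raise ValueError("residual matrix contains non-finite values")
    if axis == "brainstem":
        mat, idx = v, res.col_idx
    elif axis == "cortex":
        mat, idx = v.T, res.row_idx
    else:
        raise ValueError(f"axis must be 'brainstem' or 'cortex', got {axis!r}")
    spread = mat.max(axis=0) - mat.min(axis=0)
    if np.any(spread == 0):
        bad = int(np.flatnonzero(spread == 0)[0])
        raise ValueError(f"profile of node index {bad} is constant; "
                         "rank correlation undefined")
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    sim = np.corrcoef(ranks, rowvar=False)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(values=sim, axis=axis, node_idx=idx)
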