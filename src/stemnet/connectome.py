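"""Functional connectome construction and quality-control analyses.

Functional connectivity (FC) is the Pearson correlation between two parcels'
time-series; the group connectome is the element-wise mean of subject
connectomes (raw r, no Fisher transform).  QC analyses cover temporal SNR,
the distance dependence of FC, block-wise comparisons (within-brainstem vs
brainstem-cortex) and split-half reliability of the group connectome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nodes import NodeTable

__all__ = [
    "SubjectTimeSeries",
    "ConnectivityMatrix",
    "compute_fc",
    "group_average",
    "compute_tsnr",
    "size_association",
    "fc_distance_profile",
    "compare_fc_blocks",
    "split_half_reliability",
]


@dataclass
class SubjectTimeSeries:
    """One subject's node x time matrix (runs already concatenated)."""

    subject_id: str
    values: np.ndarray = field(repr=False)
    tr: float = 2.5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("time-series must be a 2D node x time matrix")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Pearson FC matrix with unit diagonal."""

    values: np.ndarray = field(repr=False)
    level: str = "subject"  # or "group"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric within 1e-12")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.values[np.ix_(rows, cols)]


def compute_fc(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of node time-series."""
    x = ts.values
    if x.shape[1] < 3:
        raise ValueError("need at least 3 timepoints to correlate")
    if np.isnan(x).any():
        raise ValueError("time-series contain NaN; inputs must be complete")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"node {bad} has a constant time-series; correlation undefined")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return ConnectivityMatrix(values=(r + r.T) / 2.0, level="subject")


def group_average(fcs: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of subject connectomes (raw r, no Fisher transform)."""
    if len(fcs) < 1:
        raise ValueError("need at least one subject matrix")
    shape = fcs[0].values.shape
    for fc in fcs[1:]:
        if fc.values.shape != shape:
            raise ValueError("all connectivity matrices must have the same shape")
    mean = np.mean([fc.values for fc in fcs], axis=0)
    return ConnectivityMatrix(values=mean, level="group")


def compute_tsnr(raw_ts: SubjectTimeSeries) -> np.ndarray:
    """Temporal SNR per node: time-series mean / sample SD (mean retained).

    Nodes with zero SD get NaN (flagged undefined) with a warning.
    """
    mean = raw_ts.values.mean(axis=1)
    sd = raw_ts.values.std(axis=1, ddof=1)
    tsnr = np.full(raw_ts.n_nodes, np.nan)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} node(s) have zero temporal SD; "
                      "tSNR flagged undefined", stacklevel=2)
    tsnr[ok] = mean[ok] / sd[ok]
    return tsnr


def size_association(tsnr: np.ndarray, nodes: NodeTable) -> tuple[float, float]:
    """Spearman correlation of brainstem tSNR with parcel size (voxels)."""
    idx = nodes.brainstem_idx
    sizes = nodes.column("size_voxels")[idx].astype(float)
    vals = np.asarray(tsnr, float)[idx]
    ok = np.isfinite(vals)
    if not ok.all():
        warnings.warn("excluding nodes with undefined tSNR from size association",
                      stacklevel=2)
        vals, sizes = vals[ok], sizes[ok]
    if np.unique(vals).size < 2 or np.unique(sizes).size < 2:
        return 0.0, 1.0  # degenerate ranks
    rho, p = stats.spearmanr(vals, sizes)
    return float(rho), float(p)


_BLOCKS = ("within_cortex", "within_brainstem", "cortex_brainstem")


def _block_entries(fc: ConnectivityMatrix, nodes: NodeTable,
                   distances: bool = False):
    """Unique off-diagonal FC (and optionally distance) entries per block."""
    ctx, bs = nodes.cortex_idx, nodes.brainstem_idx
    v = fc.values
    d = None
    if distances:
        c = nodes.centroids
        if np.isnan(c).any():
            raise ValueError("node centroids contain missing values")
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    out = {}
    for name, rows, cols in (("within_cortex", ctx, ctx),
                             ("within_brainstem", bs, bs),
                             ("cortex_brainstem", ctx, bs)):
        if name.startswith("within"):
            sub = v[np.ix_(rows, cols)]
            iu = np.triu_indices(len(rows), k=1)
            fc_vals = sub[iu]
            d_vals = d[np.ix_(rows, cols)][iu] if distances else None
        else:
            fc_vals = v[np.ix_(rows, cols)].ravel()
            d_vals = d[np.ix_(rows, cols)].ravel() if distances else None
        out[name] = (fc_vals, d_vals)
    return out


def fc_distance_profile(fc: ConnectivityMatrix, nodes: NodeTable,
                        method: str = "pearson") -> dict:
    """FC as a function of Euclidean centroid distance, per block.

    Returns ``{block: {"distance", "fc", "r", "p"}}`` for within-cortex,
    within-brainstem and cortex-brainstem blocks (unique pairs only).
    """
    entries = _block_entries(fc, nodes, distances=True)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    out = {}
    for name, (fc_vals, d_vals) in entries.items():
        if fc_vals.size >= 2 and np.ptp(fc_vals) > 0 and np.ptp(d_vals) > 0:
            r, p = corr(d_vals, fc_vals)
        else:
            r, p = np.nan, np.nan   # too few pairs (or degenerate) to correlate
        out[name] = {"distance": d_vals, "fc": fc_vals,
                     "r": float(r), "p": float(p)}
    return out


def compare_fc_blocks(fc: ConnectivityMatrix, nodes: NodeTable) -> tuple[float, float]:
    """Welch's two-sided t-test: brainstem-cortex FC vs within-brainstem FC."""
    entries = _block_entries(fc, nodes)
    a = entries["cortex_brainstem"][0]
    b = entries["within_brainstem"][0]
    if a.size < 2 or b.size < 2:
        raise ValueError("each block needs at least 2 entries for Welch's t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    p = max(float(p), 1e-300)  # report p ~ 0 as < 1e-300
    return float(t), p


def split_half_reliability(all_ts: list[SubjectTimeSeries], nodes: NodeTable,
                           n_reps: int = 100, seed: int = 0) -> dict[str, np.ndarray]:
    """Split-half reliability of the group connectome.

    Subjects are split into two random disjoint halves ``n_reps`` times; per
    repetition the two half-sample group connectomes are compared via the
    Pearson correlation of (i) their unique FC entries, (ii) brainstem-to-cortex
    weighted degree and (iii) cortex-to-brainstem weighted degree.
    """
    n_sub = len(all_ts)
    if n_sub < 4 or n_sub % 2:
        raise ValueError("split-half design needs an even number of subjects >= 4")
    fcs = np.stack([compute_fc(ts).values for ts in all_ts])
    ctx, bs = nodes.cortex_idx, nodes.brainstem_idx
    iu = np.triu_indices(fcs.shape[1], k=1)
    rng = np.random.default_rng(seed)
    out = {"fc": np.empty(n_reps), "brainstem_degree": np.empty(n_reps),
           "cortex_degree": np.empty(n_reps)}
    for rep in range(n_reps):
        perm = rng.permutation(n_sub)
        half_a = fcs[perm[: n_sub // 2]].mean(axis=0)
        half_b = fcs[perm[n_sub // 2:]].mean(axis=0)
        out["fc"][rep] = stats.pearsonr(half_a[iu], half_b[iu])[0]
        deg_a = half_a[np.ix_(bs, ctx)].sum(axis=1)
        deg_b = half_b[np.ix_(bs, ctx)].sum(axis=1)
        out["brainstem_degree"][rep] = stats.pearsonr(deg_a, deg_b)[0]
        deg_a = half_a[np.ix_(ctx, bs)].sum(axis=1)
        deg_b = half_b[np.ix_(ctx, bs)].sum(axis=1)
        out["cortex_degree"][rep] = stats.pearsonr(deg_a, deg_b)[0]
    return out
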