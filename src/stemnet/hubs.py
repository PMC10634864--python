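"""Weighted-degree hub maps and their comparison with annotation maps.

Weighted degree of a node is the sum of its signed FC over a seed set (no
thresholding, no absolute value): summed over the 400 cortical parcels it
ranks brainstem-to-cortex hubs, summed over the 58 brainstem nuclei it ranks
cortex-to-brainstem hubs.  Degree maps are binned by cytoarchitectonic class
(one-way ANOVA), correlated with annotation maps (MEG band power, receptor
densities) under spatial nulls, and decoded against meta-analytic term maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectivityMatrix

__all__ = [
    "DegreeMap",
    "AnnotationMap",
    "weighted_degree",
    "class_bin_anova",
    "correlate_with_map",
    "correlate_with_maps",
    "decode_terms",
]


@dataclass
class DegreeMap:
    """Weighted degree over ``seed_idx``, defined on ``target_idx`` nodes."""

    values: np.ndarray = field(repr=False)
    seed_idx: np.ndarray = field(repr=False, default=None)
    target_idx: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise ValueError("degree map contains non-finite values")


@dataclass
class AnnotationMap:
    """A per-cortical-node scalar map (receptor density, MEG power, term)."""

    name: str
    values: np.ndarray = field(repr=False)
    kind: str = "other"  # meg_power | receptor | term | other

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


def weighted_degree(fc: ConnectivityMatrix, seed_idx: np.ndarray,
                    target_idx: np.ndarray) -> DegreeMap:
    """Sum of signed FC over the seed set, for every target node."""
    seed_idx = np.asarray(seed_idx, int)
    target_idx = np.asarray(target_idx, int)
    if seed_idx.size == 0 or target_idx.size == 0:
        raise ValueError("seed and target sets must be nonempty")
    values = fc.values[np.ix_(target_idx, seed_idx)].sum(axis=1)
    return DegreeMap(values=values, seed_idx=seed_idx, target_idx=target_idx)


def class_bin_anova(values: np.ndarray, labels: np.ndarray) -> tuple[float, float, pd.DataFrame]:
    """One-way fixed-effects ANOVA of a map binned by categorical class.

    Returns (F, p, per-class summary).  F = MS_between / MS_within; when the
    between-class sum of squares is exactly zero, F = 0 and p = 1.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    classes, inverse = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    counts = np.bincount(inverse)
    if np.any(counts < 2):
        bad = classes[np.argmin(counts)]
        raise ValueError(f"class {bad!r} has fewer than 2 members")
    n = values.size
    grand = values.mean()
    means = np.bincount(inverse, weights=values) / counts
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[inverse]) ** 2))
    df_between, df_within = classes.size - 1, n - classes.size
    summary = pd.DataFrame({"class": classes, "n": counts, "mean": means})
    if ss_between == 0.0:
        return 0.0, 1.0, summary
    if ss_within == 0.0:
        return math.inf, 0.0, summary
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p, summary


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y)[0])
    if method == "spearman":
        return float(stats.spearmanr(x, y)[0])
    raise ValueError(f"unknown correlation method {method!r}")


def correlate_with_map(map_values: np.ndarray | DegreeMap, annot: AnnotationMap,
                       method: str = "pearson", null=None,
                       tails: str = "two") -> tuple[float, float]:
    """Correlate a degree map with an annotation map.

    With ``null`` (a :class:`~stemnet.nulls.SpinEnsemble`) the p-value is the
    spatial-permutation p from the spin test, the degree map being the rotated
    member; otherwise the parametric p of the chosen correlation.
    """
    x = map_values.values if isinstance(map_values, DegreeMap) else np.asarray(map_values, float)
    y = annot.values
    if x.shape != y.shape:
        raise ValueError("degree map and annotation map lengths differ")
    if null is not None:
        from .nulls import spin_pvalue
        r = _corr(x, y, method)
        p, _ = spin_pvalue(r, x, y, null, method=method, tails=tails)
        return r, p
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    r, p = func(x, y)
    return float(r), float(p)


def correlate_with_maps(map_values: np.ndarray | DegreeMap,
                        annots: list[AnnotationMap], method: str = "pearson",
                        null=None, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Batch correlation with Benjamini-Hochberg adjustment across maps."""
    rows = [(a.name, *correlate_with_map(map_values, a, method=method, null=null))
            for a in annots]
    df = pd.DataFrame(rows, columns=["name", "r", "p"])
    from statsmodels.stats.multitest import multipletests
    rej, q, _, _ = multipletests(df["p"], alpha=fdr_alpha, method="fdr_bh")
    df["q"] = q
    df["significant_fdr"] = rej
    return df


def decode_terms(map_values: np.ndarray | DegreeMap, terms: list[AnnotationMap],
                 top_fraction: float = 0.10) -> pd.DataFrame:
    """Rank meta-analytic term maps by Pearson correlation with a degree map.

    The top ``top_fraction`` of terms (floor of the count, at least one; ties
    at the boundary broken by term name) are flagged, mirroring the reporting
    convention of showing the 10% most correlated terms.
    """
    if len(terms) < 1:
        raise ValueError("need at least one term map")
    x = map_values.values if isinstance(map_values, DegreeMap) else np.asarray(map_values, float)
    fixed = []
    for t in terms:
        v = t.values
        if abs(v.mean()) > 1e-6 or abs(v.std() - 1.0) > 1e-6:
            warnings.warn(f"term map {t.name!r} is not z-scored; z-scoring on the fly",
                          stacklevel=2)
            v = (v - v.mean()) / v.std()
        fixed.append((t.name, v))
    rows = [(name, _corr(x, v, "pearson")) for name, v in fixed]
    df = pd.DataFrame(rows, columns=["term", "r"])
    # descending r, lexicographic names on exact ties
    df = df.sort_values(["r", "term"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    n_top = max(1, int(math.floor(top_fraction * len(df))))
    df["flagged"] = np.arange(len(df)) < n_top
    return df
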