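"""Spatial autocorrelation-preserving permutation nulls ("spin tests").

Correlations between cortical maps are tested against nulls that preserve
each map's spatial autocorrelation: the parcels' spherical coordinates are
randomly rotated and each original parcel is reassigned the value of the
closest rotated parcel by an optimal one-to-one matching (Hungarian
algorithm).  Rotations are drawn uniformly (orthonormalized Gaussian matrix
with determinant +1) and applied per hemisphere — the right hemisphere
receives the x-mirrored rotation so left/right spins stay congruent — and
matchings never cross the midline.  The p-value uses the (count + 1)/(n + 1)
estimator, so it is never exactly zero (floor 1/(n_spins + 1)).

Brainstem and midline nodes are never spun; maps involving them should use
parametric inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["SpinEnsemble", "generate_rotations", "spin_pvalue"]


@dataclass
class SpinEnsemble:
    """Hemisphere-closed permutations of the cortical nodes, one per spin."""

    permutations: np.ndarray = field(repr=False)  # (n_spins, n_cortex) int
    hemisphere: np.ndarray = field(repr=False)    # (n_cortex,) in {L, R}
    seed: int = 0

    @property
    def n_spins(self) -> int:
        return self.permutations.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.permutations.shape[1]

    def save(self, path) -> None:
        """Cache the ensemble to a binary sidecar file."""
        np.savez_compressed(path, permutations=self.permutations,
                            hemisphere=self.hemisphere.astype("U8"),
                            seed=np.int64(self.seed))

    @classmethod
    def load(cls, path) -> "SpinEnsemble":
        with np.load(path, allow_pickle=False) as data:
            return cls(permutations=data["permutations"],
                       hemisphere=data["hemisphere"],
                       seed=int(data["seed"]))

    def validate(self) -> None:
        """Assert every row is a within-hemisphere bijection."""
        idx = np.arange(self.n_nodes)
        for side in np.unique(self.hemisphere):
            members = idx[self.hemisphere == side]
            sub = self.permutations[:, members]
            if not np.all(np.sort(sub, axis=1) == members):
                raise AssertionError(f"spins are not closed bijections on "
                                     f"hemisphere {side!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation: QR of a Gaussian matrix, det +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def generate_rotations(geometry_or_nodes, n_spins: int = 10000,
                       seed: int = 0) -> SpinEnsemble:
    """Build a spin ensemble from cortical sphere coordinates.

    Accepts a SurfaceGeometry or NodeTable.  Per spin, one rotation is drawn
    and applied to the left hemisphere; its x-mirror conjugate is applied to
    the right; within each hemisphere the assignment minimizing total
    Euclidean distance between original and rotated parcel coordinates
    defines the permutation (original parcel i takes the value of rotated
    parcel perm[i]).
    """
    sphere, hemi = _cortex_sphere(geometry_or_nodes)
    if np.isnan(sphere).any():
        raise ValueError("sphere coordinates contain missing values")
    sides = {side: np.flatnonzero(hemi == side) for side in ("L", "R")}
    if any(v.size == 0 for v in sides.values()):
        raise ValueError("both hemispheres need cortical sphere coordinates")
    rng = np.random.default_rng(seed)
    n = sphere.shape[0]
    perms = np.empty((n_spins, n), dtype=np.int64)
    for k in range(n_spins):
        rot_l = _random_rotation(rng)
        rot_r = _MIRROR @ rot_l @ _MIRROR
        for side, rot in (("L", rot_l), ("R", rot_r)):
            members = sides[side]
            coords = sphere[members]
            rotated = coords @ rot.T
            cost = cdist(coords, rotated)
            _, col = linear_sum_assignment(cost)
            perms[k, members] = members[col]
    return SpinEnsemble(permutations=perms, hemisphere=hemi, seed=seed)


def _cortex_sphere(obj) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(obj, "sphere_coords"):  # NodeTable
        return obj.sphere_coords, obj.hemisphere[obj.cortex_idx]
    if hasattr(obj, "sphere_xyz"):     # SurfaceGeometry
        return obj.sphere_xyz, obj.hemisphere[obj.cortex_idx]
    raise TypeError("expected a NodeTable or SurfaceGeometry")


def _null_correlations(a: np.ndarray, b: np.ndarray, perms: np.ndarray,
                       method: str) -> np.ndarray:
    if method == "spearman":
        # ranks permute with the values, so rank once and correlate linearly
        a = stats.rankdata(a)
        b = stats.rankdata(b)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    return (az[perms] @ bz) / a.size


def spin_pvalue(observed_stat: float, map_a, map_b, ensemble: SpinEnsemble,
                method: str = "pearson",
                tails: str = "two") -> tuple[float, np.ndarray]:
    """Spin-test p-value for the correlation of two cortical maps.

    ``map_a`` (the first argument) is the rotated map by convention.  The
    observed statistic must equal the recomputed stat(map_a, map_b) within
    1e-10 — this guards against mixed-up inputs.  Returns (p, nulls).
    """
    a = np.asarray(getattr(map_a, "values", map_a), float)
    b = np.asarray(getattr(map_b, "values", map_b), float)
    if a.shape != b.shape or a.shape != (ensemble.n_nodes,):
        raise ValueError("maps must be defined on the ensemble's cortical nodes")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    recomputed = float(corr(a, b)[0])
    if abs(recomputed - observed_stat) > 1e-10:
        raise ValueError(f"observed statistic {observed_stat} does not match "
                         f"stat(map_a, map_b) = {recomputed}")
    nulls = _null_correlations(a, b, ensemble.permutations, method)
    if tails == "two":
        count = int(np.sum(np.abs(nulls) >= abs(observed_stat)))
    elif tails == "one":
        count = int(np.sum(nulls >= observed_stat)) if observed_stat >= 0 \
            else int(np.sum(nulls <= observed_stat))
    else:
        raise ValueError(f"tails must be 'two' or 'one', got {tails!r}")
    p = (1 + count) / (1 + ensemble.n_spins)
    return float(p), nulls
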