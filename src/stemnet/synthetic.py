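"""Synthetic brainstem-cortex datasets with planted, recoverable structure.

The generator emulates the data layout of a parcellated resting-state fMRI
study: 400 cortical parcels plus 58 brainstem nuclei, 20 subjects, three
concatenated runs of 210 volumes at TR = 2.5 s.  Subject time-series are
drawn from a zero-mean Gaussian latent-factor model

    x_t = L f_t + e_t,   f_t ~ N(0, diag(factor_sd^2)),   e_t ~ N(0, noise_sd^2 I)

whose implied covariance  Sigma = L diag(factor_sd^2) L' + noise_sd^2 I  embeds
three kinds of structure the downstream pipeline is designed to detect:

* a global factor loading on every node (``global_loading``) that induces the
  dominant weighted-degree pattern of brainstem-cortex coupling;
* one factor per brainstem community, loading on that community's nuclei and
  coupled to the cortex through that community's own smooth network map: a
  spatially autocorrelated pattern plus a bump centered on the community's
  position along the planted cortical axis.  The maps are mutually distinct
  (like real resting-state networks), so the communities are separable in
  the brainstem similarity matrix; their bump components order the networks
  along the axis, reinforcing the planted gradient.  The coupled cortical
  network of community k is the set of regions where its map dominates;
* a gradient factor with signed loadings spanning [-1, 1] on the cortex and
  community-centered signed loadings on the brainstem, tilting the whole
  cortex-brainstem block along the unimodal-transmodal-like axis.

Because the pipeline consumes only correlations, no temporal autocorrelation
is simulated: the effective number of samples equals ``n_timepoints``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import SubjectTimeSeries
from .nodes import BRAINSTEM, CORTEX, NodeTable

__all__ = [
    "SyntheticSpec",
    "SurfaceGeometry",
    "make_geometry",
    "sample_timeseries",
    "make_spatial_maps",
    "write_dataset",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Vector-valued fields default to ``None`` and are filled deterministically
    from ``seed`` by :meth:`realize` once the geometry exists; a realized spec
    is what :func:`sample_timeseries` consumes.
    """

    n_cortex: int = 400
    n_brainstem: int = 58
    n_subjects: int = 20
    n_timepoints: int = 630          # three concatenated 210-volume runs
    n_runs: int = 3
    tr: float = 2.5                  # seconds
    n_communities: int = 5
    community_labels: np.ndarray | None = None        # per brainstem node
    cortical_network_labels: np.ndarray | None = None  # per cortical node
    global_loading: np.ndarray | None = None           # per node, >= 0
    gradient_loading: np.ndarray | None = None         # per cortical node, signed
    gradient_brainstem_loading: np.ndarray | None = None  # per brainstem node, signed
    community_loading: float = 0.8
    community_bump_width: float = 0.18   # width of cortical coupling bumps (rank-space axis)
    network_map_noise: float = 0.4       # weight of the autocorrelated part of network maps
    network_map_smoothing_mm: float = 15.0  # spatial scale of that part
    network_maps: np.ndarray | None = None  # (n_cortex, n_communities) couplings
    gradient_h_scale: float = 0.2        # brainstem gradient loading amplitude
    gradient_h_jitter: float = 0.3       # within-community spread of that loading
    factor_sd: np.ndarray | None = None   # global, communities..., gradient
    noise_sd: float = 1.0
    baseline_mean: float = 100.0     # raw-signal offset, for tSNR checks
    smoothing_scale: float = 15.0    # mm, for surrogate annotation maps
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.n_cortex + self.n_brainstem

    @property
    def n_factors(self) -> int:
        return 2 + self.n_communities

    def validate(self) -> None:
        for name in ("n_cortex", "n_brainstem", "n_subjects", "n_timepoints",
                     "n_communities", "n_runs"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(self, name)}")
        if self.n_communities > self.n_brainstem:
            raise ValueError("n_communities cannot exceed n_brainstem")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.community_labels is not None:
            labels = np.asarray(self.community_labels)
            if labels.shape != (self.n_brainstem,):
                raise ValueError("community_labels length must equal n_brainstem")
            if len(np.unique(labels)) != self.n_communities:
                raise ValueError("community_labels must use exactly n_communities distinct values")
        if self.cortical_network_labels is not None:
            labels = np.asarray(self.cortical_network_labels)
            if labels.shape != (self.n_cortex,):
                raise ValueError("cortical_network_labels length must equal n_cortex")
        for name, size in (("global_loading", self.n_nodes),
                           ("gradient_loading", self.n_cortex),
                           ("gradient_brainstem_loading", self.n_brainstem)):
            vec = getattr(self, name)
            if vec is not None and np.asarray(vec).shape != (size,):
                raise ValueError(f"{name} must have length {size}")
        if self.global_loading is not None and np.any(np.asarray(self.global_loading) < 0):
            raise ValueError("global_loading must be nonnegative")

    def realize(self, nodes: NodeTable) -> "SyntheticSpec":
        """Return a copy with every vector field filled (deterministic in seed)."""
        self.validate()
        rng = np.random.default_rng([int(self.seed), 0xFAC])
        spec = dataclasses.replace(self)

        if spec.community_labels is None:
            spec.community_labels = _chunk_labels(spec.n_brainstem, spec.n_communities)
        if spec.gradient_loading is None:
            spec.gradient_loading = _default_axis(nodes)
        if spec.network_maps is None:
            centers = spec._community_centers()
            u = spec._axis_ranks()
            eta = _smooth_cortical_noise(nodes, spec.n_communities, rng,
                                         spec.network_map_smoothing_mm)
            w = float(spec.community_bump_width)
            order = np.argsort(centers)
            bumps = np.empty((spec.n_cortex, spec.n_communities))
            for k in range(spec.n_communities):
                bump = np.exp(-((u - centers[k]) ** 2) / (2.0 * w**2))
                # outermost bumps saturate past their center so the planted
                # axis stays monotone at the poles (no fold-back)
                if k == order[0]:
                    bump[u < centers[k]] = 1.0
                elif k == order[-1]:
                    bump[u > centers[k]] = 1.0
                bumps[:, k] = bump
            # the autocorrelated parts are orthogonalized against the bumps
            # and each other, so between-network map correlation is set by
            # the bump overlap alone, not by chance alignment of the noise
            basis, _ = np.linalg.qr(np.column_stack([bumps, eta]))
            eta_orth = basis[:, spec.n_communities:]
            eta_orth = (eta_orth - eta_orth.mean(axis=0)) / eta_orth.std(axis=0)
            maps = np.empty((spec.n_cortex, spec.n_communities))
            for k in range(spec.n_communities):
                xi = (bumps[:, k] / max(bumps[:, k].std(), 1e-12)
                      + spec.network_map_noise * eta_orth[:, k])
                maps[:, k] = (xi - xi.mean()) / xi.std()
            spec.network_maps = maps
        if spec.cortical_network_labels is None:
            spec.cortical_network_labels = np.argmax(spec.network_maps, axis=1)
        if spec.global_loading is None:
            spec.global_loading = rng.uniform(0.7, 1.3, size=spec.n_nodes)
        if spec.gradient_brainstem_loading is None:
            # nuclei scatter widely around their community's axis position:
            # the community mean stays small (so the gradient factor does not
            # couple adjacent communities' cortical profiles) while the
            # within-community spread orders nuclei along the axis
            centers = spec._community_centers()
            jitter = rng.uniform(-spec.gradient_h_jitter, spec.gradient_h_jitter,
                                 size=spec.n_brainstem)
            spec.gradient_brainstem_loading = np.clip(
                spec.gradient_h_scale * centers[np.asarray(spec.community_labels)]
                + jitter, -1.0, 1.0)
        if spec.factor_sd is None:
            spec.factor_sd = np.concatenate(
                [[0.9], np.full(spec.n_communities, 0.9), [1.2]])
        spec.factor_sd = np.asarray(spec.factor_sd, float)
        spec.factor_sd = np.asarray(spec.factor_sd, float)
        if spec.factor_sd.shape != (spec.n_factors,):
            raise ValueError(f"factor_sd must have length {spec.n_factors}")
        spec.validate()
        return spec

    def _axis_ranks(self) -> np.ndarray:
        """Rank-space version of the planted axis, uniform on [-1, 1]; bumps
        live here so community spacing does not depend on how the axis
        saturates."""
        t = np.asarray(self.gradient_loading, float)
        ranks = np.argsort(np.argsort(t))
        return 2.0 * ranks / max(t.size - 1, 1) - 1.0

    def _community_centers(self) -> np.ndarray:
        """Position of each community on the rank-space axis: evenly spaced
        by default, or the mean position of the coupled cortical network when
        custom network labels were supplied."""
        k = self.n_communities
        if self.cortical_network_labels is None:
            return -1.0 + (2.0 * np.arange(k) + 1.0) / k
        u = self._axis_ranks()
        nets = np.asarray(self.cortical_network_labels)
        return np.array([u[nets == j].mean() if np.any(nets == j) else 0.0
                         for j in range(k)])

    def loading_matrix(self) -> np.ndarray:
        """(n_nodes, n_factors) loading matrix L; requires a realized spec.

        Community factor k loads on its brainstem members (indicator with a
        mild multiplicative spread) and on the cortex through its z-scored
        network map.
        """
        if self.global_loading is None or self.network_maps is None:
            raise ValueError("spec must be realized before building loadings")
        L = np.zeros((self.n_nodes, self.n_factors))
        L[:, 0] = self.global_loading
        rng = np.random.default_rng([int(self.seed), 0xC0]).uniform
        bs0 = self.n_cortex
        for k in range(self.n_communities):
            col = 1 + k
            L[: self.n_cortex, col] = self.community_loading * self.network_maps[:, k]
            bs_members = np.flatnonzero(np.asarray(self.community_labels) == k)
            L[bs0 + bs_members, col] = self.community_loading * rng(0.95, 1.05, bs_members.size)
        L[: self.n_cortex, -1] = np.asarray(self.gradient_loading, float)
        L[bs0:, -1] = self.gradient_brainstem_loading
        return L

    def implied_covariance(self) -> np.ndarray:
        L = self.loading_matrix()
        sigma = (L * np.asarray(self.factor_sd) ** 2) @ L.T
        sigma[np.diag_indices_from(sigma)] += self.noise_sd**2
        return sigma


@dataclass
class SurfaceGeometry:
    """Node coordinates: centroids in mm for all nodes, unit-sphere
    projections for the cortical nodes only."""

    centroid_xyz: np.ndarray                 # (n, 3)
    sphere_xyz: np.ndarray                   # (n_cortex, 3), unit norm
    hemisphere: np.ndarray                   # (n,) in {L, R, midline}
    structure: np.ndarray = field(default=None)  # (n,) cortex/brainstem

    @property
    def cortex_idx(self) -> np.ndarray:
        return np.flatnonzero(self.structure == CORTEX)

    @property
    def brainstem_idx(self) -> np.ndarray:
        return np.flatnonzero(self.structure == BRAINSTEM)


def _chunk_labels(n: int, k: int) -> np.ndarray:
    """n labels in k near-equal contiguous chunks, every label used."""
    return np.minimum((np.arange(n) * k) // n, k - 1).astype(int)


def _default_axis(nodes: NodeTable, slope: float = 1.2) -> np.ndarray:
    """Planted cortical axis: tanh of the normalized z-coordinate, gently
    saturating toward +-1 so both poles are well populated without creating
    long runs of near-ties."""
    z = nodes.centroids[nodes.cortex_idx, 2]
    t = 2.0 * (z - z.min()) / max(float(np.ptp(z)), 1e-12) - 1.0
    return np.tanh(slope * t) / np.tanh(slope)


def _smooth_cortical_noise(nodes: NodeTable, n_maps: int,
                           rng: np.random.Generator,
                           scale_mm: float) -> np.ndarray:
    """Z-scored kernel-smoothed white noise on the cortical centroids."""
    coords = nodes.centroids[nodes.cortex_idx]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2.0 * scale_mm**2))
    eta = kernel @ rng.standard_normal((coords.shape[0], n_maps))
    return (eta - eta.mean(axis=0)) / eta.std(axis=0)


def _fibonacci_sphere(m: int) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice on the full unit sphere."""
    k = np.arange(m) + 0.5
    x = 1.0 - 2.0 * k / m          # uniform in (-1, 1): area-uniform
    r = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(m)
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


# each hemisphere is projected onto its own full sphere (the convention of
# surface-based spherical registration); in anatomical space the hemispheres
# sit side by side
HEMI_RADIUS_MM = 34.0
HEMI_CENTER_MM = {"L": np.array([-36.0, 0.0, 0.0]), "R": np.array([36.0, 0.0, 0.0])}
BRAINSTEM_CENTER_MM = np.array([0.0, -25.0, -45.0])


def make_geometry(spec: SyntheticSpec) -> tuple[SurfaceGeometry, NodeTable]:
    """Build node coordinates and the metadata table for a synthetic study.

    Cortical nodes are quasi-uniform on two mirror-symmetric hemispheric
    half-spheres (Fibonacci lattice plus a small seeded jitter); brainstem
    nodes form a compact inferior cluster with bilateral mirrored pairs and a
    midline remainder.
    """
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 0x6E0])

    n_left = (spec.n_cortex + 1) // 2
    n_right = spec.n_cortex - n_left
    left = _fibonacci_sphere(n_left)
    right = _fibonacci_sphere(n_right) * np.array([-1.0, 1.0, 1.0])  # mirror of left
    sphere = np.vstack([left, right])
    sphere = sphere + rng.normal(scale=0.01, size=sphere.shape)
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    ctx_hemi = np.array(["L"] * n_left + ["R"] * n_right)
    ctx_centroid = np.vstack([
        HEMI_CENTER_MM["L"] + HEMI_RADIUS_MM * sphere[:n_left],
        HEMI_CENTER_MM["R"] + HEMI_RADIUS_MM * sphere[n_left:]])

    n_mid = int(round(spec.n_brainstem * 8 / 58))
    if (spec.n_brainstem - n_mid) % 2:
        n_mid += 1
    n_mid = min(n_mid, spec.n_brainstem)
    n_pairs = (spec.n_brainstem - n_mid) // 2
    half = np.abs(rng.normal(scale=4.0, size=(n_pairs, 1))) + 1.0
    yz = rng.normal(scale=6.0, size=(n_pairs, 2))
    left_bs = np.column_stack([-half[:, 0], yz[:, 0], yz[:, 1]])
    right_bs = np.column_stack([half[:, 0], yz[:, 0], yz[:, 1]])
    mid_bs = np.column_stack([np.zeros(n_mid),
                              rng.normal(scale=6.0, size=(n_mid, 2))])
    bs_local = np.vstack([np.stack([left_bs, right_bs], axis=1).reshape(-1, 3),
                          mid_bs]) if n_pairs else mid_bs
    bs_centroid = BRAINSTEM_CENTER_MM + bs_local
    bs_hemi = np.array([h for _ in range(n_pairs) for h in ("L", "R")]
                       + ["midline"] * n_mid)

    structure = np.array([CORTEX] * spec.n_cortex + [BRAINSTEM] * spec.n_brainstem)
    centroid = np.vstack([ctx_centroid, bs_centroid])
    hemisphere = np.concatenate([ctx_hemi, bs_hemi])

    geometry = SurfaceGeometry(centroid_xyz=centroid, sphere_xyz=sphere,
                               hemisphere=hemisphere, structure=structure)

    names = ([f"ctx_{h}_{i:03d}" for i, h in enumerate(ctx_hemi)]
             + [f"bs_{h}_{i:02d}" for i, h in enumerate(bs_hemi)])
    sxyz = np.full((spec.n_nodes, 3), np.nan)
    sxyz[: spec.n_cortex] = sphere

    # network assignment mirrors SyntheticSpec.realize defaults exactly:
    # realize a throwaway copy against the coordinate table
    tmp = NodeTable(pd.DataFrame({
        "name": names, "structure": structure, "hemisphere": hemisphere,
        "x": centroid[:, 0], "y": centroid[:, 1], "z": centroid[:, 2]}))
    realized = spec.realize(tmp)
    network = np.concatenate([np.asarray(realized.cortical_network_labels),
                              np.asarray(realized.community_labels)])

    size_voxels = np.empty(spec.n_nodes)
    size_voxels[: spec.n_cortex] = np.round(rng.uniform(300, 900, spec.n_cortex))
    size_voxels[spec.n_cortex:] = np.round(
        np.exp(rng.uniform(np.log(10), np.log(1500), spec.n_brainstem)))

    # cytoarchitectonic / laminar classes binned along the planted axis so
    # class-wise contrasts exist by construction
    z_rank = np.argsort(np.argsort(centroid[: spec.n_cortex, 2]))
    class_laminar = np.full(spec.n_nodes, "", dtype=object)
    class_cyto = np.full(spec.n_nodes, "", dtype=object)
    class_laminar[: spec.n_cortex] = np.array(
        [f"lam{c}" for c in (z_rank * 4) // spec.n_cortex])
    class_cyto[: spec.n_cortex] = np.array(
        [f"cyto{c}" for c in (z_rank * 6) // spec.n_cortex])

    table = pd.DataFrame({
        "name": names,
        "structure": structure,
        "hemisphere": hemisphere,
        "x": centroid[:, 0], "y": centroid[:, 1], "z": centroid[:, 2],
        "sx": sxyz[:, 0], "sy": sxyz[:, 1], "sz": sxyz[:, 2],
        "size_voxels": size_voxels.astype(int),
        "class_laminar": class_laminar,
        "class_cyto": class_cyto,
        "network": network,
    })
    return geometry, NodeTable(table)


def sample_timeseries(spec: SyntheticSpec, geometry: SurfaceGeometry,
                      nodes: NodeTable | None = None,
                      demean: bool = True) -> list[SubjectTimeSeries]:
    """Draw per-subject time-series from the latent-factor model.

    Each "run" is an independent draw; runs are concatenated per subject.
    With ``demean=False`` the ``baseline_mean`` offset is retained, emulating
    raw signal for temporal-SNR computations.
    """
    if nodes is None and spec.gradient_loading is None:
        raise ValueError("spec must be realized (pass nodes or call spec.realize)")
    if spec.gradient_loading is None:
        spec = spec.realize(nodes)
    L = spec.loading_matrix() * np.asarray(spec.factor_sd)
    min_eig_bound = spec.noise_sd**2
    if min_eig_bound < 0:
        raise ValueError("implied covariance is not positive semidefinite")
    run_lengths = _run_lengths(spec.n_timepoints, spec.n_runs)
    subjects = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng([int(spec.seed), 1 + s])
        runs = []
        for t_run in run_lengths:
            f = rng.standard_normal((spec.n_factors, t_run))
            e = rng.standard_normal((spec.n_nodes, t_run)) * spec.noise_sd
            x = L @ f + e + spec.baseline_mean
            if demean:
                x = x - x.mean(axis=1, keepdims=True)
            runs.append(x)
        subjects.append(SubjectTimeSeries(subject_id=f"sub-{s:02d}",
                                          values=np.concatenate(runs, axis=1),
                                          tr=spec.tr))
    return subjects


def _run_lengths(total: int, n_runs: int) -> list[int]:
    base = total // n_runs
    lengths = [base] * n_runs
    for i in range(total - base * n_runs):
        lengths[i] += 1
    return lengths


def make_spatial_maps(geometry: SurfaceGeometry, n_maps: int,
                      smoothing_scale: float, seed: int) -> np.ndarray:
    """Spatially autocorrelated surrogate annotation maps on the cortex.

    Each map is Gaussian-kernel smoothing (scale ``smoothing_scale`` mm, on
    chordal centroid distance, within hemisphere — cortical smoothing does
    not cross the midline) of white noise, z-scored.  Returns an
    (n_cortex, n_maps) array of mutually independent maps.
    """
    if n_maps < 1:
        raise ValueError(f"n_maps must be >= 1, got {n_maps}")
    if smoothing_scale <= 0:
        raise ValueError(f"smoothing_scale must be > 0, got {smoothing_scale}")
    ctx = geometry.cortex_idx
    coords = geometry.centroid_xyz[ctx]
    hemi = geometry.hemisphere[ctx]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2.0 * smoothing_scale**2))
    kernel[hemi[:, None] != hemi[None, :]] = 0.0
    rng = np.random.default_rng(seed)
    maps = kernel @ rng.standard_normal((coords.shape[0], n_maps))
    maps -= maps.mean(axis=0)
    maps /= maps.std(axis=0)
    return maps


def write_dataset(out_dir, spec: SyntheticSpec, nodes: NodeTable,
                  timeseries: list[SubjectTimeSeries],
                  maps: np.ndarray | None = None) -> None:
    """Write the node table, per-subject time-series and optional annotation
    maps as delimited text under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes.to_tsv(out / "nodes.tsv")
    for ts in timeseries:
        np.savetxt(out / f"{ts.subject_id}_ts.tsv", ts.values, delimiter="\t")
    if maps is not None:
        cols = [f"map{i:03d}" for i in range(maps.shape[1])]
        pd.DataFrame(maps, columns=cols).to_csv(out / "maps.tsv", sep="\t",
                                                index=False)
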