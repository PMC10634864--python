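"""Synthetic geometry, time-series and surrogate map generation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import stemnet as sn


class TestGeometry:
    def test_counts_and_structure(self, small_spec, small_dataset):
        nodes = small_dataset["nodes"]
        assert len(nodes) == 78
        assert nodes.n_cortex == 60
        assert nodes.n_brainstem == 18
        assert set(nodes.hemisphere[nodes.cortex_idx]) == {"L", "R"}

    def test_default_shape_458_nodes(self):
        spec = sn.SyntheticSpec()
        geom, nodes = sn.make_geometry(spec)
        assert len(nodes) == 458 and nodes.n_cortex == 400
        assert geom.sphere_xyz.shape == (400, 3)

    def test_seeded_determinism(self, small_spec):
        g1, n1 = sn.make_geometry(small_spec)
        g2, n2 = sn.make_geometry(small_spec)
        assert np.array_equal(g1.centroid_xyz, g2.centroid_xyz)
        assert n1.table.equals(n2.table)

    def test_sphere_coords_unit_norm_and_separated(self):
        spec = sn.SyntheticSpec(n_cortex=10, n_brainstem=4, n_communities=2, seed=0)
        geom, nodes = sn.make_geometry(spec)
        norms = np.linalg.norm(geom.sphere_xyz, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)
        d = squareform(pdist(geom.sphere_xyz))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 0

    def test_mirror_symmetry_up_to_jitter(self):
        spec = sn.SyntheticSpec(n_cortex=40, n_brainstem=6, n_communities=2, seed=1)
        geom, nodes = sn.make_geometry(spec)
        hemi = nodes.hemisphere[nodes.cortex_idx]
        left = geom.sphere_xyz[hemi == "L"] * [-1, 1, 1]
        right = geom.sphere_xyz[hemi == "R"]
        assert np.allclose(left, right, atol=0.1)

    def test_invalid_counts_named(self):
        with pytest.raises(ValueError, match="n_subjects"):
            sn.make_geometry(sn.SyntheticSpec(n_subjects=0))
        with pytest.raises(ValueError, match="community_labels"):
            sn.SyntheticSpec(n_brainstem=5, n_communities=2,
                             community_labels=np.zeros(5, int)).validate()


class TestTimeSeries:
    def test_shapes_and_determinism(self, small_dataset, small_spec):
        tss = small_dataset["timeseries"]
        assert len(tss) == 4
        assert all(ts.values.shape == (78, 150) for ts in tss)
        again = sn.sample_timeseries(small_dataset["spec"], small_dataset["geometry"])
        assert np.array_equal(tss[0].values, again[0].values)
        assert tss[0].tr == small_spec.tr

    def test_demean_false_retains_baseline(self, small_dataset):
        raw = sn.sample_timeseries(small_dataset["spec"], small_dataset["geometry"],
                                   demean=False)
        assert raw[0].values.mean() == pytest.approx(100.0, abs=1.0)
        tsnr = sn.compute_tsnr(raw[0])
        assert np.all(tsnr > 0)

    def test_three_node_closed_form_correlation(self):
        # population r = l1 l2 / sqrt((l1^2 + psi)(l2^2 + psi)) for a
        # single unit-variance factor with loadings (1, 1, 0), noise 1
        spec = sn.SyntheticSpec(n_cortex=2, n_brainstem=1, n_subjects=1,
                                n_communities=1, noise_sd=1.0, seed=0,
                                global_loading=np.array([1.0, 1.0, 0.0]),
                                factor_sd=np.array([1.0, 0.0, 0.0]),
                                gradient_loading=np.zeros(2),
                                gradient_brainstem_loading=np.zeros(1),
                                network_maps=np.zeros((2, 1)),
                                cortical_network_labels=np.zeros(2, int),
                                community_labels=np.zeros(1, int))
        sigma = spec.implied_covariance()
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        assert corr[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert corr[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_implied_covariance_psd_floor(self, small_dataset):
        spec = small_dataset["spec"]
        eigs = np.linalg.eigvalsh(spec.implied_covariance())
        assert eigs.min() >= spec.noise_sd**2 * (1 - 1e-9)

    def test_group_fc_recovers_degree_pattern(self, small_dataset):
        from scipy import stats
        spec, nodes, fc = (small_dataset["spec"], small_dataset["nodes"],
                           small_dataset["fc"])
        deg = sn.weighted_degree(fc, nodes.cortex_idx, nodes.brainstem_idx)
        rho = stats.spearmanr(deg.values,
                              spec.global_loading[nodes.brainstem_idx])[0]
        assert rho > 0.8


class TestSpatialMaps:
    def test_zscored_within_tolerance(self, small_dataset):
        maps = sn.make_spatial_maps(small_dataset["geometry"], 5, 10.0, seed=0)
        assert np.allclose(maps.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(maps.std(axis=0), 1.0, atol=1e-12)

    def test_tiny_scale_behaves_like_white_noise(self, small_dataset):
        geom = small_dataset["geometry"]
        maps = sn.make_spatial_maps(geom, 200, smoothing_scale=1e-6, seed=1)
        coords = geom.centroid_xyz[geom.cortex_idx]
        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        j = int(np.argmin(d[0]))
        neighbor_corr = np.corrcoef(maps[0], maps[j])[0, 1]
        assert abs(neighbor_corr) < 0.2

    def test_moran_autocorrelation_increases_with_scale(self, small_dataset):
        geom = small_dataset["geometry"]
        coords = geom.centroid_xyz[geom.cortex_idx]
        d = squareform(pdist(coords))
        w = 1.0 / np.maximum(d, 1e-9)
        np.fill_diagonal(w, 0.0)

        def moran(x):
            xc = x - x.mean()
            return (len(x) / w.sum()) * (xc @ w @ xc) / (xc @ xc)

        morans = []
        for scale in (1.0, 5.0, 20.0):
            maps = sn.make_spatial_maps(geom, 20, scale, seed=2)
            morans.append(np.mean([moran(maps[:, k]) for k in range(20)]))
        assert morans[0] < morans[1] < morans[2]

    def test_argument_validation(self, small_dataset):
        geom = small_dataset["geometry"]
        with pytest.raises(ValueError, match="n_maps"):
            sn.make_spatial_maps(geom, 0, 10.0, seed=0)
        with pytest.raises(ValueError, match="smoothing_scale"):
            sn.make_spatial_maps(geom, 2, 0.0, seed=0)


class TestRealize:
    def test_labels_and_loadings_filled(self, small_dataset):
        spec = small_dataset["spec"]
        assert np.unique(spec.community_labels).size == 3
        assert spec.cortical_network_labels.shape == (60,)
        assert spec.global_loading.min() >= 0
        assert spec.gradient_loading.shape == (60,)
        assert abs(spec.gradient_loading.min() + spec.gradient_loading.max()) < 0.2

    def test_realize_idempotent_and_deterministic(self, small_spec, small_dataset):
        nodes = small_dataset["nodes"]
        a = small_spec.realize(nodes)
        b = small_spec.realize(nodes)
        assert np.array_equal(a.network_maps, b.network_maps)
        assert np.array_equal(a.global_loading, b.global_loading)

    def test_node_table_networks_match_realized_labels(self, small_dataset):
        nodes, spec = small_dataset["nodes"], small_dataset["spec"]
        assert np.array_equal(nodes.column("network")[nodes.cortex_idx],
                              spec.cortical_network_labels)
        assert np.array_equal(nodes.column("network")[nodes.brainstem_idx],
                              spec.community_labels)


def test_write_dataset_roundtrip(tmp_path, small_dataset):
    sn.write_dataset(tmp_path, small_dataset["spec"], small_dataset["nodes"],
                     small_dataset["timeseries"][:1])
    nodes2 = sn.NodeTable.from_tsv(tmp_path / "nodes.tsv")
    assert len(nodes2) == len(small_dataset["nodes"])
    loaded = np.loadtxt(tmp_path / "sub-00_ts.tsv")
    assert np.allclose(loaded, small_dataset["timeseries"][0].values, atol=1e-5)
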