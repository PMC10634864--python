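import numpy as np
import pandas as pd
import pytest

import stemnet as sn


@pytest.fixture(scope="session")
def small_spec():
    return sn.SyntheticSpec(n_cortex=60, n_brainstem=18, n_subjects=4,
                            n_timepoints=150, n_communities=3, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """Geometry, node table, realized spec, subject time-series and group FC
    for a reduced synthetic study shared across tests."""
    geom, nodes = sn.make_geometry(small_spec)
    spec = small_spec.realize(nodes)
    tss = sn.sample_timeseries(spec, geom)
    fc = sn.group_average([sn.compute_fc(ts) for ts in tss])
    return {"geometry": geom, "nodes": nodes, "spec": spec,
            "timeseries": tss, "fc": fc}


@pytest.fixture()
def tiny_nodes():
    """One cortical node, three brainstem nodes: the smallest table on which
    block operations are defined."""
    df = pd.DataFrame({
        "name": ["c0", "b0", "b1", "b2"],
        "structure": ["cortex", "brainstem", "brainstem", "brainstem"],
        "hemisphere": ["L", "midline", "midline", "midline"],
        "x": [0.0, 1.0, 2.0, 3.0],
        "y": 0.0, "z": 0.0,
        "size_voxels": [500, 10, 20, 30],
    })
    return sn.NodeTable(df)


def make_fc(values):
    return sn.ConnectivityMatrix(values=np.asarray(values, float))
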