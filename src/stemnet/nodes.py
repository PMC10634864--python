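"""Node metadata table: the canonical ordering every matrix in the pipeline follows.

Nodes are ordered cortex first, then brainstem (then any other structures).
All connectivity matrices, degree maps and annotation maps index into this
order; helpers here return the integer index sets the other modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CORTEX = "cortex"
BRAINSTEM = "brainstem"

_REQUIRED_COLUMNS = ("name", "structure", "hemisphere", "x", "y", "z")


@dataclass
class NodeTable:
    """Per-node metadata defining the canonical node order.

    Parameters
    ----------
    table
        One row per node. Required columns: ``name``, ``structure``
        (``cortex``/``brainstem``/...), ``hemisphere`` (``L``/``R``/``midline``)
        and centroid coordinates ``x, y, z`` in mm. Cortical rows additionally
        carry unit-sphere coordinates ``sx, sy, sz`` used by the spatial null
        model. Optional columns: ``size_voxels``, ``class_laminar``,
        ``class_cyto``, ``network``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"node table missing required column {col!r}")
        if df["name"].duplicated().any():
            dup = df["name"][df["name"].duplicated()].iloc[0]
            raise ValueError(f"node names must be unique (duplicate: {dup!r})")
        if (df["structure"].astype(str).str.len() == 0).any():
            raise ValueError("structure labels must be nonempty")
        df = df.reset_index(drop=True)
        if "node_id" in df.columns:
            if not np.array_equal(df["node_id"].to_numpy(), np.arange(len(df))):
                raise ValueError("node_id must be contiguous from 0 in table order")
        else:
            df.insert(0, "node_id", np.arange(len(df)))
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> np.ndarray:
        return self.table["name"].to_numpy()

    @property
    def structure(self) -> np.ndarray:
        return self.table["structure"].to_numpy()

    @property
    def hemisphere(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def cortex_idx(self) -> np.ndarray:
        return np.flatnonzero(self.structure == CORTEX)

    @property
    def brainstem_idx(self) -> np.ndarray:
        return np.flatnonzero(self.structure == BRAINSTEM)

    @property
    def n_cortex(self) -> int:
        return self.cortex_idx.size

    @property
    def n_brainstem(self) -> int:
        return self.brainstem_idx.size

    @property
    def centroids(self) -> np.ndarray:
        """(n, 3) centroid coordinates in mm."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    @property
    def sphere_coords(self) -> np.ndarray:
        """(n_cortex, 3) unit-sphere coordinates of the cortical nodes."""
        if not {"sx", "sy", "sz"}.issubset(self.table.columns):
            raise ValueError("node table carries no sphere coordinates")
        coords = self.table.loc[self.cortex_idx, ["sx", "sy", "sz"]].to_numpy(float)
        if np.isnan(coords).any():
            raise ValueError("sphere coordinates contain missing values")
        return coords

    def column(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"node table has no column {name!r}")
        return self.table[name].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NodeTable":
        return cls(pd.read_csv(path, sep="\t"))
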