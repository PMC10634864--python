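"""Delimited-text serialization helpers for matrices and maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_matrix", "read_matrix", "write_maps", "read_maps"]


def write_matrix(path, values: np.ndarray, names=None) -> None:
    """Dense matrix as TSV with node-name header and index; paths ending in
    ``.npz`` use the compact binary format instead."""
    path = Path(path)
    names = list(names) if names is not None else [str(i) for i in range(values.shape[0])]
    if path.suffix == ".npz":
        np.savez_compressed(path, values=values, names=np.array(names))
        return
    pd.DataFrame(values, index=names, columns=names).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            return data["values"], [str(n) for n in data["names"]]
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), list(df.columns)


def write_maps(path, maps: np.ndarray, names) -> None:
    """Node x map table with named columns."""
    pd.DataFrame(maps, columns=list(names)).to_csv(path, sep="\t", index=False)


def read_maps(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
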