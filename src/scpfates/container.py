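"""Layered count container and on-disk formats shared by every pipeline stage.

A :class:`CountContainer` holds one or more integer count layers over the same
cells × genes axes ("total" is mandatory; "spliced"/"unspliced" are optional),
a boolean spike-in flag per gene, and a per-cell metadata table.  On disk a
container is a directory of one MatrixMarket file per layer plus ``genes.tsv``,
``cells.tsv`` and a ``container.json`` manifest.  Matrices are stored with
cells as columns (genes × cells), the convention recorded in the manifest;
in-memory arrays are always cells × genes and 0-based.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountContainer",
    "ResultTable",
    "FormatError",
    "read_count_container",
    "write_count_container",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """Raised when an on-disk container violates the format contract."""


@dataclass
class CountContainer:
    """Cells × genes counts with named layers and cell metadata.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique string identifiers defining the row/column order of every layer.
    layers
        Mapping of layer name to a nonnegative integer ``(n_cells, n_genes)``
        sparse or dense matrix.  A ``"total"`` layer is required.
    ercc
        Boolean flag per gene marking exogenous spike-in controls.
    obs
        Per-cell metadata (stage label, plate, free-form columns), indexed by
        ``cell_ids``.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    layers: dict[str, sp.csr_matrix]
    ercc: np.ndarray
    obs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if "total" not in self.layers:
            raise FormatError("missing required layer 'total'")
        shape = (len(self.cell_ids), len(self.gene_ids))
        clean = {}
        for name, mat in self.layers.items():
            m = sp.csr_matrix(mat)
            if m.shape != shape:
                raise FormatError(
                    f"layer {name!r} has shape {m.shape}, expected {shape}"
                )
            if m.nnz and m.data.min() < 0:
                raise FormatError(f"layer {name!r} contains negative counts")
            m.data = m.data.astype(np.int64)
            clean[name] = m
        self.layers = clean
        self.ercc = np.asarray(self.ercc, dtype=bool)
        if self.ercc.shape != (len(self.gene_ids),):
            raise FormatError("ERCC flag length does not match gene ids")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.obs = self.obs.copy()
            self.obs.index = pd.Index(self.cell_ids, name="cell_id")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def layer(self, name: str) -> sp.csr_matrix:
        if name not in self.layers:
            raise FormatError(f"layer {name!r} not present in container")
        return self.layers[name]

    def subset_cells(self, index: np.ndarray) -> "CountContainer":
        """Return a new container restricted to the given cell positions."""
        index = np.asarray(index)
        return CountContainer(
            cell_ids=self.cell_ids[index],
            gene_ids=self.gene_ids,
            layers={k: v[index] for k, v in self.layers.items()},
            ercc=self.ercc,
            obs=self.obs.iloc[index],
        )


@dataclass
class ResultTable:
    """A keyed result table plus the provenance of the stage that made it."""

    table: pd.DataFrame
    stage: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise FormatError("result table row keys must be unique")

    def provenance(self) -> dict:
        return {
            "stage": self.stage,
            "params": dict(self.params),
            "seed": self.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }


def write_count_container(c: CountContainer, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, mat in c.layers.items():
        # genes x cells on disk (cells-as-columns), 1-based inside MTX
        scipy.io.mmwrite(str(path / f"{name}.mtx"), mat.T.tocoo(), field="integer")
    genes = pd.DataFrame({"gene_id": c.gene_ids, "ercc": c.ercc.astype(int)})
    genes.to_csv(path / "genes.tsv", sep="\t", index=False)
    cells = c.obs.reset_index()
    cells.to_csv(path / "cells.tsv", sep="\t", index=False)
    manifest = {
        "format": "scpfates-container",
        "version": 1,
        "orientation": "genes-by-cells",
        "layers": sorted(c.layers),
        "n_cells": c.n_cells,
        "n_genes": c.n_genes,
    }
    (path / "container.json").write_text(json.dumps(manifest, indent=2))


def read_count_container(path: str | Path) -> CountContainer:
    """Load a container directory written by :func:`write_count_container`.

    Round-trips losslessly for integer layers and metadata.  Raises
    :class:`FormatError` on missing "total" layer or inter-layer dimension
    mismatch.
    """
    path = Path(path)
    manifest_file = path / "container.json"
    if not manifest_file.exists():
        raise FormatError(f"no container.json manifest under {path}")
    manifest = json.loads(manifest_file.read_text())
    genes = pd.read_csv(path / "genes.tsv", sep="\t", dtype={"gene_id": str})
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    if genes["gene_id"].duplicated().any():
        raise FormatError("duplicate gene ids in genes.tsv")
    layers = {}
    for name in manifest["layers"]:
        mat = scipy.io.mmread(str(path / f"{name}.mtx"))
        layers[name] = sp.csr_matrix(mat.T)
    if "total" not in layers:
        raise FormatError("container is missing the required 'total' layer")
    shapes = {m.shape for m in layers.values()}
    if len(shapes) > 1:
        raise FormatError(f"layer dimension mismatch: {sorted(shapes)}")
    obs = cells.set_index("cell_id")
    return CountContainer(
        cell_ids=obs.index.to_numpy(dtype=object),
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        layers=layers,
        ercc=genes["ercc"].to_numpy(dtype=bool),
        obs=obs,
    )


def write_table(table: ResultTable, path: str | Path) -> None:
    """Write a result table as TSV with a provenance sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.table.to_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".prov.json")
    sidecar.write_text(json.dumps(table.provenance(), indent=2, default=str))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
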