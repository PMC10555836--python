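"""Readers and writers for count matrices, cell tables and gene sets.

Supported on-disk formats:

* spot data: MatrixMarket ``.mtx`` (genes x spots) with one-id-per-line
  ``genes.tsv`` / ``spots.tsv`` sidecars and a tab-separated coordinate table
  (``spot_id``, ``x``, ``y``), or a single HDF5 container with datasets
  ``/counts``, ``/genes``, ``/spots``, ``/coords``;
* cell tables: CSV/TSV with columns ``cell_id``, ``x``, ``y`` followed by one
  column per gene (counts);
* gene sets: JSON mapping of name -> gene list, or GMT
  (``name<TAB>description<TAB>gene...`` per line).

Curated dorsoventral neural-tube marker modules and the SHH target set used
as the radial-enrichment readout ship with the package; see
:func:`bundled_gene_sets`.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import CellTable, FormatError, GeneSet, SpotDataset

__all__ = [
    "read_spot_dataset",
    "write_spot_dataset",
    "read_cell_table",
    "write_cell_table",
    "read_gene_sets",
    "write_gene_sets",
    "bundled_gene_sets",
    "get_bundled_gene_set",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# spot datasets

def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing {what} sidecar: {path}")
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    # sidecars may carry extra tab-separated annotation columns; first wins
    return [ln.split("\t")[0] for ln in lines if ln]


def _read_coords_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise FormatError(f"coordinate table {path} needs spot_id, x, y columns")
    df = df.rename(columns={df.columns[0]: "spot_id", df.columns[1]: "x", df.columns[2]: "y"})
    df["spot_id"] = df["spot_id"].astype(str)
    return df.set_index("spot_id")


def read_spot_dataset(
    matrix_path: str | Path,
    coords_path: str | Path | None = None,
    *,
    genes_path: str | Path | None = None,
    spots_path: str | Path | None = None,
) -> SpotDataset:
    """Read a spot dataset from MTX + sidecars, or an HDF5 container.

    For MTX input the gene and spot id sidecars default to ``genes.tsv`` and
    ``spots.tsv`` next to the matrix, and ``coords_path`` is required. Spots
    that have no row in the coordinate table are dropped (the number dropped
    is logged); a coordinate row without a matching spot is ignored.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix.lower() in {".h5", ".hdf5"}:
        return _read_spot_h5(matrix_path)

    try:
        counts = spio.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on malformed MTX
        raise FormatError(f"could not parse MTX file {matrix_path}: {exc}") from exc
    counts = np.asarray(sparse.coo_matrix(counts).todense())
    if not np.issubdtype(counts.dtype, np.integer):
        if np.any(counts != np.floor(counts)):
            raise FormatError(f"{matrix_path} contains non-integer counts")
        counts = counts.astype(np.int64)
    if counts.size and counts.min() < 0:
        raise FormatError(f"{matrix_path} contains negative counts")

    genes_path = Path(genes_path) if genes_path else matrix_path.with_name("genes.tsv")
    spots_path = Path(spots_path) if spots_path else matrix_path.with_name("spots.tsv")
    gene_ids = _read_ids(genes_path, "gene id")
    spot_ids = _read_ids(spots_path, "spot id")
    if counts.shape != (len(gene_ids), len(spot_ids)):
        raise FormatError(
            f"matrix shape {counts.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(spot_ids)} spots)"
        )
    if coords_path is None:
        raise FormatError("coords_path is required for MTX input")
    coords_df = _read_coords_table(Path(coords_path))

    keep = [i for i, s in enumerate(spot_ids) if s in coords_df.index]
    n_dropped = len(spot_ids) - len(keep)
    if n_dropped:
        log.warning("dropping %d spot(s) without coordinates", n_dropped)
    kept_ids = [spot_ids[i] for i in keep]
    coords = coords_df.loc[kept_ids, ["x", "y"]].to_numpy(dtype=float)
    return SpotDataset(
        gene_ids=np.asarray(gene_ids, dtype=object),
        spot_ids=np.asarray(kept_ids, dtype=object),
        counts=counts[:, keep],
        coords=coords,
    )


def _read_spot_h5(path: Path) -> SpotDataset:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("counts", "genes", "spots", "coords"):
            if key not in f:
                raise FormatError(f"HDF5 container {path} missing /{key}")
        counts = f["counts"][...]
        genes = [g.decode() if isinstance(g, bytes) else str(g) for g in f["genes"][...]]
        spots = [s.decode() if isinstance(s, bytes) else str(s) for s in f["spots"][...]]
        coords = f["coords"][...]
    return SpotDataset(genes, spots, counts, coords)


def write_spot_dataset(data: SpotDataset, path: str | Path) -> None:
    """Write a spot dataset.

    ``.h5`` writes the single-file container; ``.mtx`` writes the matrix plus
    ``genes.tsv``, ``spots.tsv`` and ``coords.tsv`` sidecars alongside it.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=data.counts)
            f.create_dataset("genes", data=np.array([str(g) for g in data.gene_ids], dtype="S"))
            f.create_dataset("spots", data=np.array([str(s) for s in data.spot_ids], dtype="S"))
            f.create_dataset("coords", data=data.coords)
        return
    spio.mmwrite(str(path), sparse.coo_matrix(data.counts))
    path.with_name("genes.tsv").write_text("\n".join(map(str, data.gene_ids)) + "\n")
    path.with_name("spots.tsv").write_text("\n".join(map(str, data.spot_ids)) + "\n")
    pd.DataFrame(
        {"spot_id": data.spot_ids, "x": data.coords[:, 0], "y": data.coords[:, 1]}
    ).to_csv(path.with_name("coords.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell tables

def read_cell_table(path: str | Path) -> CellTable:
    """Read a segmented-cell table (CSV/TSV: cell_id, x, y, then genes).

    Coordinates are interpreted as micrometres. Duplicate cell ids and
    missing centroids are format errors; a table with zero gene columns is
    allowed but logged.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise FormatError(f"cell table {path} needs cell_id, x, y columns")
    cell_ids = df.iloc[:, 0].astype(str)
    if cell_ids.duplicated().any():
        raise FormatError(f"duplicate cell ids in {path}")
    centroids = df.iloc[:, 1:3].to_numpy(dtype=float)
    if np.any(~np.isfinite(centroids)):
        raise FormatError(f"NaN/non-finite centroid in {path}")
    gene_cols = list(df.columns[3:])
    if not gene_cols:
        log.warning("cell table %s has no gene columns", path)
    counts = df.iloc[:, 3:].to_numpy()
    if counts.size == 0:
        counts = counts.reshape(len(df), 0).astype(np.int64)
    return CellTable(
        cell_ids=cell_ids.to_numpy(dtype=object),
        centroids=centroids,
        counts=counts,
        gene_ids=np.asarray(gene_cols, dtype=object),
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(
        {"cell_id": table.cell_ids, "x": table.centroids[:, 0], "y": table.centroids[:, 1]}
    )
    for j, g in enumerate(table.gene_ids):
        df[str(g)] = table.counts[:, j]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# gene sets

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read named gene lists from a JSON mapping or a GMT file."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = []
        for ln in path.read_text().splitlines():
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line needs name, description, >=1 gene: {ln!r}")
            sets.append(GeneSet(fields[0], tuple(g for g in fields[2:] if g)))
        return sets
    payload = json.loads(path.read_text())
    if isinstance(payload, dict):
        return [GeneSet(name, tuple(genes)) for name, genes in payload.items()]
    if isinstance(payload, list):
        return [GeneSet(d["name"], tuple(d["genes"])) for d in payload]
    raise FormatError(f"unrecognized gene-set JSON structure in {path}")


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        lines = ["\t".join([gs.name, "-", *gs.genes]) for gs in sets]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps({gs.name: list(gs.genes) for gs in sets}, indent=1))


def bundled_gene_sets() -> list[GeneSet]:
    """The curated gene sets shipped with the package.

    ``shh_set`` is the SHH-and-targets readout for the radial enrichment
    analysis; ``shh_module`` and the dorsoventral domain lists (floor plate
    through roof plate) are the module-scoring marker sets.
    """
    payload = json.loads(
        resources.files("optopattern").joinpath("resources/gene_sets.json").read_text()
    )
    return [GeneSet(name, tuple(genes)) for name, genes in payload.items()]


def get_bundled_gene_set(name: str) -> GeneSet:
    for gs in bundled_gene_sets():
        if gs.name == name:
            return gs
    known = [gs.name for gs in bundled_gene_sets()]
    raise KeyError(f"no bundled gene set {name!r}; available: {known}")
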