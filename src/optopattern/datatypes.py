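"""Shared domain containers for spatial induction analysis.

Two kinds of spatial data are modelled: spot-level capture data (a genes x
spots integer count matrix with one planar coordinate per spot, as produced
by barcoded-spot spatial transcriptomics) and segmented-cell molecule data
(per-cell centroids in micrometres with per-gene molecule counts, as produced
by single-molecule FISH segmentation). Gene sets are simple named lists of
gene identifiers; analysis defaults live in :class:`AnalysisConfig`.

Coordinates are unitless planar values: radial breakpoints are interpreted in
whatever units the coordinates are supplied in (the synthetic generator uses
micrometres throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "GeneSet",
    "SpotDataset",
    "CellTable",
    "AnalysisConfig",
]


class FormatError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


def _as_id_array(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1:
        raise FormatError(f"{what} must be a 1-D sequence")
    if len(set(arr)) != len(arr):
        dupes = [x for x in arr if list(arr).count(x) > 1]
        raise FormatError(f"duplicate {what}: {sorted(set(dupes))[:5]}")
    return arr


def _validate_counts(counts: np.ndarray, what: str) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise FormatError(f"{what} counts must be a 2-D matrix")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(np.isfinite(counts)) or not np.all(counts == np.floor(counts)):
            raise FormatError(f"{what} counts must be integers")
        counts = counts.astype(np.int64)
    if counts.size and counts.min() < 0:
        raise FormatError(f"{what} counts must be non-negative")
    return counts


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def match(self, panel: Sequence[str], case_insensitive: bool = False) -> list[str]:
        """Return the panel gene ids matched by this set.

        Matching is exact and case-sensitive by default; with
        ``case_insensitive=True`` a fallback case-folded lookup is used.
        The returned ids are panel ids (useful when cases differ).
        """
        panel_set = set(panel)
        hits = [g for g in self.genes if g in panel_set]
        if case_insensitive:
            folded = {p.casefold(): p for p in panel}
            for g in self.genes:
                if g not in panel_set and g.casefold() in folded:
                    hits.append(folded[g.casefold()])
        return hits


@dataclass
class SpotDataset:
    """Genes x spots count matrix with per-spot planar coordinates.

    Parameters
    ----------
    gene_ids, spot_ids
        Ordered unique identifiers for the matrix axes.
    counts
        Non-negative integer matrix of shape ``(n_genes, n_spots)``.
    coords
        Array of shape ``(n_spots, 2)`` with finite planar positions.
    """

    gene_ids: np.ndarray
    spot_ids: np.ndarray
    counts: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _as_id_array(self.gene_ids, "gene ids")
        self.spot_ids = _as_id_array(self.spot_ids, "spot ids")
        self.counts = _validate_counts(self.counts, "spot")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if self.coords.shape != (len(self.spot_ids), 2):
            raise FormatError("coords must have shape (n_spots, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("spot coordinates must be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._spot_index = {s: i for i, s in enumerate(self.spot_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in panel") from None

    def spot_position(self, spot_id: str) -> np.ndarray:
        try:
            return self.coords[self._spot_index[spot_id]]
        except KeyError:
            raise KeyError(f"unknown spot id {spot_id!r}") from None

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.asarray([self.gene_index(g) for g in genes], dtype=int)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (spots as observations)."""
        import anndata
        import pandas as pd
        from scipy import sparse

        ad = anndata.AnnData(
            X=sparse.csr_matrix(self.counts.T),
            obs=pd.DataFrame(index=list(self.spot_ids)),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )
        ad.obsm["spatial"] = self.coords.copy()
        return ad


@dataclass
class CellTable:
    """Segmented cells with centroid coordinates (um) and molecule counts.

    ``counts`` is cells x genes (one row per cell), the transpose of the
    spot-data convention, mirroring how segmentation pipelines export
    per-cell tables.
    """

    cell_ids: np.ndarray
    centroids: np.ndarray
    counts: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _as_id_array(self.cell_ids, "cell ids")
        self.gene_ids = _as_id_array(self.gene_ids, "gene ids")
        self.counts = _validate_counts(self.counts, "cell")
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape != (len(self.cell_ids), 2):
            raise FormatError("centroids must have shape (n_cells, 2)")
        if not np.all(np.isfinite(self.centroids)):
            raise FormatError("cell centroids must be finite")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_counts(self, gene: str) -> np.ndarray:
        try:
            return self.counts[:, self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in panel") from None

    def to_anndata(self):
        import anndata
        import pandas as pd

        ad = anndata.AnnData(
            X=self.counts.astype(float),
            obs=pd.DataFrame(index=list(self.cell_ids)),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )
        ad.obsm["spatial"] = self.centroids.copy()
        return ad


#: Radial breakpoints (inner six boundaries; the seventh bin is everything
#: beyond the last breakpoint) used for the concentric-annulus analysis.
DEFAULT_BREAKPOINTS: tuple[float, ...] = (500.0, 775.0, 1050.0, 1325.0, 1600.0, 1825.0)


@dataclass
class AnalysisConfig:
    """Defaults for the spatial induction analyses.

    ``radii_breakpoints`` partition spots into concentric annuli (the
    outermost bin is open beyond the last breakpoint). ``count_threshold``
    is the minimum molecule count for calling a cell positive for a
    transcript. ``umi_min`` / ``mito_max_fraction`` are the expression QC
    cutoffs (keep cells with strictly more than ``umi_min`` total counts and
    strictly less than ``mito_max_fraction`` mitochondrial content).
    """

    radii_breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS
    n_permutations: int = 1000
    count_threshold: int = 5
    umi_min: int = 800
    mito_max_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bp = np.asarray(self.radii_breakpoints, dtype=float)
        if bp.ndim != 1 or len(bp) < 1:
            raise ValueError("radii_breakpoints must be a non-empty sequence")
        if bp[0] <= 0 or np.any(np.diff(bp) <= 0):
            raise ValueError("radii_breakpoints must be positive and strictly increasing")
        self.radii_breakpoints = tuple(bp)
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.count_threshold < 1:
            raise ValueError("count_threshold must be positive")
        if self.umi_min < 1:
            raise ValueError("umi_min must be positive")
        if not 0.0 <= self.mito_max_fraction <= 1.0:
            raise ValueError("mito_max_fraction must be in [0, 1]")
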