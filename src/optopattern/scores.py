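"""Expression QC, normalization and gene-module scoring.

QC keeps cells with strictly more than a UMI floor (default 800) and
strictly less than a mitochondrial-fraction ceiling (default 5%,
mitochondrial genes recognized by an ``MT-`` prefix or an explicit list).
Counts are then depth-normalized to a fixed target sum per cell and
log1p-transformed.

Module scores follow the binned-control scheme popularized by single-cell
toolkits: panel genes are ranked by dataset-average expression and split
into equal-frequency bins; for every module gene, control genes are sampled
from its bin; the score of a cell is the mean expression of the module genes
minus the mean expression of the pooled control genes. Scores are therefore
centred near zero for a random gene set and positive in cells where the
module is coherently elevated. The bin count (25) and controls per gene
(100) are the scheme's conventional defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import CellTable, GeneSet

__all__ = [
    "QCReport",
    "qc_filter",
    "log_normalize",
    "ModuleScoreResult",
    "module_score",
    "score_modules",
]


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_fail_umi: int
    n_fail_mito: int
    n_kept: int


def qc_filter(
    table: CellTable,
    umi_min: int = 800,
    mito_max: float = 0.05,
    mito_prefix: str = "MT-",
    mito_genes: Optional[Sequence[str]] = None,
) -> tuple[CellTable, QCReport]:
    """Keep cells with total counts > ``umi_min`` and mito fraction < ``mito_max``.

    Both cutoffs are strict. With no mitochondrial genes in the panel the
    mito fraction is zero for every cell and only the UMI rule applies. The
    report counts failures per rule (a cell may fail both).
    """
    if mito_genes is None:
        mito_cols = np.array([str(g).startswith(mito_prefix) for g in table.gene_ids])
    else:
        mito_set = set(mito_genes)
        mito_cols = np.array([g in mito_set for g in table.gene_ids])
    totals = table.counts.sum(axis=1)
    mito_counts = table.counts[:, mito_cols].sum(axis=1) if mito_cols.any() else np.zeros(table.n_cells)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    pass_umi = totals > umi_min
    pass_mito = mito_frac < mito_max
    keep = pass_umi & pass_mito
    report = QCReport(
        n_input=table.n_cells,
        n_fail_umi=int((~pass_umi).sum()),
        n_fail_mito=int((~pass_mito).sum()),
        n_kept=int(keep.sum()),
    )
    filtered = CellTable(
        cell_ids=table.cell_ids[keep],
        centroids=table.centroids[keep],
        counts=table.counts[keep],
        gene_ids=table.gene_ids,
    )
    return filtered, report


def log_normalize(counts, target_sum: float = 1e4) -> np.ndarray:
    """Depth-normalize each cell to ``target_sum`` total counts, then log1p.

    Accepts a cells x genes array or a :class:`CellTable`; cells with zero
    total counts stay all-zero. Scaling a cell's counts by any constant
    leaves its normalized vector unchanged.
    """
    if isinstance(counts, CellTable):
        counts = counts.counts
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, x / totals * target_sum, 0.0)
    return np.log1p(scaled)


@dataclass
class ModuleScoreResult:
    module: str
    scores: np.ndarray  # one score per cell
    genes_used: tuple[str, ...]
    control_genes: tuple[str, ...]


def _expression_bins(avg: np.ndarray, gene_ids: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency expression bins; ties broken by gene id for determinism."""
    n = len(avg)
    order = np.lexsort((np.asarray(gene_ids, dtype=str), avg))
    n_bins = min(n_bins, n)
    bin_id = np.empty(n, dtype=int)
    bin_id[order] = (np.arange(n) * n_bins) // n
    return bin_id


def module_score(
    normalized: np.ndarray,
    gene_ids: Sequence[str],
    gene_set: GeneSet,
    *,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Score a gene module per cell against expression-matched controls.

    ``normalized`` is cells x genes (log-normalized). For every module gene
    present in the panel, ``n_ctrl`` control genes (or the whole bin, if
    smaller) are sampled without replacement from its expression bin; the
    score is mean(module genes) - mean(pooled control genes), per cell.
    Deterministic under ``seed``.
    """
    gene_ids = np.asarray(list(gene_ids), dtype=object)
    normalized = np.asarray(normalized, dtype=float)
    if normalized.shape[1] != len(gene_ids):
        raise ValueError("normalized matrix width must match gene_ids")
    index = {g: i for i, g in enumerate(gene_ids)}
    module_idx = np.array([index[g] for g in gene_set.genes if g in index], dtype=int)
    if module_idx.size == 0:
        raise ValueError(f"no gene of module {gene_set.name!r} is in the panel")

    rng = np.random.default_rng(seed)
    avg = normalized.mean(axis=0)
    bin_id = _expression_bins(avg, gene_ids, n_bins)

    ctrl: set[int] = set()
    for g in module_idx:
        pool = np.flatnonzero(bin_id == bin_id[g])
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl), dtype=int)

    scores = normalized[:, module_idx].mean(axis=1) - normalized[:, ctrl_idx].mean(axis=1)
    return ModuleScoreResult(
        module=gene_set.name,
        scores=scores,
        genes_used=tuple(gene_ids[module_idx]),
        control_genes=tuple(gene_ids[ctrl_idx]),
    )


def score_modules(
    table: CellTable,
    modules: Sequence[GeneSet],
    *,
    target_sum: float = 1e4,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> dict[str, ModuleScoreResult]:
    """Log-normalize a cell table and score several modules.

    Each module gets an independent RNG stream derived from ``seed`` so that
    adding or removing modules does not perturb the others' scores.
    """
    norm = log_normalize(table, target_sum=target_sum)
    children = np.random.SeedSequence(seed).spawn(len(modules))
    out = {}
    for gs, child in zip(modules, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out[gs.name] = module_score(
            norm, table.gene_ids, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=sub_seed
        )
    return out
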