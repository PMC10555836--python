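import numpy as np
import pytest

from optopattern import CellTable, GeneSet, SpotDataset


@pytest.fixture
def tiny_spots() -> SpotDataset:
    """3 genes x 4 spots on a line, hand-checkable counts."""
    counts = np.array(
        [
            [8, 2, 1, 1],
            [0, 5, 5, 0],
            [2, 3, 4, 9],
        ]
    )
    coords = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0], [300.0, 0.0]])
    return SpotDataset(["GA", "GB", "GC"], ["s1", "s2", "s3", "s4"], counts, coords)


@pytest.fixture
def small_cells() -> CellTable:
    """Source cell at the origin plus targets on 3-4-5 triangles."""
    cell_ids = ["src", "t1", "t2", "far"]
    centroids = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0], [100.0, 0.0]])
    #             SHH  FOXA2
    counts = np.array([[9, 0], [0, 5], [0, 7], [1, 1]])
    return CellTable(cell_ids, centroids, counts, ["SHH", "FOXA2"])


def random_spot_dataset(rng: np.random.Generator, n_genes=6, n_spots=12) -> SpotDataset:
    counts = rng.integers(0, 30, size=(n_genes, n_spots))
    coords = rng.uniform(-500, 500, size=(n_spots, 2))
    genes = [f"g{i}" for i in range(n_genes)]
    spots = [f"s{i}" for i in range(n_spots)]
    return SpotDataset(genes, spots, counts, coords)


def random_cell_table(rng: np.random.Generator, n_cells=20, n_genes=4) -> CellTable:
    counts = rng.integers(0, 12, size=(n_cells, n_genes))
    centroids = rng.uniform(0, 300, size=(n_cells, 2))
    return CellTable(
        [f"c{i}" for i in range(n_cells)],
        centroids,
        counts,
        [f"g{i}" for i in range(n_genes)],
    )
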