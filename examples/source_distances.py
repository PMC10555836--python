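"""Distance of expressing cells to the nearest source cell.

Simulates a segmented-cell section with a source-cell pole (high SHH) and
two genes expressed in rings at 50 um and 200 um from the pole, then
computes, for every cell with >= 5 molecules of each gene, the Euclidean
distance to the nearest SHH+ cell.
"""

from optopattern import (
    distance_to_nearest_source,
    generate_cell_table,
    summarize_distances,
)

cells = generate_cell_table(
    3000, source_pole=(0.0, 0.0),
    ring_genes=[("FOXA1", 0.0, 60.0), ("NKX2-2", 50.0, 40.0), ("PAX6", 200.0, 40.0)],
    rng_seed=1,
)

results = [
    distance_to_nearest_source(cells, gene, source_gene="SHH", threshold=5)
    for gene in ("FOXA1", "NKX2-2", "PAX6")
]
print(summarize_distances(results).to_string(index=False))

# Genes confined to the source cells themselves (FOXA1-like) show near-zero
# medians because a dual-positive cell is its own nearest source; ring genes
# recover their ring radii minus the source-pole spread, preserving the
# near < far ordering.
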