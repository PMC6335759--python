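"""Neighbor frequencies on a Voronoi-adjacency graph.

Reproduces the textbook single-cell examples (5, 8 and 13 neighbors) and
then summarizes a whole synthetic region: mean +/- SD neighbor frequency
for every ordered phenotype pair, plus densities in cells/mm^2.
"""

from cellsoc import (
    CD3_CD8_T,
    UNSTAINED,
    TissueModel,
    build_graph,
    generate_tissue,
    neighbor_frequency,
    ring_tissue,
    summarize,
)

cells, roi, focal = ring_tissue(["red", "blue", "yellow", "yellow", "yellow"], "red")
g = build_graph(cells, roi)
print("focal cell with 5 neighbors (1 red, 1 blue, 3 yellow):")
for phen in ("red", "blue", "yellow"):
    print(f"  f({phen}) = {neighbor_frequency(g, cells, focal, phen):.3f}")
# 0.200 / 0.200 / 0.600 — each neighbor contributes 1/5.

model = TissueModel(
    n_cells=300,
    proportions={UNSTAINED: 0.85, CD3_CD8_T: 0.15},
    regime="infiltrated",
    mixing_fraction=0.6,
    seed=7,
)
cells, roi = generate_tissue(model)
g = build_graph(cells, roi)
res = summarize(g, cells, phenotypes=(UNSTAINED, CD3_CD8_T))
print("\nregion summary (infiltrated cytotoxic T cells):")
print(res.frequencies.to_string(index=False))
print(res.densities.to_string(index=False))
# f(UNSTAINED -> CD3_CD8_T) is the tumor-immune contact metric: the mean
# fraction of a tumor cell's Voronoi neighbors that are cytotoxic T cells.
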