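"""Build and inspect a read-overlap graph on a toy dataset.

Tiles error-free reads across one random genome so consecutive reads
overlap by a known number of bases, then shows that the edge weight
between two reads equals the dot product of their k-mer composition
vectors — for error-free reads with distinct k-mers, simply the count of
shared k-mers (overlap - k + 1).
"""

import numpy as np

from clior import Read, build_graph, build_index, edge_weights_for_read
from clior.synthetic import random_genome

rng = np.random.default_rng(7)
genome = random_genome(2_000, rng)

step, length, k, m = 40, 80, 30, 5
reads = [
    Read(f"tile_{i}", genome[pos : pos + length])
    for i, pos in enumerate(range(0, len(genome) - length + 1, step))
]
graph = build_graph(reads, k=k, m=m)
print(f"{len(reads)} tiled reads, {graph.n_edges} edges (k={k}, m={m})")
print(f"consecutive reads overlap by {length - step} bases "
      f"-> expect {length - step - k + 1} shared {k}-mers")
print(f"weight(tile_0, tile_1) = {graph.weight(0, 1)}")
print(f"weight(tile_0, tile_2) = {graph.weight(0, 2)}  (overlap 0 < m: no edge)")

# the inverted-index route gives the same sparse weights row by row
index = build_index(reads, k=k)
row = edge_weights_for_read(0, index, reads)
print(f"sparse weight row of tile_0: {dict(sorted(row.items()))}")
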