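"""Grouping diagnostics: size, independent sets, and species purity.

Partitions a two-species community into overlap groups and reports how
pure the groups are (fraction of multi-read groups whose members all come
from one species) — the property the majority vote relies on — plus the
group-size cap at work: each group's independent-set length stays below
T + one read length.
"""

from clior import CommunitySpec, build_graph, partition_graph, simulate_community
from clior.synthetic import GenomeSpec

spec = CommunitySpec(
    genomes=[
        GenomeSpec("species_A", "genus_A", 50_000),
        GenomeSpec("species_B", "genus_B", 50_000),
    ],
    abundances=[0.5, 0.5],
    n_reads=8_000,
    error_rate=0.01,
    seed=3,
)
reads, truth, _ = simulate_community(spec)
read_ids = [r.read_id for r in reads]

T = 9000
graph = build_graph(reads, k=30, m=5)
partition = partition_graph(graph, reads, T=T)

multi = [g for g in partition if len(g) > 1]
pure = sum(1 for g in multi if len({truth[read_ids[i]] for i in g.members}) == 1)
sizes = sorted(len(g) for g in partition)
print(f"{len(partition)} groups ({len(multi)} with >1 read); "
      f"largest {sizes[-1]} reads, median {sizes[len(sizes) // 2]}")
print(f"single-species fraction of multi-read groups: {pure / len(multi):.4f}")
print(f"max independent-set length: {max(g.independent_length for g in partition)} "
      f"(cap T={T} + one read)")
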