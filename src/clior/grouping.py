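"""Greedy partition of the overlap graph into small high-purity groups.

Starting from a seed read, the group repeatedly absorbs the frontier
candidate (an unvisited non-member neighbor of the group) with the most
edges into the current members.  Because overlapping reads double-count
sequence, group *size* is measured on a greedily maintained independent
set I(G): a member joins I(G) when it is adjacent to no current I(G) read,
and growth stops once the summed length of I(G) reaches T.  The cap keeps
groups from bridging two species connected by a few spurious edges.
Exhausted seeds are taken in read-index order until every read is grouped.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io import Read


@dataclass
class ReadGroup:
    """A group of reads with its greedy independent set.

    ``members`` is in insertion (growth) order; ``independent`` is the
    subset forming the greedy independent set I(G), whose summed read
    length ``independent_length`` is the group's effective size.
    """

    group_id: int
    members: list[int] = field(default_factory=list)
    independent: set[int] = field(default_factory=set)
    independent_length: int = 0

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Partition:
    """Disjoint cover of all reads by groups."""

    groups: list[ReadGroup] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    def membership(self) -> dict[int, int]:
        """Map read index -> group id."""
        return {i: g.group_id for g in self.groups for i in g.members}

    def write(self, path: str | Path, read_ids: Sequence[str] | None = None) -> None:
        """TSV export: ``group_id<TAB>read_id<TAB>in_independent_set``."""
        with open(path, "w") as out:
            out.write("group_id\tread_id\tin_independent_set\n")
            for group in self.groups:
                for i in group.members:
                    rid = read_ids[i] if read_ids is not None else str(i)
                    out.write(f"{group.group_id}\t{rid}\t{int(i in group.independent)}\n")


def grow_group(
    seed: int,
    graph,
    reads: Sequence[Read],
    T: int,
    visited: set[int],
    group_id: int = 0,
) -> ReadGroup:
    """Grow one group from a seed by greedy frontier absorption.

    One node is added per iteration: the unvisited non-member neighbor with
    the greatest *number* of edges into the current members (ties break to
    the lowest read index).  Edges to visited nodes of other groups do not
    score.  The added read joins I(G) when adjacent to none of its members.
    Growth stops when I(G)'s total length reaches T or the frontier
    empties; members are then marked visited.
    """
    if seed in visited:
        raise ValueError(f"seed {seed} already visited")
    adjacency = graph.adjacency()
    group = ReadGroup(group_id=group_id, members=[seed], independent={seed})
    group.independent_length = reads[seed].length
    in_group = {seed}
    # lazy max-heap of (-edge count, candidate); stale entries skipped on pop
    edge_count: dict[int, int] = {}
    heap: list[tuple[int, int]] = []

    def _push_neighbors(node: int) -> None:
        for nb in adjacency[node]:
            if nb in in_group or nb in visited:
                continue
            edge_count[nb] = edge_count.get(nb, 0) + 1
            heapq.heappush(heap, (-edge_count[nb], nb))

    _push_neighbors(seed)
    while group.independent_length < T and heap:
        neg, candidate = heapq.heappop(heap)
        if candidate in in_group or edge_count.get(candidate) != -neg:
            continue  # stale or already absorbed
        del edge_count[candidate]
        group.members.append(candidate)
        in_group.add(candidate)
        if not any(nb in group.independent for nb in adjacency[candidate]):
            group.independent.add(candidate)
            group.independent_length += reads[candidate].length
        _push_neighbors(candidate)
    visited.update(in_group)
    return group


def partition_graph(graph, reads: Sequence[Read], T: int = 9000) -> Partition:
    """Partition every read into exactly one group.

    Seeds are taken in canonical read-index order among unvisited reads, so
    the result is deterministic for a fixed graph.  Isolated reads become
    singleton groups.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    visited: set[int] = set()
    partition = Partition()
    for seed in range(graph.n_reads):
        if seed in visited:
            continue
        group = grow_group(seed, graph, reads, T, visited, group_id=len(partition.groups))
        partition.groups.append(group)
    return partition
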