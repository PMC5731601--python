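"""Majority-consensus re-labeling of read groups.

Each labeled member of a group casts one vote for its taxon; UNASSIGNED
members do not vote (a single labeled read out-votes any number of
unassigned ones — the whole point is shrinking the unassigned set).  Ties
between maximal labels are broken uniformly at random with a generator
seeded per (run seed, group id), so results are reproducible and
independent of group processing order.  With re-assignment on (the default)
the winner overwrites every member's label; with it off only unassigned
members are filled in.
"""

from __future__ import annotations

import json
import random
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .grouping import Partition, ReadGroup
from .io import UNASSIGNED, AssignmentTable


@dataclass
class VoteResult:
    """Outcome of one group's vote."""

    group_id: int
    winner: object  # taxon label or UNASSIGNED
    tally: dict
    tie: bool


def _tie_rng(rng_seed: int, group_id: int) -> random.Random:
    # order-independent per-group stream; keep the derived seed in 31 bits
    return random.Random((rng_seed * 1_000_003 + group_id) & 0x7FFFFFFF)


def vote_group(
    group: ReadGroup,
    table: AssignmentTable,
    read_ids,
    rng_seed: int = 0,
) -> VoteResult:
    """Majority consensus vote over one group.

    ``read_ids`` maps read index -> read id (the table is keyed by id).
    Winner is the unique max-count label; among tied maxima a seeded
    uniform choice.  A group with no labeled member wins UNASSIGNED.
    A tie is only declared between >= 2 distinct max-count labels.
    """
    tally: Counter = Counter()
    for idx in group.members:
        rid = read_ids[idx]
        if rid not in table:
            raise KeyError(f"group member {rid!r} missing from assignment table")
        label = table[rid]
        if label is not UNASSIGNED:
            tally[label] += 1
    if not tally:
        return VoteResult(group.group_id, UNASSIGNED, {}, tie=False)
    top = max(tally.values())
    winners = sorted(label for label, c in tally.items() if c == top)
    tie = len(winners) > 1
    if tie:
        winner = _tie_rng(rng_seed, group.group_id).choice(winners)
    else:
        winner = winners[0]
    return VoteResult(group.group_id, winner, dict(tally), tie=tie)


def apply_voting(
    partition: Partition,
    table: AssignmentTable,
    read_ids,
    rng_seed: int = 0,
    reassign_labeled: bool = True,
) -> tuple[AssignmentTable, list[VoteResult]]:
    """Vote every group and return the boosted table plus per-group results.

    With ``reassign_labeled`` every member of a group whose winner is a
    real taxon takes the winner label; otherwise only UNASSIGNED members
    are filled in.  Groups that win UNASSIGNED are left untouched.  The
    input table is not modified.
    """
    covered = {read_ids[i] for g in partition for i in g.members}
    if covered != set(table.entries):
        missing = set(table.entries) ^ covered
        raise ValueError(f"partition and table cover different read sets ({len(missing)} mismatched ids)")
    boosted = table.copy()
    results: list[VoteResult] = []
    for group in partition:
        result = vote_group(group, table, read_ids, rng_seed)
        results.append(result)
        if result.winner is UNASSIGNED:
            continue
        for idx in group.members:
            rid = read_ids[idx]
            if reassign_labeled or table[rid] is UNASSIGNED:
                boosted[rid] = result.winner
    return boosted, results


def write_vote_report(results: list[VoteResult], path: str | Path) -> None:
    """Per-group vote report: group_id, winner, tie flag, tally as JSON."""
    with open(path, "w") as out:
        out.write("group_id\twinner\ttie\ttally\n")
        for r in results:
            winner = "NA" if r.winner is UNASSIGNED else r.winner
            out.write(f"{r.group_id}\t{winner}\t{int(r.tie)}\t{json.dumps(r.tally, sort_keys=True)}\n")
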