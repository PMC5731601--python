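"""End-to-end orchestration: classification tables in, boosted tables out.

The three phases are (i) initial classification — consumed as input tables,
one per taxonomic rank; (ii) grouping — one overlap graph and one partition
shared by all ranks, since grouping depends only on the sequences; and
(iii) voting — run independently per rank.  ``boost`` is the in-memory
entry point; ``run_clior`` adds file I/O, a run manifest, and diagnostics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .grouping import Partition, partition_graph
from .io import AssignmentTable, Read, read_assignments, read_sequences, write_assignments
from .metrics import EvalReport, abundance, evaluate, pearson_abundance
from .overlap import OverlapGraph, build_graph
from .voting import VoteResult, apply_voting, write_vote_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one boosting run.

    k/m/T defaults are the standard short-read settings: 30-mers, at least
    5 shared k-mers for an edge, and groups capped at 9000 bases of
    independent (non-overlapping) sequence.
    """

    reads_path: str
    assignment_paths: Mapping[str, str]  # rank -> table path
    output_dir: str
    k: int = 30
    m: int = 5
    T: int = 9000
    seed: int = 0
    reassign_labeled: bool = True
    canonical: bool = True
    unassigned_token: str = "NA"

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1 or self.T < 1:
            raise ValueError("k, m and T must all be >= 1")


@dataclass
class BoostResult:
    """In-memory artifacts of a boosting run."""

    graph: OverlapGraph
    partition: Partition
    boosted: dict  # rank -> AssignmentTable
    votes: dict  # rank -> list[VoteResult]

    def tie_fraction(self, rank: str) -> float:
        votes = self.votes[rank]
        return sum(v.tie for v in votes) / len(votes) if votes else 0.0


def boost(
    reads: Sequence[Read],
    tables: Mapping[str, AssignmentTable],
    k: int = 30,
    m: int = 5,
    T: int = 9000,
    seed: int = 0,
    reassign_labeled: bool = True,
    canonical: bool = True,
) -> BoostResult:
    """Boost one or more per-rank assignment tables over a shared partition."""
    read_ids = [r.read_id for r in reads]
    graph = build_graph(reads, k=k, m=m, canonical=canonical)
    partition = partition_graph(graph, reads, T=T)
    boosted: dict[str, AssignmentTable] = {}
    votes: dict[str, list[VoteResult]] = {}
    for rank, table in tables.items():
        boosted[rank], votes[rank] = apply_voting(
            partition, table, read_ids, rng_seed=seed, reassign_labeled=reassign_labeled
        )
    return BoostResult(graph=graph, partition=partition, boosted=boosted, votes=votes)


def run_clior(config: RunConfig) -> BoostResult:
    """File-to-file boosting run: read inputs, boost, write all artifacts.

    Writes per rank a boosted assignment table and a vote report, plus the
    group file and a JSON manifest of parameters and diagnostics (read,
    edge, group and tie counts, before/after assigned fractions).
    Deterministic: identical configs produce byte-identical outputs.
    """
    t0 = time.monotonic()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        reads = read_sequences(config.reads_path)
    except Exception as exc:
        raise RuntimeError(f"[io] failed to load reads from {config.reads_path}: {exc}") from exc
    read_ids = [r.read_id for r in reads]
    tables: dict[str, AssignmentTable] = {}
    for rank, path in config.assignment_paths.items():
        try:
            tables[rank] = read_assignments(
                path, rank=rank, unassigned_token=config.unassigned_token, known_reads=read_ids
            )
        except Exception as exc:
            raise RuntimeError(f"[io] failed to load {rank} assignments from {path}: {exc}") from exc
        if set(tables[rank].entries) != set(read_ids):
            raise RuntimeError(
                f"[io] {rank} assignment table does not cover the read set "
                f"({len(tables[rank])} rows vs {len(read_ids)} reads)"
            )
    logger.info("loaded %d reads and %d assignment tables", len(reads), len(tables))

    result = boost(
        reads,
        tables,
        k=config.k,
        m=config.m,
        T=config.T,
        seed=config.seed,
        reassign_labeled=config.reassign_labeled,
        canonical=config.canonical,
    )
    logger.info(
        "graph: %d edges; partition: %d groups", result.graph.n_edges, len(result.partition)
    )

    result.partition.write(out / "groups.tsv", read_ids)
    manifest: dict = {
        "parameters": {
            "k": config.k,
            "m": config.m,
            "T": config.T,
            "seed": config.seed,
            "reassign_labeled": config.reassign_labeled,
            "canonical": config.canonical,
        },
        "n_reads": len(reads),
        "n_edges": result.graph.n_edges,
        "n_groups": len(result.partition),
        "ranks": {},
    }
    for rank, table in result.boosted.items():
        write_assignments(table, out / f"boosted.{rank}.csv", unassigned_token=config.unassigned_token)
        write_vote_report(result.votes[rank], out / f"votes.{rank}.tsv")
        before = tables[rank].n_assigned() / len(reads)
        after = table.n_assigned() / len(reads)
        ties = sum(v.tie for v in result.votes[rank])
        affected = sum(
            len(result.partition.groups[v.group_id].members) for v in result.votes[rank] if v.tie
        )
        manifest["ranks"][rank] = {
            "assigned_fraction_before": before,
            "assigned_fraction_after": after,
            "tie_groups": ties,
            "tie_group_fraction": ties / len(result.partition) if len(result.partition) else 0.0,
            "tie_affected_read_fraction": affected / len(reads),
        }
        logger.info(
            "%s: assigned %.3f -> %.3f, %d tie groups", rank, before, after, ties
        )
    manifest["elapsed_seconds"] = round(time.monotonic() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result


def run_eval(pred_path: str | Path, truth_path: str | Path, rank: str = "species",
             unassigned_token: str = "NA") -> tuple[EvalReport, float]:
    """Evaluate a predicted table file against a truth table file.

    Returns the precision/recall/F report and the Pearson correlation of
    the two abundance profiles.
    """
    pred = read_assignments(pred_path, rank=rank, unassigned_token=unassigned_token)
    truth = read_assignments(truth_path, rank=rank, unassigned_token=unassigned_token)
    if set(pred.entries) != set(truth.entries):
        raise ValueError("predicted and truth tables cover different read sets")
    report = evaluate(pred, truth)
    r = pearson_abundance(abundance(pred), abundance(truth))
    return report, r
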