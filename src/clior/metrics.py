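"""Evaluation metrics: precision/recall/F-measure and abundance profiles.

With N reads to classify, Y of them assigned and X assigned correctly,
precision P = X/Y, recall R = X/N and F = 2PR/(P+R).  Correctness is exact
label equality at the evaluated rank.  Abundance profiles are per-taxon
fractions of *classified* reads; predicted and true profiles are compared
with the Pearson correlation coefficient over the union of their taxa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .io import UNASSIGNED, AssignmentTable


@dataclass(frozen=True)
class EvalReport:
    """Classification quality of a predicted table against ground truth."""

    n: int  # reads to classify
    assigned: int  # Y: reads with a label
    correct: int  # X: reads with the true label

    @property
    def precision(self) -> float:
        return self.correct / self.assigned if self.assigned else 0.0

    @property
    def recall(self) -> float:
        return self.correct / self.n if self.n else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "N": self.n,
            "Y": self.assigned,
            "X": self.correct,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


@dataclass
class AbundanceProfile:
    """Per-taxon fraction of classified reads at one rank."""

    rank: str
    proportions: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("taxon\tproportion\n")
            for taxon in sorted(self.proportions):
                out.write(f"{taxon}\t{self.proportions[taxon]:.10g}\n")


def evaluate(pred: AssignmentTable, truth: AssignmentTable) -> EvalReport:
    """Score a predicted table against the truth over identical read sets."""
    if set(pred.entries) != set(truth.entries):
        raise ValueError("predicted and truth tables cover different read sets")
    n = len(truth)
    assigned = 0
    correct = 0
    for rid, label in pred.entries.items():
        if label is UNASSIGNED:
            continue
        assigned += 1
        if label == truth[rid]:
            correct += 1
    return EvalReport(n=n, assigned=assigned, correct=correct)


def abundance(table: AssignmentTable, of_all_reads: bool = False) -> AbundanceProfile:
    """Abundance profile of a table.

    By default proportions are over classified reads only (profiles from
    tools with different recall stay comparable); with ``of_all_reads``
    the denominator is the full read count, so proportions need not sum
    to 1.
    """
    counts: dict[str, int] = {}
    for label in table.entries.values():
        if label is UNASSIGNED:
            continue
        counts[label] = counts.get(label, 0) + 1
    total = len(table) if of_all_reads else sum(counts.values())
    if not counts:
        warnings.warn(f"abundance: no classified reads at rank {table.rank!r}", stacklevel=2)
        return AbundanceProfile(table.rank, {})
    return AbundanceProfile(table.rank, {t: c / total for t, c in counts.items()})


def pearson_abundance(pred: AbundanceProfile, truth: AbundanceProfile) -> float:
    """Pearson r between two profiles over the union of their taxa.

    Taxa present in only one profile contribute 0 in the other.  Returns
    NaN (with a warning) when either zero-filled vector is constant, where
    the correlation is undefined.
    """
    if pred.rank != truth.rank:
        raise ValueError(f"rank mismatch: {pred.rank!r} vs {truth.rank!r}")
    taxa = sorted(set(pred.proportions) | set(truth.proportions))
    if len(taxa) < 2:
        warnings.warn("pearson_abundance: fewer than two taxa, correlation undefined", stacklevel=2)
        return float("nan")
    x = np.array([pred.proportions.get(t, 0.0) for t in taxa])
    y = np.array([truth.proportions.get(t, 0.0) for t in taxa])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("pearson_abundance: constant profile, correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
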