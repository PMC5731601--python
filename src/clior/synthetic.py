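"""Synthetic communities and an imperfect base classifier.

Generates desk-scale datasets with the statistical structure the booster
assumes: several genomes (i.i.d. uniform over ACGT, so that for k around 30
a shared k-mer between two genomes is vanishingly unlikely), short reads
drawn with genome probabilities proportional to abundances, uniform start
and strand, and independent per-base substitution errors (default 1% on
80 bp reads, substitution-only as in Illumina-like short-read error
profiles).  A configurable noisy classifier (label dropout + mislabeling)
stands in for the external single-read classifier whose output the booster
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import UNASSIGNED, AssignmentTable, Read

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """One community member: species + genus labels and its sequence length."""

    species: str
    genus: str
    length: int
    sequence: str | None = None  # generated uniformly at random when None


@dataclass
class CommunitySpec:
    """A multi-species community and its sequencing parameters.

    Defaults mirror short-read shotgun data: 80 bp reads with a 1%
    per-base substitution rate.  Two genomes may share a genus, enabling
    rank-dependent agreement (species votes split, genus votes agree).
    """

    genomes: list[GenomeSpec]
    abundances: Sequence[float]
    n_reads: int
    read_length: int = 80
    error_rate: float = 0.01
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genomes) != len(self.abundances):
            raise ValueError("one abundance per genome required")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for g in self.genomes:
            if g.length < self.read_length:
                raise ValueError(f"genome {g.species!r} shorter than read_length")


@dataclass
class ClassifierSpec:
    """Imperfect single-read classifier: dropout and mislabeling rates.

    A read's true label is withheld (UNASSIGNED) with probability
    ``dropout``; a retained label is replaced by a uniformly chosen wrong
    taxon with probability ``mislabel``.  Empirically precision converges
    to 1-mislabel and recall to (1-dropout)(1-mislabel).
    """

    dropout: float = 0.5
    mislabel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout <= 1 and 0 <= self.mislabel <= 1):
            raise ValueError("dropout and mislabel must be in [0, 1]")


def random_genome(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT sequence of the given length."""
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_community(spec: CommunitySpec) -> tuple[list[Read], AssignmentTable, AssignmentTable]:
    """Draw reads from a community; return (reads, species truth, genus truth).

    Per read: source genome with probability proportional to abundance,
    start position uniform, strand uniform (the read is the reverse
    complement of the genomic window half the time), then independent
    substitutions at ``error_rate`` (always to a different base).  With
    ``paired`` reads come as /1,/2 mates of a fragment (mate 2 reverse
    complemented); mates are adjacent in the output and count toward
    ``n_reads`` individually.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    code = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    genome_codes = []
    for g in spec.genomes:
        seq = g.sequence if g.sequence is not None else random_genome(g.length, rng)
        if len(seq) != g.length:
            raise ValueError(f"genome {g.species!r}: sequence length != declared length")
        genome_codes.append(code[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)])

    L = spec.read_length
    probs = np.asarray(spec.abundances, dtype=float)
    probs = probs / probs.sum()
    if spec.paired:
        n_fragments = (spec.n_reads + 1) // 2
        frag_len = min(2 * L + 50, min(g.length for g in spec.genomes))
    else:
        n_fragments = spec.n_reads
        frag_len = L
    source = rng.choice(len(spec.genomes), size=n_fragments, p=probs)
    strand = rng.integers(0, 2, size=n_fragments)
    starts = np.empty(n_fragments, dtype=np.int64)
    for gi, g in enumerate(spec.genomes):
        mask = source == gi
        starts[mask] = rng.integers(0, g.length - frag_len + 1, size=int(mask.sum()))

    offsets = np.arange(L)
    reads: list[Read] = []
    species = AssignmentTable("species")
    genus = AssignmentTable("genus")
    windows = np.empty((n_fragments, L), dtype=np.uint8)
    mate2 = np.empty((n_fragments, L), dtype=np.uint8) if spec.paired else None
    for gi in range(len(spec.genomes)):
        mask = source == gi
        if not mask.any():
            continue
        idx = starts[mask][:, None] + offsets[None, :]
        windows[mask] = genome_codes[gi][idx]
        if spec.paired:
            idx2 = (starts[mask] + frag_len - L)[:, None] + offsets[None, :]
            mate2[mask] = genome_codes[gi][idx2]

    def _finalize(codes: np.ndarray, flip: np.ndarray) -> np.ndarray:
        out = codes.copy()
        out[flip] = (3 - out[flip])[:, ::-1]
        if spec.error_rate > 0:
            err = rng.random(out.shape) < spec.error_rate
            shift = rng.integers(1, 4, size=out.shape)
            out[err] = (out[err] + shift[err]) % 4
        return out

    flip = strand.astype(bool)
    r1 = _finalize(windows, flip)
    if spec.paired:
        # mate 2 is read from the opposite end of the fragment
        r2 = _finalize(mate2, ~flip)

    digits = max(6, len(str(n_fragments)))
    for f in range(n_fragments):
        g = spec.genomes[source[f]]
        if spec.paired:
            for mate, arr in ((1, r1), (2, r2)):
                if len(reads) >= spec.n_reads:
                    break
                rid = f"r{f:0{digits}d}/{mate}"
                reads.append(Read(rid, _BASES[arr[f]].tobytes().decode("ascii")))
                species[rid] = g.species
                genus[rid] = g.genus
        else:
            rid = f"r{f:0{digits}d}"
            reads.append(Read(rid, _BASES[r1[f]].tobytes().decode("ascii")))
            species[rid] = g.species
            genus[rid] = g.genus
    return reads, species, genus


def simulate_classifier(truth: AssignmentTable, spec: ClassifierSpec) -> AssignmentTable:
    """Corrupt a truth table into a plausible base-classifier output."""
    taxa = sorted(truth.labels())
    if not taxa:
        raise ValueError("truth table has no taxa")
    if spec.mislabel > 0 and len(taxa) < 2:
        raise ValueError("mislabel > 0 requires at least two taxa")
    rng = np.random.default_rng(spec.seed)
    out = AssignmentTable(truth.rank)
    rids = sorted(truth.entries)
    drop = rng.random(len(rids)) < spec.dropout
    wrong = rng.random(len(rids)) < spec.mislabel
    pick = rng.integers(0, max(len(taxa) - 1, 1), size=len(rids))
    for i, rid in enumerate(rids):
        true_label = truth[rid]
        if drop[i]:
            out[rid] = UNASSIGNED
        elif wrong[i] and true_label is not UNASSIGNED:
            others = [t for t in taxa if t != true_label]
            out[rid] = others[pick[i] % len(others)]
        else:
            out[rid] = true_label
    return out
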