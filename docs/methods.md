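# Methods

## The model

`clior` treats taxonomic read classification as a label-smoothing problem
on an approximate read-overlap graph. The premise: for k around 30, the
probability that two bacterial genomes share a k-mer is small, so reads
sharing several k-mers almost surely originate from the same genome and,
with high probability, from overlapping positions on it. A connected
neighbourhood of such reads is therefore (almost always) single-species,
and any labels a base classifier managed to place inside it can be
propagated to the rest by majority consensus.

The pipeline assumes nothing about the base classifier beyond its output
format: a per-read taxon label or an unassigned marker, one table per
taxonomic rank. Grouping depends only on the sequences, so one partition
serves all ranks; voting runs per rank.

### Overlap graph

The edge weight between reads i and j is the dot product W_ij = V_i·V_j of
their k-mer composition vectors (V_i the 4^k-dimensional count vector of
the k-mers of read i). Edges exist iff W_ij ≥ m; the inclusive form of the
threshold is used. W_ij is computed sparsely: a global inverted index maps
each k-mer to the reads containing it (with multiplicities), and for each
read the postings of its k-mers are accumulated into a transient sparse
row, of which only entries ≥ m survive. For short reads and k = 30, k-mers
within a read are almost always distinct, so W_ij usually equals the
number of shared k-mers; two error-free reads overlapping in at least
m+k−1 bases (with distinct shared windows) are guaranteed an edge.

Implementation: for k ≤ 31 k-mers are packed into 2k-bit integers and the
pair counting is vectorised (one global sort of (k-mer, read) pairs,
run-length pair expansion in bounded chunks); for larger k a plain
dict-of-postings accumulation is used. The two routes produce identical
edge sets and the test suite asserts this, as well as agreement with a
dense 4^k dot-product oracle at small k.

Strand handling: k-mers are canonicalized (lexicographic minimum of the
window and its reverse complement) by default, since shotgun reads come
from both strands and opposite-strand overlaps would otherwise be
invisible. A `canonical=False` switch disables this. Windows containing
`N` are skipped entirely — an ambiguous base cannot certify overlap. Reads
shorter than k become isolated nodes.

### Grouping

Groups are grown greedily from seed reads taken in input order. At each
step the frontier candidate — an unvisited non-member neighbour of the
group — with the greatest *number of edges* (not summed weight) into the
current members is absorbed; ties break to the lowest read index for
determinism. Edges toward reads already claimed by earlier groups do not
score. Each absorbed read that is adjacent to no current member of the
group's independent set I(G) joins I(G).

Because overlapping reads double-count sequence, group size is measured as
the summed length of I(G) — mutually non-adjacent, hence non-overlapping,
reads (a greedy approximation; exact maximum independent set is NP-hard).
Growth stops when that length reaches T, so it can overshoot T by at most
one read. The cap prevents groups from bridging two species connected by a
few spurious edges. Visited reads are never reconsidered: the result is a
hard partition, each read in exactly one group.

### Voting

Each labeled member of a group casts one unweighted vote; unassigned
members do not vote, so a single labeled read decides an otherwise
unlabeled group — by design, since the goal is shrinking the unassigned
set. The winner label is assigned to all members (default) or only to the
unassigned ones (`reassign_labeled=False`, a strictly more conservative
variant). Ties between maximal labels are broken uniformly at random by a
generator seeded from (run seed, group id), making results reproducible
and independent of group processing order; a tie is declared only when two
or more distinct labels share the maximal count. Voting never invents
taxa and is idempotent at a fixed seed.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| k | 30 | bases | k-mer length; large enough that inter-genome sharing is negligible |
| m | 5 | shared-k-mer dot product | minimum evidence of overlap for an edge; raise (e.g. 45) to thin the graph on very large datasets |
| T | 9000 | bases of independent sequence | group-size cap; the standard short-read setting |
| seed | 0 | — | tie-break stream |
| reassign_labeled | on | — | whether majority winners overwrite existing labels |
| canonical | on | — | strand-collapsed k-mers |

Metrics follow the standard definitions: with N reads, Y assigned and X
correct, P = X/Y (0 when Y = 0), R = X/N, F = 2PR/(P+R) (0 when P+R = 0).
Correctness is exact label equality at the evaluated rank. Abundance
profiles are per-taxon fractions of *classified* reads by default (an
`of_all_reads` switch uses all reads as denominator); profile agreement is
the Pearson correlation over the union of taxa with zero-filling, reported
as NaN when a zero-filled vector is constant.

## The synthetic generator

`clior.synthetic` generates the study conditions the tests run under:
genomes i.i.d. uniform over ACGT (so shared 30-mers between genomes are
vanishingly rare — the separability premise in its cleanest form), reads
of 80 bp drawn with genome probabilities proportional to abundances,
uniform start and strand, and independent substitutions at 1% per base.
The error model is substitution-only: short-read error profiles are
substitution-dominated, and since the method never aligns, indels would
only marginally perturb k-mer sharing. Each genome carries species and
genus labels, and two genomes may share a genus, so genus votes can agree
where species votes split. The emulated base classifier withholds each
read's label with probability `dropout` and replaces it with a uniformly
chosen wrong taxon with probability `mislabel`, independently per read.

What this does **not** emulate: real inter-genome k-mer sharing between
related species (which caps group purity below 100% in practice), coverage
biases, quality-dependent errors, and — importantly — *species-structured*
classifier error. Real classifiers drop reads at species-dependent rates
(database representation varies), which is what distorts their abundance
profiles; the uniform-dropout emulator produces nearly unbiased base
abundance estimates, so passing tests demonstrate that boosting preserves
abundance accuracy, not that it improves it. Group-consensus labels are
correlated within groups, which slightly inflates the sampling variance of
boosted abundance estimates relative to per-read labels; on real data this
is dwarfed by the bias reduction from recovering dropped reads.

Reference experiment (used by `scripts/acceptance.py` and the heaviest
tests): three 100 kb genomes, two congeneric, abundances 0.6/0.3/0.1
(distinct by design — a Pearson comparison against a constant truth
profile would be undefined), 30 000 reads, dropout 0.5, mislabel 0.02.
These sizes give ~8× coverage, enough for the overlap graph to connect
most reads while remaining a desk-scale computation; at this scale the
pipeline boosts species recall from ~0.49 to ~0.98 with a small precision
gain and perfectly pure groups.

## Numerical and design choices

- Seeds: all generators are `numpy` `default_rng` / `random.Random`
  seeded explicitly; identical inputs and seeds give byte-identical
  outputs end to end (including written files).
- Tie-break RNG is derived as `(seed * 1_000_003 + group_id) mod 2^31`,
  one independent stream per group.
- Degenerate inputs: empty assignment files parse to empty tables with a
  warning; all-unassigned tables yield empty abundance profiles; k longer
  than a read yields no k-mers rather than an error.
- Frontier growth absorbs one node per iteration (the frontier is
  recomputed after each addition) rather than level-by-level; candidate
  scoring counts edges, not weights. Both choices follow the method's
  greedy description; the lazy max-heap used internally pops candidates in
  (count, −index) order, which realises the deterministic tie-break.
- Paired-end reads are ingested as two independent reads; pairing survives
  only in the `/1`,`/2` id suffixes, and mates are classified and voted
  individually.

## Known limitations

- Group membership is final: a read absorbed early into a wrong-species
  group (possible when genomes share k-mers) cannot be rescued.
- Memory for the inverted index and edge list is linear in total k-mer
  count and edge count; `m` is the practical knob for very large datasets.
- No hierarchical reconciliation across ranks: species and genus tables
  are voted independently and may disagree.
- The dense-oracle equivalence tests are only feasible for k ≤ 6; for
  k = 30 correctness rests on the cross-route agreement and overlap
  guarantee tests.
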