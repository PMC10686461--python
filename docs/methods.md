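# Methods

This note documents the model and the numerical choices behind `strobex`,
what the synthetic data generator does and does not emulate, and the known
limitations.

## Strobemer seeding

A strobemer anchored at position `i` of a read concatenates `n` strobes,
each the minimizer of the `w` candidate l-mers whose start positions lie
in the window beginning at `i + j·v` (j = 0 … n−1). Every strobe is a
window minimizer — there is no fixed first strobe — so the windows
inspected on the forward strand of a span are exactly the windows
inspected on its reverse complement. The canonical key at an anchor is
therefore well defined: the lexicographically smaller of the forward
strobemer of the spanned characters and the strobemer of their reverse
complement (forward wins ties). An anchor can inspect at most
`span = (n−1)·v + w + l − 1` bases and covers at least
`min_cover = (n−1)·v − w + l + 1` bases (first strobe at its window's last
position, last strobe at its window's first position). Choosing `v` as
the smallest integer with `min_cover ≥ k` guarantees that every grouped
sequence can yield a k-mer while staying close to k in length.

Minimizer order: by default an invertible 64-bit mixing function
(shift/add/xor steps, masked to `2l` bits after each arithmetic step) of
the 2-bit packed l-mer. Invertibility makes the order a bijection on
l-mers, so unequal l-mers never tie; equal l-mers tie and the leftmost
window position wins. A lexicographic mode exists mainly for tests —
alphabetical order biases minimizer positions and misbehaves in
homopolymer runs, which is why hashing is the default. Anchors whose span
contains an ambiguous base are skipped rather than guessed at.

The scan is vectorised per read (packed l-mers, sliding-window argmins,
keys as ≤64-bit integers, requiring `n·l ≤ 32`); a scalar reference path
(`canonical_strobemer`) implements the definition directly and the test
suite cross-checks the two position by position.

## Counting, solidity and occurrence gathering

Counting is exact (hash map), one count per anchor position. A strobemer
with count ≥ `a` is solid. Consecutive anchors of one read often emit the
same key (all strobes are minimizers, which change only every few
positions); at the counting stage each anchor still counts, a deliberate
dialect documented here because the gathering stage *does* merge: a run
of consecutive anchors with the same key contributes one sequence
covering the union of their covers. Runs are broken by a key change, an
invalid anchor, or a canonical-orientation flip. Covered sequences are
stored reverse-complemented when the canonical orientation was reverse,
so every group is strand-normalised: all members begin with the key's
first strobe and end with its last (the *skeleton*), which is what makes
end-to-end global alignment the right consensus model. Only covered
substrings are retained; whole reads are never kept after scanning.

## Partial-order alignment

Groups are folded into a character-labelled DAG one sequence at a time by
global sequence-to-graph alignment followed by node fusion (match fuses;
mismatch fuses into an aligned-linked node with the matching character if
one exists, otherwise creates a node in that column; unaligned characters
become fresh nodes). Edges are unique per node pair and record the
traversing sequence ids; the graph is lossless (every input sequence is
recoverable from its path, asserted by tests).

Scoring is linear-gap global: match +2, mismatch −3, gap −3,
configurable. The grouped sequences share identical ends, so global mode
is the faithful choice; the score set is a declared dialect (an
alternative set 5/−4/−8 changes headline recall by <0.3 pp). Traceback
ties prefer match/mismatch over a node-consuming gap over a
sequence-consuming gap, and among predecessors the heavier incoming edge,
then the smaller node id — determinism is required for reproducible
output. Alignment ends at a sink node; the DP is a numba kernel (the
pipeline performs one alignment per grouped sequence, which dominates the
run time).

## Consensus: modified heaviest bundle

Node scores are computed in topological order: each node picks its
heaviest positive incoming edge and scores that weight plus the chosen
predecessor's score; the consensus is the traceback from the best-scoring
node. Picking by edge weight *first* (not by weight+score sum) matters: a
max-sum rule would let a minority detour through two edges of weight m
outvote a single direct edge of weight M whenever 2m > M, threading
minority insertions into the consensus. Ties among equal-weight incoming
edges prefer the higher-scoring, then smaller-id predecessor. An edge's
weight is the number of *active* sequences traversing it; bundled
sequences are deactivated after each round and never contribute again.

One round of the modified algorithm: (1) set the strength threshold
`t_w` to the weight of the i-th heaviest positive edge, i the mean active
sequence length rounded to the nearest integer (nearest, not floor: on
the six-sequence worked example floor misidentifies the deletion-bearing
reads as strongest); (2) compute per-sequence weakness
`s_w = e_m + e_w` and boost the path edges of the minimiser by `|S|`
per boosted sequence (any boost ≥ the maximum edge weight makes the
selected family dominate; `|S|` is the smallest self-scaling choice);
(3) one heaviest-bundle pass collects the initial bundle of sequences
similar to the strongest one (≥ `b·ℓ` shared path nodes for a length-ℓ
sequence); (4) the whole initial bundle is boosted and the final pass
produces the consensus and its bundle. Acceptance requires
`|B| ≥ max(g, z·|S|)` with `|S|` the original group size, and ≥ `c`
bundle rows supporting every consensus character (consensus-gap MSA
columns are bundle-only insertions and are ignored). Rounds repeat while
the last bundle was non-empty and at least `g` sequences remain active
(with fewer than `g`, no future bundle could pass — a provably
output-equivalent early stop). With boost 0 and a single round the
procedure reduces to the classic algorithm, kept as a regression test.

## Parameters

| name | default | meaning |
|------|---------|---------|
| n, l | 3, 7 | strobes per seed and strobe length; 21 fixed characters total, independent of k so the per-seed error exposure is constant |
| w | 11 | minimizer start positions per window; ≥ l so no character is shared by all candidates |
| v | solved | smallest integer with (n−1)v − w + l + 1 ≥ k |
| a | 4 | minimum strobemer abundance (solidity) |
| b | 0.8 | bundling similarity threshold |
| g, z | 4, 0.4 | absolute / proportional bundle-size acceptance |
| c | 4 | per-character bundle support |

`a`, `g` and `c` are coupled (a bundle cannot exceed its group; no column
can outnumber its bundle), so the evaluation workflow sweeps them
together.

## Synthetic data

The simulator draws i.i.d. uniform ACGT genomes and reads of fixed
nominal length with uniform start and strand, until the requested
coverage in emitted bases is reached. Each template base independently
errs with probability `e`, the error uniformly a substitution (to a
different base), an insertion (one random base emitted after the current
one, itself error-free) or a deletion. The genome is treated as circular
by default — the model organisms behind the pipeline's intended inputs
are bacteria — which keeps coverage uniform; with a linear genome
(`circular=False`) roughly one read length at each end is under-covered,
which at small genome sizes dominates the error budget for no
methodological reason. A deterministic `tiling_reads` helper provides
guaranteed-uniform error-free coverage for identity tests.

What the generator does *not* emulate: realistic long-read error
profiles (homopolymer-length biases, quality-correlated error bursts),
read-length distributions, chimeric reads, or genomic repeat structure
(i.i.d. genomes are nearly repeat-free at these sizes). Passing tests
therefore demonstrate correctness of the machinery and replication of
uniform-error behaviour, not performance on real instrument data, where
precision in particular is expected to degrade.

## Problem sizes

The bundled replication experiment uses a 50 kb genome at 40× coverage
with 2 kb reads and 6% errors, three seeds; the full pipeline runs in
about a minute per seed on one CPU (graph alignment dominates). At
default parameters this yields ≈ 91–92% recall at ≈ 94% precision for
97-mers, while exact counting at its best threshold stays below 1%
recall. Unit and property tests use 2–12 kb genomes.

## Known limitations

- Group sizes |S| of 4–6 frequently fail the `c = 4` support filter (a
  column needs 4 correct rows); recall is driven by the local density of
  well-recovered strobemer groups.
- Erroneous strobemers can become solid through run-length counting
  within a single read; their groups are almost always smaller than `g`
  and die silently, at some gathering cost.
- POA graph topology depends on sequence insertion order (inherent to
  progressive partial-order alignment); output k-mer sets are
  nevertheless deterministic for a fixed input order, and set-identical
  under read reordering in practice (asserted on test data).
- Abundance *counts* for output k-mers are not estimated, only the set.
- Memory holds all covered substrings of one run at once; no partitioned
  multi-pass mode.
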