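"""Read simulation with a uniform error model, plus evaluation utilities.

The simulator emulates long-read sets with a uniform per-base error rate:
at each template base an error occurs with probability ``e`` and is equally
likely to be a substitution (to a different base), an insertion (a random
base emitted after the current one) or a deletion.  Reads have a fixed
nominal length, a uniformly random start and strand, and are drawn until the
requested coverage is reached.  By default the genome is treated as circular
(as bacterial chromosomes are), so reads may wrap around the origin and
coverage is uniform along the genome; set ``circular=False`` for a linear
genome with reads clipped to fit, which under-covers the two ends.

Evaluation follows the usual set definitions: precision is the fraction of
reported k-mers that occur in the genome, recall the fraction of genome
k-mers that were reported.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._dna import BASES, revcomp
from .kmers import canonicalize_kmer

__all__ = [
    "SimulationConfig",
    "SimulatedRead",
    "EvalResult",
    "simulate_genome",
    "simulate_reads",
    "tiling_reads",
    "reference_kmers",
    "count_kmers",
    "exact_count_baseline",
    "precision_recall",
    "write_fasta",
    "write_fastq",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Read-set generation settings.

    error_rate is the total per-base error probability; substitution,
    insertion and deletion each occur with probability ``error_rate / 3``.
    """

    coverage: float = 40.0
    read_length: int = 2000
    error_rate: float = 0.06
    seed: int = 0
    circular: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0 or self.read_length < 1:
            raise ValueError("coverage and read_length must be positive")


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    sequence: str
    start: int
    strand: str  # "+" or "-"
    n_sub: int
    n_ins: int
    n_del: int


def simulate_genome(length: int, seed: int) -> str:
    """I.i.d. uniform ACGT genome of the given length, reproducible by seed."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _apply_errors(template: str, error_rate: float, rng: np.random.Generator):
    """Corrupt *template* base by base; insertions emit the extra base after
    the current one and do not themselves receive further errors."""
    m = len(template)
    if error_rate == 0.0:
        return template, 0, 0, 0
    err = rng.random(m) < error_rate
    idx = np.flatnonzero(err)
    if idx.size == 0:
        return template, 0, 0, 0
    kinds = rng.integers(0, 3, size=idx.size)  # 0 sub, 1 ins, 2 del
    subs = rng.integers(1, 4, size=idx.size)  # offset to a different base
    inss = rng.integers(0, 4, size=idx.size)
    parts = []
    prev = 0
    n_sub = n_ins = n_del = 0
    for t, (i, kind) in enumerate(zip(idx.tolist(), kinds.tolist())):
        parts.append(template[prev:i])
        base = template[i]
        if kind == 0:
            parts.append(BASES[(BASES.index(base) + int(subs[t])) % 4])
            n_sub += 1
        elif kind == 1:
            parts.append(base + BASES[int(inss[t])])
            n_ins += 1
        else:
            n_del += 1
        prev = i + 1
    parts.append(template[prev:])
    return "".join(parts), n_sub, n_ins, n_del


def simulate_reads(genome: str, config: SimulationConfig) -> list[SimulatedRead]:
    """Draw reads from *genome* until coverage * |genome| bases are emitted."""
    L = len(genome)
    rl = config.read_length
    if rl > L:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(config.seed)
    target = config.coverage * L
    total = 0
    reads: list[SimulatedRead] = []
    doubled = genome + genome  # for circular wrap-around slices
    while total < target:
        if config.circular:
            start = int(rng.integers(0, L))
            template = doubled[start : start + rl]
        else:
            start = int(rng.integers(0, L - rl + 1))
            template = genome[start : start + rl]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = revcomp(template)
        seq, n_sub, n_ins, n_del = _apply_errors(template, config.error_rate, rng)
        reads.append(
            SimulatedRead(
                name=f"read_{len(reads)}",
                sequence=seq,
                start=start,
                strand=strand,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
        total += len(seq)
    return reads


def tiling_reads(
    genome: str,
    read_length: int,
    stride: int,
    copies: int = 1,
    circular: bool = False,
) -> list[str]:
    """Deterministic error-free reads tiling the genome at a fixed stride.

    Start positions run 0, stride, 2*stride, ...; on a circular genome the
    reads wrap past the origin, giving every position identical coverage.
    On a linear genome a final read ending at the last base is added.  The
    tiling is repeated *copies* times — handy for tests that need
    guaranteed uniform coverage without sampling noise.
    """
    L = len(genome)
    if read_length > L:
        raise ValueError("read length exceeds genome length")
    if circular:
        doubled = genome + genome
        starts = range(0, L, stride)
        return [doubled[s : s + read_length] for s in starts] * copies
    starts = list(range(0, L - read_length + 1, stride))
    if starts[-1] != L - read_length:
        starts.append(L - read_length)
    return [genome[s : s + read_length] for s in starts] * copies


def reference_kmers(genome: str, k: int, circular: bool = False) -> set[str]:
    """Canonical set of all k-mer windows of the genome."""
    if k > len(genome):
        raise ValueError("k exceeds genome length")
    text = genome + genome[: k - 1] if circular else genome
    return {canonicalize_kmer(text[i : i + k]) for i in range(len(text) - k + 1)}


def count_kmers(reads: Iterable[str], k: int) -> Counter:
    """Exact canonical k-mer counts over a read collection."""
    counts: Counter = Counter()
    for read in reads:
        rc = revcomp(read)
        n = len(read)
        for i in range(n - k + 1):
            km = read[i : i + k]
            if "N" in km:
                continue
            kr = rc[n - i - k : n - i]
            counts[km if km <= kr else kr] += 1
    return counts


def exact_count_baseline(reads: Iterable[str], k: int, a: int) -> set[str]:
    """Canonical k-mers occurring at least *a* times — the plain-counting
    baseline that collapses for long k on high-error reads."""
    return {km for km, n in count_kmers(reads, k).items() if n >= a}


@dataclass(frozen=True)
class EvalResult:
    precision: float  # NaN when nothing was reported
    recall: float
    n_true_positive: int
    n_reported: int
    n_truth: int


def precision_recall(reported: set[str], truth: set[str]) -> EvalResult:
    """Precision and recall of a reported k-mer set against the genome truth."""
    if not truth:
        raise ValueError("truth set is empty")
    tp = len(reported & truth)
    precision = tp / len(reported) if reported else math.nan
    return EvalResult(
        precision=precision,
        recall=tp / len(truth),
        n_true_positive=tp,
        n_reported=len(reported),
        n_truth=len(truth),
    )


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: Sequence[SimulatedRead], path) -> None:
    """FASTQ with dummy qualities (the pipeline never uses them)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name} start={r.start} strand={r.strand}\n")
            fh.write(r.sequence + "\n+\n" + "I" * len(r.sequence) + "\n")
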