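"""Consensus-to-k-mer conversion: splitting, canonicalisation, dedup, I/O.

The strobemer geometry must guarantee consensus inputs of length >= k, which
is the inequality ``(n-1)*v - w + l + 1 >= k`` relating the window geometry
to the k-mer length.  Consensus sequences longer than k yield every k-length
window; each k-mer is reported once, in canonical form (the smaller of the
k-mer and its reverse complement under the standard A<C<G<T order).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._dna import AmbiguousBaseError, revcomp
from .strobemer import StrobemerParams

__all__ = [
    "ParameterError",
    "ParameterCheck",
    "min_v_for_k",
    "validate_parameters",
    "split_into_kmers",
    "canonicalize_kmer",
    "KmerSet",
    "emit",
    "write_kmers_text",
    "write_kmers_fasta",
    "read_kmers",
]


class ParameterError(ValueError):
    """Strobemer geometry cannot guarantee k-length consensus input."""


@dataclass(frozen=True)
class ParameterCheck:
    min_cover: int
    min_v: int


def min_v_for_k(n: int, l: int, w: int, k: int) -> int:
    """Smallest window distance v with ``(n-1)*v - w + l + 1 >= k``."""
    num = k + w - l - 1
    return max(1, -(-num // (n - 1)))


def validate_parameters(params: StrobemerParams, k: int) -> ParameterCheck:
    """Check the coverage inequality ``(n-1)*v - w + l + 1 >= k``.

    Returns the achieved minimum cover and the minimal v that would satisfy
    the inequality; raises :class:`ParameterError` on violation.
    """
    mc = params.min_cover
    mv = min_v_for_k(params.n, params.l, params.w, k)
    if mc < k:
        raise ParameterError(
            f"(n-1)*v - w + l + 1 = {mc} < k = {k}; "
            f"smallest admissible v is {mv} (got v = {params.v})"
        )
    return ParameterCheck(min_cover=mc, min_v=mv)


def split_into_kmers(consensus: str, k: int) -> list[str]:
    """All k-length windows of *consensus* (empty when it is too short)."""
    if len(consensus) < k:
        return []
    return [consensus[i : i + k] for i in range(len(consensus) - k + 1)]


def canonicalize_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement (A<C<G<T)."""
    for ch in kmer:
        if ch not in "ACGT":
            raise AmbiguousBaseError(f"ambiguous base {ch!r} in k-mer")
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerSet:
    """Deduplicated canonical k-mers plus a too-short consensus counter."""

    def __init__(self, k: int):
        self.k = k
        self.kmers: set[str] = set()
        self.too_short = 0

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.kmers

    def add_consensus(self, consensus: str, count_too_short: bool = True) -> int:
        """Split one consensus sequence into canonical k-mers; returns #added windows."""
        windows = split_into_kmers(consensus, self.k)
        if not windows:
            if count_too_short:
                self.too_short += 1
            return 0
        for km in windows:
            self.kmers.add(canonicalize_kmer(km))
        return len(windows)

    def update(self, other: "KmerSet") -> None:
        if other.k != self.k:
            raise ValueError("k-mer lengths differ")
        self.kmers |= other.kmers
        self.too_short += other.too_short


def emit(kmer_sets: Iterable[KmerSet], k: int) -> KmerSet:
    """Union of per-group k-mer sets with deduplication."""
    out = KmerSet(k)
    for ks in kmer_sets:
        out.update(ks)
    return out


def write_kmers_text(kmers: KmerSet, path) -> None:
    """One canonical k-mer per line, lexicographically sorted, with a header."""
    with open(path, "w") as fh:
        fh.write(f"# canonical {kmers.k}-mers: {len(kmers)}\n")
        for km in sorted(kmers.kmers):
            fh.write(km + "\n")


def write_kmers_fasta(kmers: KmerSet, path) -> None:
    with open(path, "w") as fh:
        for i, km in enumerate(sorted(kmers.kmers)):
            fh.write(f">kmer_{i}\n{km}\n")


def read_kmers(path) -> set[str]:
    """Read k-mers written by either writer (text lines or FASTA)."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            out.add(line)
    return out
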