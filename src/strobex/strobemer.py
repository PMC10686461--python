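"""Modified strobemers: minimizer-window seeds with a canonical orientation.

A strobemer anchored at read position ``i`` is the concatenation of ``n``
minimizers (strobes), each of length ``l``.  Strobe ``j`` is the minimizer of
the ``w`` candidate l-mers whose start positions lie in the window beginning
at ``i + j*v``.  Unlike the classic definition, *every* strobe is a window
minimizer, so the windows inspected in the forward orientation of a span are
exactly the windows inspected in its reverse complement.  That symmetry is
what makes a canonical (strand-independent) strobemer well defined: the key
reported for an anchor is the lexicographically smaller of the forward
strobemer of the spanned characters and the strobemer of their reverse
complement.

Two minimizer orders are supported: an invertible 64-bit mixing hash (the
default; avoids the positional bias of alphabetical minimizers) and plain
lexicographic order (useful in tests because it is easy to reason about).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from ._dna import AmbiguousBaseError, decode_packed, encode, revcomp

__all__ = [
    "StrobemerParams",
    "StrobemerRecord",
    "MinimizerOrder",
    "ReadScan",
    "pack_lmer",
    "minimizer_in_window",
    "strobemer_at",
    "canonical_strobemer",
    "enumerate_strobemers",
    "scan_read",
    "decode_key",
]


@dataclass(frozen=True)
class StrobemerParams:
    """Window geometry of a strobemer.

    Parameters
    ----------
    n : number of strobes (>= 2).
    l : strobe (minimizer) length in bases.
    v : distance between the start positions of consecutive minimizer windows.
    w : number of candidate start positions per minimizer window.
    """

    n: int
    l: int
    v: int
    w: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.l < 1 or self.v < 1 or self.w < 1:
            raise ValueError("l, v and w must be >= 1")

    @property
    def span(self) -> int:
        """Total bases an anchor can inspect: ``(n-1)*v + w + l - 1``."""
        return (self.n - 1) * self.v + self.w + self.l - 1

    @property
    def min_cover(self) -> int:
        """Shortest sequence a strobemer can cover: ``(n-1)*v - w + l + 1``.

        Attained when the first strobe sits at the last position of its
        window and the last strobe at the first position of its window.
        """
        return (self.n - 1) * self.v - self.w + self.l + 1

    @property
    def key_length(self) -> int:
        return self.n * self.l


@dataclass(frozen=True)
class StrobemerRecord:
    """A strobemer observed at one read anchor.

    ``cover_start``/``cover_end`` delimit (0-based, half-open, in read
    coordinates) the read substring from the first base of the first strobe
    through the last base of the last strobe of the *canonical* strobemer.
    """

    key: str
    orientation: Literal["forward", "reverse"]
    cover_start: int
    cover_end: int


def _mix_int(x: int, mask: int) -> int:
    # Invertible integer finalizer (shift/add/xor steps), masked to the key
    # width after every arithmetic step so the transform stays a bijection
    # on the 2l-bit domain.
    x = (~x + (x << 21)) & mask
    x = x ^ (x >> 24)
    x = (x + (x << 3) + (x << 8)) & mask
    x = x ^ (x >> 14)
    x = (x + (x << 2) + (x << 4)) & mask
    x = x ^ (x >> 28)
    x = (x + (x << 31)) & mask
    return x


def _mix_np(arr: np.ndarray, mask: np.uint64) -> np.ndarray:
    x = arr.astype(np.uint64)
    x = (~x + (x << np.uint64(21))) & mask
    x = x ^ (x >> np.uint64(24))
    x = (x + (x << np.uint64(3)) + (x << np.uint64(8))) & mask
    x = x ^ (x >> np.uint64(14))
    x = (x + (x << np.uint64(2)) + (x << np.uint64(4))) & mask
    x = x ^ (x >> np.uint64(28))
    x = (x + (x << np.uint64(31))) & mask
    return x


@dataclass(frozen=True)
class MinimizerOrder:
    """Total order over l-mers used to pick window minimizers.

    ``hash`` applies an invertible bit-mixing function to the 2-bit packed
    l-mer, masked to ``2*l`` bits; distinct l-mers therefore keep distinct
    order values.  ``lexicographic`` orders packed values directly, which for
    the fixed-width A<C<G<T encoding coincides with string order.  Ties (equal
    l-mers) are always broken by the leftmost window position.
    """

    mode: Literal["hash", "lexicographic"] = "hash"

    def value(self, packed: int, l: int) -> int:
        if self.mode == "lexicographic":
            return packed
        return _mix_int(packed, (1 << (2 * l)) - 1)

    def values(self, packed: np.ndarray, l: int) -> np.ndarray:
        if self.mode == "lexicographic":
            return packed
        return _mix_np(packed, np.uint64((1 << (2 * l)) - 1))


def pack_lmer(seq: str) -> int:
    """2-bit pack an l-mer (A=0, C=1, G=2, T=3; first base most significant)."""
    value = 0
    for ch in seq:
        try:
            code = "ACGT".index(ch.upper())
        except ValueError:
            raise AmbiguousBaseError(f"non-ACGT base {ch!r}") from None
        value = (value << 2) | code
    return value


def minimizer_in_window(
    seq: str,
    start: int,
    params: StrobemerParams,
    order: MinimizerOrder,
) -> Optional[tuple[int, str]]:
    """Minimizer among the ``w`` l-mers starting in ``[start, start+w)``.

    Returns ``(position, l-mer)`` with leftmost tie-breaking, or ``None`` if
    every candidate contains an ambiguous base.  Raises ``ValueError`` when
    the window does not fit inside *seq*.
    """
    l, w = params.l, params.w
    if start < 0 or start + w - 1 + l > len(seq):
        raise ValueError("minimizer window extends past the end of the sequence")
    best: Optional[tuple[int, int, str]] = None
    for pos in range(start, start + w):
        lmer = seq[pos : pos + l]
        try:
            packed = pack_lmer(lmer)
        except AmbiguousBaseError:
            continue
        val = order.value(packed, l)
        if best is None or val < best[0]:
            best = (val, pos, lmer)
    if best is None:
        return None
    return best[1], best[2]


def strobemer_at(
    seq: str,
    i: int,
    params: StrobemerParams,
    order: MinimizerOrder,
) -> Optional[StrobemerRecord]:
    """Single-orientation strobemer anchored at position *i* of *seq*.

    The key is the concatenation of the ``n`` window minimizers; the cover
    interval runs from the start of the first strobe to the end of the last
    one.  Returns ``None`` when some window has no valid minimizer; raises
    ``ValueError`` when the span does not fit.
    """
    if i < 0 or i + params.span > len(seq):
        raise ValueError("strobemer span extends past the end of the sequence")
    strobes = []
    positions = []
    for j in range(params.n):
        hit = minimizer_in_window(seq, i + j * params.v, params, order)
        if hit is None:
            return None
        positions.append(hit[0])
        strobes.append(hit[1])
    return StrobemerRecord(
        key="".join(strobes),
        orientation="forward",
        cover_start=positions[0],
        cover_end=positions[-1] + params.l,
    )


def canonical_strobemer(
    seq: str,
    i: int,
    params: StrobemerParams,
    order: MinimizerOrder,
) -> Optional[StrobemerRecord]:
    """Strand-independent strobemer at anchor *i*.

    Computes the strobemer of the spanned characters in forward orientation
    and of their reverse complement (anchored at offset 0 of the
    reverse-complemented span), and keeps the lexicographically smaller key;
    the forward orientation wins ties.  The cover interval is always reported
    in read coordinates.
    """
    fwd = strobemer_at(seq, i, params, order)
    if fwd is None:
        return None
    span = params.span
    rc_span = revcomp(seq[i : i + span])
    rev = strobemer_at(rc_span, 0, params, order)
    if rev is None:
        return None
    if fwd.key <= rev.key:
        return StrobemerRecord(
            key=fwd.key,
            orientation="forward",
            cover_start=fwd.cover_start,
            cover_end=fwd.cover_end,
        )
    return StrobemerRecord(
        key=rev.key,
        orientation="reverse",
        cover_start=i + span - rev.cover_end,
        cover_end=i + span - rev.cover_start,
    )


@dataclass(frozen=True)
class ReadScan:
    """Vectorised per-read scan: one row per valid anchor position.

    Keys are 2-bit packed canonical strobemer strings (``2*n*l`` bits, so the
    array path requires ``n*l <= 32``; the default geometry packs 21 bases
    into 42 bits).  ``reverse`` flags anchors whose canonical key came from
    the reverse-complement orientation.
    """

    anchors: np.ndarray  # int64
    keys: np.ndarray  # uint64 packed canonical keys
    reverse: np.ndarray  # bool
    cover_start: np.ndarray  # int64
    cover_end: np.ndarray  # int64


_EMPTY_SCAN = None


def _empty_scan() -> ReadScan:
    global _EMPTY_SCAN
    if _EMPTY_SCAN is None:
        zi = np.zeros(0, dtype=np.int64)
        _EMPTY_SCAN = ReadScan(zi, np.zeros(0, dtype=np.uint64), np.zeros(0, bool), zi, zi)
    return _EMPTY_SCAN


def scan_read(read: str, params: StrobemerParams, order: MinimizerOrder) -> ReadScan:
    """Canonical strobemers at every valid anchor of *read* (vectorised).

    Anchors whose span contains an ambiguous base are skipped.  Agrees
    position-by-position with :func:`canonical_strobemer`.
    """
    n, l, v, w = params.n, params.l, params.v, params.w
    if params.key_length > 32:
        raise ValueError("packed scan supports n*l <= 32; use canonical_strobemer")
    span = params.span
    L = len(read)
    if L < span:
        return _empty_scan()

    codes = encode(read).astype(np.uint64)
    bad = (codes > 3).astype(np.int64)
    codes = np.where(codes > 3, np.uint64(0), codes)
    comp = np.uint64(3) - codes

    n_lmers = L - l + 1
    F = np.zeros(n_lmers, dtype=np.uint64)
    C = np.zeros(n_lmers, dtype=np.uint64)
    for t in range(l):
        F = (F << np.uint64(2)) | codes[t : t + n_lmers]
        C |= comp[t : t + n_lmers] << np.uint64(2 * t)

    hf = order.values(F, l)
    hc = order.values(C, l)

    win = np.lib.stride_tricks.sliding_window_view
    # leftmost argmin per window of forward order values
    amin_f = np.argmin(win(hf, w), axis=1)
    # rightmost argmin per window of reverse-complement order values
    # (leftmost in reverse-complement coordinates)
    amin_c = (w - 1) - np.argmin(win(hc, w)[:, ::-1], axis=1)

    anchors = np.arange(0, L - span + 1, dtype=np.int64)

    shift = 2 * l
    keyF = np.zeros(anchors.shape[0], dtype=np.uint64)
    keyR = np.zeros(anchors.shape[0], dtype=np.uint64)
    pF = np.empty((n, anchors.shape[0]), dtype=np.int64)
    pR = np.empty((n, anchors.shape[0]), dtype=np.int64)
    for j in range(n):
        sF = anchors + j * v
        pF[j] = sF + amin_f[sF]
        keyF = (keyF << np.uint64(shift)) | F[pF[j]]
        sR = anchors + span - l - j * v - (w - 1)
        pR[j] = sR + amin_c[sR]
        keyR = (keyR << np.uint64(shift)) | C[pR[j]]

    rev = keyR < keyF
    keys = np.where(rev, keyR, keyF)
    cover_start = np.where(rev, pR[n - 1], pF[0])
    cover_end = np.where(rev, pR[0] + l, pF[n - 1] + l)

    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        ok = (cs[anchors + span] - cs[anchors]) == 0
        anchors = anchors[ok]
        keys = keys[ok]
        rev = rev[ok]
        cover_start = cover_start[ok]
        cover_end = cover_end[ok]

    return ReadScan(anchors, keys, rev, cover_start, cover_end)


def decode_key(key: int, params: StrobemerParams) -> str:
    """Expand a packed canonical key back into its ``n*l``-base string."""
    return decode_packed(int(key), params.key_length)


def enumerate_strobemers(
    read: str, params: StrobemerParams, order: MinimizerOrder
) -> list[StrobemerRecord]:
    """Canonical strobemer records for every valid anchor of *read*, in order."""
    if params.key_length > 32:
        out = []
        for i in range(0, len(read) - params.span + 1):
            rec = canonical_strobemer(read, i, params, order)
            if rec is not None:
                out.append(rec)
        return out
    scan = scan_read(read, params, order)
    return [
        StrobemerRecord(
            key=decode_key(k, params),
            orientation="reverse" if r else "forward",
            cover_start=int(cs),
            cover_end=int(ce),
        )
        for k, r, cs, ce in zip(scan.keys, scan.reverse, scan.cover_start, scan.cover_end)
    ]
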