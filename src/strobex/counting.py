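"""Exact canonical-strobemer counting and solid-strobemer selection.

Counting is per anchor position: consecutive anchors in one read that emit
the same canonical key each increment the count (run-merging happens later,
at occurrence gathering).  A strobemer is *solid* when its count reaches the
minimum abundance threshold ``a``; with ``a >= 2`` the singletons created by
sequencing errors are discarded.  Counts are held in an exact hash map keyed
by the 2-bit packed canonical key.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

from .strobemer import MinimizerOrder, StrobemerParams, decode_key, scan_read

__all__ = ["StrobemerCounts", "count_strobemers", "solid_strobemers"]


class StrobemerCounts(Mapping):
    """Mapping from canonical strobemer string to occurrence count.

    Storage is packed-integer keyed; string keys are decoded on access, so
    iteration order follows the packed encoding.  ``by_int`` exposes the raw
    ``{packed key: count}`` dict for the fast pipeline path.
    """

    def __init__(self, params: StrobemerParams, data: dict[int, int] | None = None):
        self.params = params
        self.by_int: dict[int, int] = data if data is not None else {}

    def __getitem__(self, key: str | int) -> int:
        return self.by_int[self._as_int(key)]

    def __iter__(self):
        for k in self.by_int:
            yield decode_key(k, self.params)

    def __len__(self) -> int:
        return len(self.by_int)

    def _as_int(self, key: str | int) -> int:
        if isinstance(key, str):
            if len(key) != self.params.key_length:
                raise KeyError(key)
            value = 0
            for ch in key:
                value = (value << 2) | "ACGT".index(ch)
            return value
        return int(key)

    @property
    def total(self) -> int:
        """Number of anchor positions that produced a strobemer."""
        return sum(self.by_int.values())

    def dump_tsv(self, path) -> None:
        """Write ``key<TAB>count`` lines sorted by key (debugging aid)."""
        with open(path, "w") as fh:
            for key in sorted(self):
                fh.write(f"{key}\t{self[key]}\n")


def count_strobemers(
    reads: Iterable[str],
    params: StrobemerParams,
    order: MinimizerOrder,
) -> StrobemerCounts:
    """Count canonical strobemers over *reads*, one count per anchor position."""
    counts: dict[int, int] = {}
    for read in reads:
        scan = scan_read(read, params, order)
        if scan.keys.shape[0] == 0:
            continue
        uniq, per = np.unique(scan.keys, return_counts=True)
        for k, c in zip(uniq.tolist(), per.tolist()):
            counts[k] = counts.get(k, 0) + c
    return StrobemerCounts(params, counts)


def solid_strobemers(counts: StrobemerCounts, a: int) -> set[int]:
    """Packed canonical keys whose count is at least *a*.

    The solid set shrinks monotonically as *a* grows.
    """
    if a < 1:
        raise ValueError("abundance threshold a must be >= 1")
    return {k for k, c in counts.by_int.items() if c >= a}
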