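"""Second pass over the reads: group covered sequences by solid strobemer.

For every anchor whose canonical key is solid, the covered read substring
(first base of the first strobe through the last base of the last strobe) is
appended to that key's group, reverse-complemented first when the canonical
orientation was reverse.  A run of consecutive anchors in one read that emit
the same key contributes a single sequence covering the union of their
covers; a run is broken by a different key, an invalid anchor, or an
orientation flip.  Because the first and last strobes are part of the key,
all sequences stored under one key begin with strobe ``m_1`` and end with
strobe ``m_n`` — the shared skeleton that anchors the later consensus
alignment.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np

from ._dna import revcomp
from .strobemer import MinimizerOrder, StrobemerParams, decode_key, scan_read

__all__ = ["OccurrenceIndex", "gather_occurrences", "group_sizes"]


class OccurrenceIndex(Mapping):
    """Mapping from canonical strobemer string to its covered sequences.

    Each value is the list of read substrings (oriented to start with the
    key's first strobe) gathered for that solid strobemer — the group ``S``
    fed to consensus generation.  ``by_int`` exposes the packed-key dict.
    """

    def __init__(self, params: StrobemerParams):
        self.params = params
        self.by_int: dict[int, list[str]] = {}

    def __getitem__(self, key: str | int) -> list[str]:
        if isinstance(key, str):
            value = 0
            for ch in key:
                value = (value << 2) | "ACGT".index(ch)
            key = value
        return self.by_int[int(key)]

    def __iter__(self):
        for k in self.by_int:
            yield decode_key(k, self.params)

    def __len__(self) -> int:
        return len(self.by_int)


def gather_occurrences(
    reads: Iterable[str],
    solid: set[int],
    params: StrobemerParams,
    order: MinimizerOrder,
) -> OccurrenceIndex:
    """Collect, for each solid key, the sequences it covers in *reads*.

    *solid* holds packed canonical keys as returned by
    :func:`strobex.counting.solid_strobemers`; it must have been produced
    with the same *params* and *order*.
    """
    index = OccurrenceIndex(params)
    if not solid:
        return index
    solid_arr = np.fromiter(solid, dtype=np.uint64, count=len(solid))
    solid_arr.sort()
    for read in reads:
        scan = scan_read(read, params, order)
        m = scan.keys.shape[0]
        if m == 0:
            continue
        # run boundaries: key change, non-consecutive anchor, orientation flip
        if m == 1:
            starts = np.array([0], dtype=np.int64)
        else:
            brk = (
                (scan.keys[1:] != scan.keys[:-1])
                | (scan.anchors[1:] != scan.anchors[:-1] + 1)
                | (scan.reverse[1:] != scan.reverse[:-1])
            )
            starts = np.concatenate(([0], np.flatnonzero(brk) + 1))
        ends = np.concatenate((starts[1:], [m]))
        run_keys = scan.keys[starts]
        pos = np.searchsorted(solid_arr, run_keys)
        pos[pos == solid_arr.shape[0]] = 0
        is_solid = solid_arr[pos] == run_keys
        for s, e in zip(starts[is_solid].tolist(), ends[is_solid].tolist()):
            cs = int(scan.cover_start[s:e].min())
            ce = int(scan.cover_end[s:e].max())
            seq = read[cs:ce]
            if scan.reverse[s]:
                seq = revcomp(seq)
            key = int(scan.keys[s])
            index.by_int.setdefault(key, []).append(seq)
    return index


def group_sizes(index: OccurrenceIndex) -> dict[str, int]:
    """Group size |S| per canonical strobemer string."""
    return {decode_key(k, index.params): len(v) for k, v in index.by_int.items()}
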