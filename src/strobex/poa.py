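"""Partial-order multiple sequence alignment (PO-MSA) graph.

The graph is a character-labelled DAG built by aligning sequences to it one
at a time and fusing matching nodes.  Fusion follows three rules: an aligned
pair with equal characters shares a node; an aligned pair whose graph node
is already aligned-linked to a node with the matching character fuses into
that node; otherwise a fresh node is created and aligned-linked to the graph
node (aligned-linked nodes form a column and always carry distinct
characters).  Unaligned sequence characters become fresh nodes.  Edges are
unique per ordered node pair and remember which sequences traverse them, so
an edge's weight is the number of (active) sequences using it and every
input sequence can be reconstructed exactly from its stored path — the graph
is lossless.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._kernels import align_global

__all__ = [
    "AlignmentScoring",
    "Alignment",
    "POAGraph",
    "align_to_graph",
    "add_sequence",
    "build_graph",
    "msa_of",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap global alignment scores (match > 0, mismatch <= 0, gap < 0)."""

    match: int = 2
    mismatch: int = -3
    gap: int = -3

    def __post_init__(self) -> None:
        if not (self.match > 0 and self.mismatch <= 0 and self.gap < 0):
            raise ValueError("require match > 0, mismatch <= 0, gap < 0")


@dataclass(frozen=True)
class Alignment:
    """Pairs of (graph node id | None, sequence position | None)."""

    pairs: tuple[tuple[Optional[int], Optional[int]], ...]
    score: int


class POAGraph:
    """Mutable PO-MSA graph; nodes are characters, paths spell sequences."""

    def __init__(self) -> None:
        self.chars: list[str] = []
        self.succs: list[dict[int, set[int]]] = []  # u -> {v: traversing seq ids}
        self.preds: list[list[int]] = []
        self.group_of: list[int] = []  # aligned-link column per node
        self.groups: dict[int, list[int]] = {}
        self.paths: list[list[int]] = []  # per sequence id
        self.seqs: list[str] = []
        self.active: list[int] = []  # 0/1 weight per sequence
        self._topo: Optional[list[int]] = None
        self._consensus_index = None

    # -- structure -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.chars)

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    def _invalidate(self) -> None:
        self._topo = None
        self._consensus_index = None

    def _new_node(self, char: str, group: Optional[int] = None) -> int:
        nid = len(self.chars)
        self.chars.append(char)
        self.succs.append({})
        self.preds.append([])
        if group is None:
            group = nid
            self.groups[group] = [nid]
        else:
            self.groups[group].append(nid)
        self.group_of.append(group)
        return nid

    def _add_edge(self, u: int, v: int, sid: int) -> None:
        ids = self.succs[u].get(v)
        if ids is None:
            self.succs[u][v] = {sid}
            self.preds[v].append(u)
        else:
            ids.add(sid)

    def edges(self):
        """Iterate ``(u, v, seq_ids)`` over the unique edges."""
        for u, d in enumerate(self.succs):
            for v, ids in d.items():
                yield u, v, ids

    def topological_order(self) -> list[int]:
        if self._topo is None:
            indeg = [len(p) for p in self.preds]
            ready = [n for n in range(self.n_nodes) if indeg[n] == 0]
            order: list[int] = []
            while ready:
                nxt: list[int] = []
                for u in ready:
                    order.append(u)
                    for v in self.succs[u]:
                        indeg[v] -= 1
                        if indeg[v] == 0:
                            nxt.append(v)
                ready = nxt
            if len(order) != self.n_nodes:
                raise RuntimeError("PO-MSA graph contains a cycle")
            self._topo = order
        return self._topo

    def reconstruct(self, sid: int) -> str:
        """Spell sequence *sid* from its stored node path (lossless check)."""
        return "".join(self.chars[n] for n in self.paths[sid])

    def to_dot(self) -> str:
        """DOT export for debugging (node = id:char, edge label = weight)."""
        lines = ["digraph poa {"]
        for n, ch in enumerate(self.chars):
            lines.append(f'  n{n} [label="{n}:{ch}"];')
        for u, v, ids in self.edges():
            w = sum(self.active[s] for s in ids)
            lines.append(f'  n{u} -> n{v} [label="{w}"];')
        lines.append("}")
        return "\n".join(lines)


def align_to_graph(
    graph: POAGraph, seq: str, scoring: AlignmentScoring = AlignmentScoring()
) -> Optional[Alignment]:
    """Optimal global alignment of *seq* against the current graph.

    Returns ``None`` for an empty graph (the sequence then becomes the
    initial path).  An empty sequence yields an all-gap alignment down one
    graph path.
    """
    if graph.n_nodes == 0:
        return None
    order = graph.topological_order()
    rank_of = {n: r for r, n in enumerate(order)}
    N = graph.n_nodes
    chars = np.frombuffer("".join(graph.chars[n] for n in order).encode(), np.uint8)
    ids = np.asarray(order, dtype=np.int64)
    indptr = np.zeros(N + 1, np.int64)
    pred_ranks: list[int] = []
    pred_w: list[int] = []
    for r, n in enumerate(order):
        for u in graph.preds[n]:
            pred_ranks.append(rank_of[u])
            pred_w.append(len(graph.succs[u][n]))
        indptr[r + 1] = len(pred_ranks)
    is_sink = np.asarray([len(graph.succs[n]) == 0 for n in order], bool)
    score, nodes, poss = align_global(
        chars,
        ids,
        indptr,
        np.asarray(pred_ranks, np.int64),
        np.asarray(pred_w, np.int64),
        is_sink,
        np.frombuffer(seq.encode(), np.uint8),
        np.int32(scoring.match),
        np.int32(scoring.mismatch),
        np.int32(scoring.gap),
    )
    pairs = tuple(
        (order[nr] if nr >= 0 else None, int(p) if p >= 0 else None)
        for nr, p in zip(nodes.tolist(), poss.tolist())
    )
    return Alignment(pairs=pairs, score=int(score))


def add_sequence(graph: POAGraph, seq: str, alignment: Optional[Alignment]) -> int:
    """Fuse *seq* into *graph* along *alignment*; returns the new sequence id.

    *alignment* must have been computed against the current graph state (or
    be ``None`` when the graph is empty).
    """
    sid = len(graph.seqs)
    path: list[int] = []
    prev = -1
    if alignment is None:
        if graph.n_nodes != 0:
            raise ValueError("alignment may be None only for an empty graph")
        pairs: Sequence = tuple((None, p) for p in range(len(seq)))
    else:
        pairs = alignment.pairs
    for node, pos in pairs:
        if pos is None:
            continue
        c = seq[pos]
        if node is None:
            cur = graph._new_node(c)
        elif graph.chars[node] == c:
            cur = node
        else:
            group = graph.group_of[node]
            cur = -1
            for cand in graph.groups[group]:
                if graph.chars[cand] == c:
                    cur = cand
                    break
            if cur < 0:
                cur = graph._new_node(c, group)
        if prev >= 0 and cur != prev:
            graph._add_edge(prev, cur, sid)
        path.append(cur)
        prev = cur
    graph.paths.append(path)
    graph.seqs.append(seq)
    graph.active.append(1)
    graph._invalidate()
    return sid


def build_graph(
    sequences: Sequence[str], scoring: AlignmentScoring = AlignmentScoring()
) -> POAGraph:
    """Fold a list of sequences into a PO-MSA graph, in input order."""
    if not sequences:
        raise ValueError("cannot build a PO-MSA graph from an empty group")
    graph = POAGraph()
    for seq in sequences:
        add_sequence(graph, seq, align_to_graph(graph, seq, scoring))
    return graph


def _column_order(graph: POAGraph, paths: Sequence[Sequence[int]]) -> dict[int, int]:
    """Topological order of aligned-link columns touched by *paths*.

    Returns ``{group id: column index}``.  Column precedence is induced by
    consecutive path nodes; ready columns are emitted smallest-id first for
    determinism.
    """
    used_groups: set[int] = set()
    succ: dict[int, set[int]] = {}
    indeg: dict[int, int] = {}
    for p in paths:
        for n in p:
            g = graph.group_of[n]
            if g not in used_groups:
                used_groups.add(g)
                succ[g] = set()
                indeg[g] = 0
    for p in paths:
        for a, b in zip(p, p[1:]):
            ga, gb = graph.group_of[a], graph.group_of[b]
            if ga != gb and gb not in succ[ga]:
                succ[ga].add(gb)
                indeg[gb] += 1
    heap = [g for g, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    col_of: dict[int, int] = {}
    while heap:
        g = heapq.heappop(heap)
        col_of[g] = len(col_of)
        for h in succ[g]:
            indeg[h] -= 1
            if indeg[h] == 0:
                heapq.heappush(heap, h)
    if len(col_of) != len(used_groups):
        raise RuntimeError("aligned-link columns do not admit a topological order")
    return col_of


def msa_of(
    graph: POAGraph,
    sequence_ids: Sequence[int],
    extra_paths: Sequence[Sequence[int]] | None = None,
) -> list[str]:
    """Rectangular MSA rows (gap ``-``) for the selected sequences.

    Columns follow a topological order in which aligned-linked (and fused)
    nodes share a column; removing the gaps from a row reproduces the stored
    sequence exactly.  *extra_paths* appends rows spelled from explicit node
    paths (used to place a consensus path inside its bundle's MSA).
    """
    paths: list[Sequence[int]] = [graph.paths[s] for s in sequence_ids]
    if extra_paths:
        paths.extend(extra_paths)
    if not paths:
        return []
    col_of = _column_order(graph, paths)
    width = len(col_of)
    rows = []
    for p in paths:
        row = [GAP] * width
        for n in p:
            row[col_of[graph.group_of[n]]] = graph.chars[n]
        rows.append("".join(row))
    return rows
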