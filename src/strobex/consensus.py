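"""Heaviest-bundle consensus generation on a PO-MSA graph.

The classic heaviest-bundle algorithm scores nodes in topological order by
the heaviest incoming edge chain and traces the best path back as the
consensus; sequences sharing at least ``b * length`` nodes with that path
form its bundle.  When one graph mixes sequences from several genomic
origins, the classic traceback can stitch a chimera out of two origins.  The
modified variant implemented here first identifies the most strongly
supported sequence — the one whose path minimises the weakness score
``s_w = e_m + e_w`` (strong edges missed plus weak edges carried), where an
edge is *strong* when its weight reaches ``t_w``, the weight of the i-th
heaviest edge for i the average active-sequence length — then temporarily
boosts that sequence's path edges, bundles the sequences similar to it,
boosts the whole bundle, and only then runs the heaviest-bundle traceback.
The boost steers the consensus onto a single origin without privileging any
one noisy sequence.  Accepted consensus sequences must pass a bundle-size
filter (``|B| >= max(g, z*|S|)``) and a per-column character-support filter
(every consensus character seen in at least ``c`` bundle rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import heaviest_path
from .poa import GAP, POAGraph, msa_of

__all__ = [
    "ConsensusParams",
    "ConsensusRecord",
    "heaviest_bundle",
    "edge_strength_threshold",
    "weakness_scores",
    "generate_consensus_sequences",
    "filter_consensus",
]

REJECT_BUNDLE = "bundle-size"
REJECT_SUPPORT = "character-support"


@dataclass(frozen=True)
class ConsensusParams:
    """Consensus acceptance and reweighting parameters.

    b : bundling threshold in (0,1) — a length-ℓ sequence joins a bundle
        when its path shares >= b*ℓ nodes with the consensus path.
    g : absolute minimum bundle size.
    z : proportional bundle threshold in (0,1), applied to the original
        group size |S|.
    c : character support threshold (bundle rows per consensus column).
    boost : bonus weight multiple added to each path edge of a boosted
        sequence during reweighting; ``None`` uses |S|, which guarantees
        the boosted family dominates the traceback.
    """

    b: float = 0.8
    g: int = 4
    z: float = 0.4
    c: int = 4
    boost: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.b < 1.0 and 0.0 < self.z < 1.0):
            raise ValueError("b and z must lie in (0, 1)")
        if self.g < 1 or self.c < 1:
            raise ValueError("g and c must be >= 1")


@dataclass
class ConsensusRecord:
    """One consensus sequence, its bundle, and the bundle MSA.

    ``msa`` holds one gapped row per bundle member (in ``bundle`` order)
    followed by ``consensus_row``, the consensus path written over the same
    columns.
    """

    consensus: str
    bundle: tuple[int, ...]
    msa: list[str]
    consensus_row: str
    accepted: bool
    reason: Optional[str] = None
    path: tuple[int, ...] = field(default=(), repr=False)


class _GraphIndex:
    """Array views of a frozen graph topology for fast consensus rounds."""

    def __init__(self, graph: POAGraph):
        edges = []
        eidx: dict[tuple[int, int], int] = {}
        seq_lists = []
        for u, v, ids in graph.edges():
            eidx[(u, v)] = len(edges)
            edges.append((u, v))
            seq_lists.append(sorted(ids))
        E = len(edges)
        n = graph.n_nodes
        self.n_edges = E
        self.edge_seq_ids = (
            np.concatenate([np.asarray(s, np.int64) for s in seq_lists])
            if E
            else np.zeros(0, np.int64)
        )
        self.edge_seq_indptr = np.zeros(E + 1, np.int64)
        acc = 0
        for i, s in enumerate(seq_lists):
            acc += len(s)
            self.edge_seq_indptr[i + 1] = acc
        # incoming-edge CSR by node id
        in_lists: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for i, (u, v) in enumerate(edges):
            in_lists[v].append((u, i))
        self.in_indptr = np.zeros(n + 1, np.int64)
        srcs: list[int] = []
        eis: list[int] = []
        for v in range(n):
            for u, i in in_lists[v]:
                srcs.append(u)
                eis.append(i)
            self.in_indptr[v + 1] = len(srcs)
        self.in_src = np.asarray(srcs, np.int64)
        self.in_eidx = np.asarray(eis, np.int64)
        self.topo = np.asarray(graph.topological_order(), np.int64)
        self.path_nodes = [np.asarray(p, np.int64) for p in graph.paths]
        self.path_edges = [
            np.asarray([eidx[(a, b)] for a, b in zip(p, p[1:])], np.int64)
            for p in graph.paths
        ]
        self.seq_lens = np.asarray([len(s) for s in graph.seqs], np.float64)

    def edge_weights(self, wt: np.ndarray) -> np.ndarray:
        if self.n_edges == 0:
            return np.zeros(0, np.float64)
        return np.add.reduceat(wt[self.edge_seq_ids], self.edge_seq_indptr[:-1])


def _index(graph: POAGraph) -> _GraphIndex:
    if graph._consensus_index is None:
        graph._consensus_index = _GraphIndex(graph)
    return graph._consensus_index


def _weights(graph: POAGraph, bonus: Optional[np.ndarray] = None) -> np.ndarray:
    wt = np.asarray(graph.active, np.float64)
    if bonus is not None:
        wt = wt * (1.0 + bonus)
    return wt


def heaviest_bundle(
    graph: POAGraph,
    params: ConsensusParams,
    _bonus: Optional[np.ndarray] = None,
) -> tuple[list[int], list[int]]:
    """One heaviest-bundle round: ``(consensus node path, bundle seq ids)``.

    With no boosting this is the classic algorithm: node scores accumulate
    along heaviest active incoming edges, the consensus is the traceback
    from the top-scoring node, and active sequences sharing >= b*ℓ nodes
    with it are bundled.  Raises ``ValueError`` when no sequence is active.
    """
    if not any(graph.active):
        raise ValueError("heaviest bundle requires at least one active sequence")
    idx = _index(graph)
    ew = idx.edge_weights(_weights(graph, _bonus))
    path_arr, _score = heaviest_path(idx.topo, idx.in_indptr, idx.in_src, idx.in_eidx, ew)
    path = path_arr.tolist()
    on_path = np.zeros(graph.n_nodes, bool)
    on_path[path_arr] = True
    bundle = [
        s
        for s in range(graph.n_sequences)
        if graph.active[s]
        and int(on_path[idx.path_nodes[s]].sum()) >= params.b * idx.seq_lens[s]
    ]
    return path, bundle


def edge_strength_threshold(graph: POAGraph) -> float:
    """Weight of the i-th heaviest active edge, i = average active length.

    The average active-sequence length is rounded to the nearest integer.
    Zero-weight edges (all their sequences deactivated) are ignored; when
    fewer than i positive edges exist, the minimum positive weight is used,
    so there are always at least i "strong" edges when i edges exist at all.
    """
    idx = _index(graph)
    active = np.asarray(graph.active, np.float64)
    if active.sum() == 0:
        raise ValueError("no active sequences")
    i = int(np.floor(idx.seq_lens[active > 0].mean() + 0.5))
    ew = idx.edge_weights(active)
    pos = np.sort(ew[ew > 0])[::-1]
    if pos.size == 0:
        return 0.0
    if pos.size < i:
        return float(pos[-1])
    return float(pos[max(i - 1, 0)])


def weakness_scores(graph: POAGraph, t_w: float) -> dict[int, int]:
    """Per-active-sequence weakness ``s_w = e_m + e_w`` at threshold *t_w*.

    ``e_m`` counts strong edges absent from the sequence's path and ``e_w``
    counts its path edges that are not strong; the most strongly supported
    sequence minimises the sum.
    """
    idx = _index(graph)
    ew = idx.edge_weights(np.asarray(graph.active, np.float64))
    strong = (ew >= t_w) & (ew > 0)
    n_strong = int(strong.sum())
    out: dict[int, int] = {}
    for s in range(graph.n_sequences):
        if not graph.active[s]:
            continue
        pe = idx.path_edges[s]
        on = int(strong[pe].sum()) if pe.size else 0
        out[s] = (n_strong - on) + (pe.size - on)
    return out


def filter_consensus(
    record: ConsensusRecord, group_size: int, params: ConsensusParams
) -> tuple[bool, Optional[str]]:
    """Apply the bundle-size and character-support acceptance filters.

    The bundle must satisfy ``|B| >= max(g, z*|S|)`` with |S| the original
    group size.  Then, for every column where the consensus row is not a
    gap, the consensus character must appear in at least ``c`` bundle rows;
    consensus-gap columns (bundle-only insertions) are ignored.
    """
    if len(record.bundle) < max(params.g, params.z * group_size):
        return False, REJECT_BUNDLE
    rows = record.msa[: len(record.bundle)]
    for col, ch in enumerate(record.consensus_row):
        if ch == GAP:
            continue
        support = sum(1 for row in rows if row[col] == ch)
        if support < params.c:
            return False, REJECT_SUPPORT
    return True, None


def _make_record(
    graph: POAGraph, path: list[int], bundle: list[int], group_size: int,
    params: ConsensusParams,
) -> ConsensusRecord:
    bundle = sorted(bundle)
    rows = msa_of(graph, bundle, extra_paths=[path])
    record = ConsensusRecord(
        consensus="".join(graph.chars[n] for n in path),
        bundle=tuple(bundle),
        msa=rows,
        consensus_row=rows[-1],
        accepted=False,
        path=tuple(path),
    )
    record.accepted, record.reason = filter_consensus(record, group_size, params)
    return record


def generate_consensus_sequences(
    graph: POAGraph,
    group_size: Optional[int] = None,
    params: ConsensusParams = ConsensusParams(),
) -> list[ConsensusRecord]:
    """Iteratively extract consensus sequences from one strobemer group.

    Each round: (1) find the edge-strength threshold, weakness scores and
    the strongest active sequence; (2) boost its path edges and run one
    heaviest-bundle pass to collect the sequences similar to it; (3) boost
    that whole initial bundle and run the final heaviest-bundle pass; (4)
    record the consensus with its bundle MSA and acceptance verdict; (5)
    deactivate the bundled sequences and repeat while bundles are non-empty
    and enough sequences remain.  The graph's active flags are restored on
    return.
    """
    if group_size is None:
        group_size = graph.n_sequences
    if graph.n_sequences == 0:
        return []
    saved_active = list(graph.active)
    boost = float(group_size) if params.boost is None else float(params.boost)
    bonus = np.zeros(graph.n_sequences, np.float64)
    records: list[ConsensusRecord] = []
    try:
        while True:
            n_active = sum(graph.active)
            if n_active == 0 or n_active < params.g:
                break
            t_w = edge_strength_threshold(graph)
            sw = weakness_scores(graph, t_w)
            strongest = min(sw, key=lambda s: (sw[s], s))
            bonus[:] = 0.0
            bonus[strongest] = boost
            _, initial_bundle = heaviest_bundle(graph, params, bonus)
            bonus[:] = 0.0
            bonus[initial_bundle] = boost
            path, bundle = heaviest_bundle(graph, params, bonus)
            bonus[:] = 0.0
            if not path:
                break
            records.append(_make_record(graph, path, bundle, group_size, params))
            for s in bundle:
                graph.active[s] = 0
            if not bundle:
                break
    finally:
        graph.active = saved_active
    return records
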