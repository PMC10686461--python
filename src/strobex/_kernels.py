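"""Numba-compiled inner loops for graph alignment and consensus scoring."""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**9))


@njit(cache=True)
def align_global(
    chars,  # uint8[N]  node characters in topological order (by rank)
    ids,  # int64[N]  node ids by rank (for deterministic tie-breaking)
    pred_indptr,  # int64[N+1]  CSR over predecessor lists, rank-indexed
    pred_ranks,  # int64[]   predecessor ranks
    pred_w,  # int64[]   weight of the incoming edge (tie-breaking)
    is_sink,  # bool[N]
    seq,  # uint8[m]
    match,
    mismatch,
    gap,
):
    """Global sequence-to-DAG alignment with deterministic traceback.

    DP rows follow topological rank; row 0 is a virtual start shared by all
    source nodes.  Ties prefer a diagonal move over a node-consuming gap over
    a sequence-consuming gap, and among predecessors the heavier incoming
    edge, then the smaller node id.  Returns ``(score, nodes, poss)`` where
    ``nodes[t]``/``poss[t]`` are the aligned (node rank, sequence position)
    pairs with -1 marking a gap on either side.
    """
    N = chars.shape[0]
    m = seq.shape[0]
    S = np.empty((N + 1, m + 1), np.int32)
    move = np.zeros((N + 1, m + 1), np.uint8)  # 1=diag 2=vert 3=horiz
    ptr = np.zeros((N + 1, m + 1), np.int32)

    for j in range(m + 1):
        S[0, j] = gap * j
        if j > 0:
            move[0, j] = 3
    big = np.int64(1) << np.int64(62)
    for r in range(1, N + 1):
        ri = r - 1
        p0 = pred_indptr[ri]
        p1 = pred_indptr[ri + 1]
        # column 0: vertical chain from the virtual start
        bv = NEG
        bpv = 0
        bwv = np.int64(-1)
        biv = big
        if p0 == p1:
            bv = S[0, 0] + gap
        else:
            for t in range(p0, p1):
                pr = pred_ranks[t] + 1
                cand = S[pr, 0] + gap
                w = pred_w[t]
                pid = ids[pr - 1]
                if cand > bv or (cand == bv and (w > bwv or (w == bwv and pid < biv))):
                    bv = cand
                    bpv = pr
                    bwv = w
                    biv = pid
        S[r, 0] = bv
        move[r, 0] = 2
        ptr[r, 0] = bpv
        nch = chars[ri]
        for j in range(1, m + 1):
            sub = match if seq[j - 1] == nch else mismatch
            bd = NEG
            bpd = 0
            bwd = np.int64(-1)
            bid = big
            bv = NEG
            bpv = 0
            bwv = np.int64(-1)
            biv = big
            if p0 == p1:
                bd = S[0, j - 1] + sub
                bv = S[0, j] + gap
            else:
                for t in range(p0, p1):
                    pr = pred_ranks[t] + 1
                    w = pred_w[t]
                    pid = ids[pr - 1]
                    cd = S[pr, j - 1] + sub
                    if cd > bd or (cd == bd and (w > bwd or (w == bwd and pid < bid))):
                        bd = cd
                        bpd = pr
                        bwd = w
                        bid = pid
                    cv = S[pr, j] + gap
                    if cv > bv or (cv == bv and (w > bwv or (w == bwv and pid < biv))):
                        bv = cv
                        bpv = pr
                        bwv = w
                        biv = pid
            ch = S[r, j - 1] + gap
            best = bd
            mv = np.uint8(1)
            bp = bpd
            if bv > best:
                best = bv
                mv = np.uint8(2)
                bp = bpv
            if ch > best:
                best = ch
                mv = np.uint8(3)
                bp = r
            S[r, j] = best
            move[r, j] = mv
            ptr[r, j] = bp

    # alignment must end at a sink node (or the virtual start if N == 0)
    er = 0
    bestS = NEG
    eid = big
    for r in range(1, N + 1):
        if is_sink[r - 1]:
            s = S[r, m]
            if s > bestS or (s == bestS and ids[r - 1] < eid):
                bestS = s
                er = r
                eid = ids[r - 1]
    if N == 0:
        bestS = S[0, m]

    nodes = np.empty(N + m + 2, np.int32)
    poss = np.empty(N + m + 2, np.int32)
    t = 0
    r = er
    j = m
    while r != 0 or j != 0:
        mv = move[r, j]
        if mv == 1:
            nodes[t] = r - 1
            poss[t] = j - 1
            r = ptr[r, j]
            j -= 1
        elif mv == 2:
            nodes[t] = r - 1
            poss[t] = -1
            r = ptr[r, j]
        else:
            nodes[t] = -1
            poss[t] = j - 1
            j -= 1
        t += 1
    return bestS, nodes[:t][::-1].copy(), poss[:t][::-1].copy()


@njit(cache=True)
def heaviest_path(order, in_indptr, in_src, in_eidx, eweights):
    """Heaviest-bundle path search over a DAG with per-edge weights.

    Scores nodes in topological *order*: each node picks its heaviest
    positive incoming edge and scores the edge's weight plus the chosen
    source's score (sources score 0).  Selecting by edge weight first — not
    by the weight+score sum — keeps a minority detour of several light
    edges from outvoting a single well-supported edge.  Edges with
    non-positive weight are treated as absent.  Ties prefer the
    higher-scoring, then smaller-id source; the traceback starts at the
    global best-scoring node (ties: smaller node id).
    """
    n = in_indptr.shape[0] - 1
    score = np.zeros(n, np.float64)
    back = np.full(n, -1, np.int64)
    best_score = -1.0
    best_node = -1
    for oi in range(order.shape[0]):
        u = order[oi]
        bs = 0.0
        bb = np.int64(-1)
        bw = -1.0
        for t in range(in_indptr[u], in_indptr[u + 1]):
            w = eweights[in_eidx[t]]
            if w <= 0.0:
                continue
            s = in_src[t]
            if (
                w > bw
                or (w == bw and (score[s] > bs - bw))
                or (w == bw and score[s] == bs - bw and (bb == -1 or s < bb))
            ):
                bs = w + score[s]
                bb = s
                bw = w
        score[u] = bs
        back[u] = bb
        if bs > best_score or (bs == best_score and (best_node == -1 or u < best_node)):
            best_score = bs
            best_node = u
    path = np.empty(n, np.int64)
    t = 0
    u = best_node
    while u != -1:
        path[t] = u
        t += 1
        u = back[u]
    return path[:t][::-1].copy(), best_score
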