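"""Modified heaviest-bundle consensus: thresholds, weakness, boosting, filters."""

import edlib
import numpy as np
import pytest

from strobex import (
    ConsensusParams,
    ConsensusRecord,
    build_graph,
    edge_strength_threshold,
    filter_consensus,
    generate_consensus_sequences,
    heaviest_bundle,
    weakness_scores,
)
from strobex.poa import POAGraph

from .conftest import random_dna
from .test_poa import noisy_copy

FIG_SEQS = ["AGAA", "AGACA", "AGACA", "ATATA", "ATATA", "ATTA"]
RELAXED = ConsensusParams(b=0.8, g=2, z=0.4, c=2)


def manual_two_path_graph():
    """Two disjoint 4-node paths: one carried by 3 sequences, one by 1."""
    g = POAGraph()
    for ch in "ACGTACGT":
        g._new_node(ch)
    for sid in range(3):
        g.paths.append([0, 1, 2, 3])
        g.seqs.append("ACGT")
        g.active.append(1)
        for u, v in zip([0, 1, 2], [1, 2, 3]):
            g._add_edge(u, v, sid)
    g.paths.append([4, 5, 6, 7])
    g.seqs.append("ACGT")
    g.active.append(1)
    for u, v in zip([4, 5, 6], [5, 6, 7]):
        g._add_edge(u, v, 3)
    return g


def spell(g, path):
    return "".join(g.chars[n] for n in path)


def naive_heaviest_path(g):
    """Independent dict-based reimplementation of the consensus scoring:
    each node takes its heaviest incoming edge (ties: higher source score,
    then smaller source id) and adds the source's score."""
    weights = {(u, v): sum(g.active[s] for s in ids) for u, v, ids in g.edges()}
    score, back = {}, {}
    for v in g.topological_order():
        best = None
        for u in g.preds[v]:
            w = weights[(u, v)]
            if w <= 0:
                continue
            cand = (w, score[u], -u)
            if best is None or cand > best:
                best = cand
                back[v] = u
        score[v] = (best[0] + best[1]) if best else 0
    end = min((n for n in score), key=lambda n: (-score[n], n))
    path = [end]
    while path[-1] in back:
        path.append(back[path[-1]])
    return path[::-1], score[end]


class TestHeaviestBundle:
    def test_single_sequence(self, rng):
        x = random_dna(rng, 20)
        g = build_graph([x])
        path, bundle = heaviest_bundle(g, RELAXED)
        assert spell(g, path) == x
        assert bundle == [0]

    def test_worked_example_is_chimeric(self):
        # uniform weights let the classic traceback stitch the two origins
        # into AGATA
        g = build_graph(FIG_SEQS)
        path, _ = heaviest_bundle(g, RELAXED)
        assert spell(g, path) == "AGATA"

    def test_matches_naive_scoring_oracle(self, rng):
        # the kernel's consensus path must equal a dict-based naive
        # reimplementation of the greedy heaviest-edge scoring
        for _ in range(60):
            origin = random_dna(rng, int(rng.integers(4, 12)))
            seqs = [s for s in (noisy_copy(rng, origin, 0.25) for _ in range(4)) if s]
            if not seqs:
                continue
            g = build_graph(seqs)
            path, _ = heaviest_bundle(g, RELAXED)
            expected, _ = naive_heaviest_path(g)
            assert path == expected

    def test_requires_active_sequences(self):
        g = build_graph(["ACGT"])
        g.active[0] = 0
        with pytest.raises(ValueError):
            heaviest_bundle(g, RELAXED)


class TestEdgeStrength:
    def test_single_sequence_all_edges_strong(self, rng):
        x = random_dna(rng, 10)
        g = build_graph([x])
        # i = 10 exceeds the 9 edges, so t_w is the minimum weight 1
        assert edge_strength_threshold(g) == 1.0
        sw = weakness_scores(g, 1.0)
        assert sw == {0: 0}

    def test_two_disjoint_paths(self):
        g = manual_two_path_graph()
        # weights {3,3,3,1,1,1}, i = 4 -> t_w is the 4th heaviest = 1
        assert edge_strength_threshold(g) == 1.0


class TestWeakness:
    def test_worked_example_strongest_is_full_length(self):
        g = build_graph(FIG_SEQS)
        t_w = edge_strength_threshold(g)
        sw = weakness_scores(g, t_w)
        best = min(sw.values())
        winners = {s for s, v in sw.items() if v == best}
        # the deletion-bearing AGAA (0) and ATTA (5) never win
        assert winners and winners.isdisjoint({0, 5})
        assert winners <= {1, 2, 3, 4}

    def test_matches_set_arithmetic_oracle(self, rng):
        for _ in range(20):
            origin = random_dna(rng, 15)
            seqs = [noisy_copy(rng, origin, 0.2) for _ in range(4)]
            g = build_graph(seqs)
            t_w = edge_strength_threshold(g)
            sw = weakness_scores(g, t_w)
            weights = {(u, v): sum(g.active[s] for s in ids) for u, v, ids in g.edges()}
            strong = {e for e, w in weights.items() if w >= t_w and w > 0}
            for sid, seq_path in enumerate(g.paths):
                path_edges = set(zip(seq_path, seq_path[1:]))
                e_m = len(strong - path_edges)
                e_w = len(path_edges - strong)
                assert sw[sid] == e_m + e_w


class TestGenerate:
    def test_identical_group_single_record(self, rng):
        x = random_dna(rng, 30)
        group = [x] * 6
        g = build_graph(group)
        params = ConsensusParams(b=0.8, g=4, z=0.4, c=4)
        recs = generate_consensus_sequences(g, len(group), params)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.consensus == x
        assert rec.bundle == tuple(range(6))
        assert rec.accepted

    def test_worked_example_recovers_both_origins(self):
        g = build_graph(FIG_SEQS)
        recs = generate_consensus_sequences(g, 6, RELAXED)
        accepted = [r.consensus for r in recs if r.accepted]
        assert accepted[0] == "AGACA"
        assert accepted == ["AGACA", "ATATA"]
        # bundles partition by origin and never reuse a removed sequence
        assert set(recs[0].bundle) == {0, 1, 2}
        assert set(recs[1].bundle) == {3, 4, 5}

    def test_zero_boost_single_round_reduces_to_classic(self):
        g = build_graph(FIG_SEQS)
        params = ConsensusParams(b=0.8, g=2, z=0.4, c=2, boost=0.0)
        recs = generate_consensus_sequences(g, 6, params)
        path, _ = heaviest_bundle(g, params)
        assert recs[0].consensus == spell(g, path) == "AGATA"

    def test_consensus_row_degaps_to_consensus(self, rng):
        origin = random_dna(rng, 40)
        group = [noisy_copy(rng, origin, 0.05) for _ in range(8)]
        g = build_graph(group)
        for rec in generate_consensus_sequences(g, len(group), RELAXED):
            assert rec.consensus_row.replace("-", "") == rec.consensus
            # consensus is a path in the graph
            for u, v in zip(rec.path, rec.path[1:]):
                assert v in g.succs[u]

    def test_active_flags_restored(self, rng):
        g = build_graph([random_dna(rng, 20)] * 4)
        generate_consensus_sequences(g, 4, RELAXED)
        assert g.active == [1, 1, 1, 1]

    def test_two_origin_separation(self, rng):
        # 10 sequences, 5+5 from two distinct 120-base origins at 3% error:
        # both origins must be recovered exactly in >= 90% of 50 trials.
        # Like any sequences grouped under one strobemer, the two origins
        # share the first and last strobe (7 bases each).
        params = ConsensusParams(b=0.8, g=3, z=0.4, c=3)
        hits = 0
        for trial in range(50):
            trial_rng = np.random.default_rng(1000 + trial)
            head, tail = random_dna(trial_rng, 7), random_dna(trial_rng, 7)
            o1 = head + random_dna(trial_rng, 106) + tail
            o2 = head + random_dna(trial_rng, 106) + tail
            group = [noisy_copy(trial_rng, o1, 0.03) for _ in range(5)]
            group += [noisy_copy(trial_rng, o2, 0.03) for _ in range(5)]
            g = build_graph(group)
            recs = generate_consensus_sequences(g, 10, params)
            accepted = [r.consensus for r in recs if r.accepted]
            if len(accepted) == 2:
                d1 = edlib.align(accepted[0], o1)["editDistance"]
                d2 = edlib.align(accepted[1], o2)["editDistance"]
                if {d1, d2} == {0} or (
                    edlib.align(accepted[0], o2)["editDistance"] == 0
                    and edlib.align(accepted[1], o1)["editDistance"] == 0
                ):
                    hits += 1
        assert hits >= 45

    def test_empty_graph(self):
        assert generate_consensus_sequences(POAGraph(), 0, RELAXED) == []


class TestFilter:
    def _record(self, bundle, msa, consensus_row):
        return ConsensusRecord(
            consensus=consensus_row.replace("-", ""),
            bundle=tuple(range(bundle)),
            msa=msa + [consensus_row],
            consensus_row=consensus_row,
            accepted=False,
        )

    def test_bundle_size_thresholds(self):
        params = ConsensusParams(b=0.8, g=3, z=0.4, c=1)
        rec = self._record(3, ["AAA"] * 3, "AAA")
        # |B|=3 vs max(3, 0.4*5)=3 passes; vs max(3, 0.4*10)=4 fails
        assert filter_consensus(rec, 5, params) == (True, None)
        ok, reason = filter_consensus(rec, 10, params)
        assert not ok and reason == "bundle-size"

    def test_character_support(self):
        params = ConsensusParams(b=0.8, g=2, z=0.1, c=3)
        msa = ["ACGT", "ACGT", "AAGT"]
        ok, reason = filter_consensus(self._record(3, msa, "ACGT"), 3, params)
        assert not ok and reason == "character-support"  # C supported twice

    def test_consensus_gap_columns_ignored(self):
        params = ConsensusParams(b=0.8, g=2, z=0.1, c=2)
        msa = ["ACGT", "ACGT", "AC-T"]
        assert filter_consensus(self._record(3, msa, "AC-T"), 3, params) == (True, None)
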