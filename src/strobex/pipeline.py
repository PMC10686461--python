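"""End-to-end pipeline: solid strobemers -> groups -> consensus -> k-mers.

The five steps are: (1) count canonical strobemers over the reads and keep
the solid ones (abundance >= a); (2) gather, per solid strobemer, the read
sequences it covers; (3) build a PO-MSA graph per group and generate
consensus sequences with the modified heaviest-bundle algorithm; (4) split
accepted consensus sequences into k-mers; (5) canonicalise and deduplicate.
The result is a set — independent of read order — and the run is fully
deterministic for a given configuration.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import consensus as cns
from . import counting, kmers, occurrences, simulate
from .poa import AlignmentScoring, build_graph
from .strobemer import MinimizerOrder, StrobemerParams

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_evaluation", "read_sequences"]

log = logging.getLogger("strobex")


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameter set of an extraction run.

    ``v`` defaults to the smallest window distance satisfying the coverage
    inequality ``(n-1)*v - w + l + 1 >= k`` for the requested k, so the
    covered sequences are long enough to yield k-mers while staying close
    to k.
    """

    k: int = 97
    n: int = 3
    l: int = 7
    w: int = 11
    v: Optional[int] = None
    a: int = 4
    order: str = "hash"
    consensus: cns.ConsensusParams = field(default_factory=cns.ConsensusParams)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def resolved(self) -> "PipelineConfig":
        """Fill in v (if unset) and validate the geometry against k."""
        v = self.v
        if v is None:
            v = kmers.min_v_for_k(self.n, self.l, self.w, self.k)
        cfg = replace(self, v=v)
        kmers.validate_parameters(cfg.strobemer_params, cfg.k)
        return cfg

    @property
    def strobemer_params(self) -> StrobemerParams:
        if self.v is None:
            raise ValueError("call resolved() first to solve for v")
        return StrobemerParams(n=self.n, l=self.l, v=self.v, w=self.w)

    @property
    def minimizer_order(self) -> MinimizerOrder:
        return MinimizerOrder(mode=self.order)


@dataclass
class PipelineResult:
    kmers: kmers.KmerSet
    report: dict


def run_pipeline(config: PipelineConfig, reads: Sequence[str]) -> PipelineResult:
    """Extract canonical k-mers from *reads* (two streaming passes + consensus)."""
    cfg = config.resolved()
    params = cfg.strobemer_params
    order = cfg.minimizer_order
    log.info(
        "pipeline: k=%d n=%d l=%d v=%d w=%d a=%d b=%.2f z=%.2f g=%d c=%d order=%s",
        cfg.k, cfg.n, cfg.l, cfg.v, cfg.w, cfg.a,
        cfg.consensus.b, cfg.consensus.z, cfg.consensus.g, cfg.consensus.c, cfg.order,
    )

    counts = counting.count_strobemers(reads, params, order)
    solid = counting.solid_strobemers(counts, cfg.a)
    index = occurrences.gather_occurrences(reads, solid, params, order)

    out = kmers.KmerSet(cfg.k)
    n_records = n_accepted = 0
    rejections: dict[str, int] = {}
    for group in index.by_int.values():
        graph = build_graph(group, cfg.scoring)
        for rec in cns.generate_consensus_sequences(graph, len(group), cfg.consensus):
            n_records += 1
            if rec.accepted:
                n_accepted += 1
                out.add_consensus(rec.consensus)
            else:
                rejections[rec.reason] = rejections.get(rec.reason, 0) + 1

    report = {
        "n_reads": len(reads),
        "n_strobemers_counted": counts.total,
        "n_distinct_strobemers": len(counts),
        "n_solid": len(solid),
        "n_groups": len(index.by_int),
        "n_consensus": n_records,
        "n_accepted": n_accepted,
        "n_rejected": rejections,
        "n_kmers": len(out),
        "too_short": out.too_short,
        "config": cfg,
    }
    log.info(
        "pipeline: %d groups -> %d consensus (%d accepted) -> %d k-mers",
        report["n_groups"], n_records, n_accepted, len(out),
    )
    return PipelineResult(kmers=out, report=report)


def run_evaluation(
    config: PipelineConfig,
    genome: str,
    reads: Sequence[str],
    ks: Sequence[int] | None = None,
    pipeline_a: Sequence[int] = (4, 5, 6),
    baseline_a: Sequence[int] = (2, 3, 4),
    circular: bool = True,
) -> pd.DataFrame:
    """Precision/recall table: this pipeline vs. exact counting, per k and a.

    For the pipeline rows the abundance sweep sets ``g = c = a`` as well,
    since the three support thresholds act as one coupled parameter (a
    bundle can never be larger than the group, and no consensus column can
    outnumber the bundle).
    """
    ks = list(ks) if ks is not None else [config.k]
    rows = []
    for k in ks:
        truth = simulate.reference_kmers(genome, k, circular=circular)
        for a in pipeline_a:
            cfg = replace(
                config, k=k, v=None, a=a,
                consensus=replace(config.consensus, g=a, c=a),
            )
            result = run_pipeline(cfg, reads)
            ev = simulate.precision_recall(result.kmers.kmers, truth)
            rows.append(("strobemer-consensus", k, a, ev.precision, ev.recall,
                         ev.n_true_positive, ev.n_reported, ev.n_truth))
        kmer_counts = simulate.count_kmers(reads, k)
        for a in baseline_a:
            reported = {km for km, n in kmer_counts.items() if n >= a}
            ev = simulate.precision_recall(reported, truth)
            rows.append(("exact-count", k, a, ev.precision, ev.recall,
                         ev.n_true_positive, ev.n_reported, ev.n_truth))
    return pd.DataFrame(
        rows,
        columns=["method", "k", "a", "precision", "recall",
                 "true_positives", "reported", "truth"],
    )


def read_sequences(path) -> list[str]:
    """Read sequences from FASTA or FASTQ, plain or gzipped."""
    from Bio import SeqIO

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        fmt = "fastq" if first == "@" else "fasta"
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)]
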