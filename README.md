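# strobex

Extraction of **long k-mers** (k ≈ 50–100) from **high-error long reads**.

k-mer–based methods (de Bruijn graph assembly, variant calling, repeat
analysis) benefit from long k-mers because those map uniquely to genomic
loci. But exact k-mer counting fails on noisy long reads: at a 6% per-base
error rate, a 97-mer survives error-free in a read with probability
0.94⁹⁷ ≈ 0.2%, so almost no genomic 97-mer reaches a usable abundance
threshold. `strobex` recovers them anyway by correcting only the k-mers,
never the reads:

1. **Group** read substrings of common genomic origin using *strobemers* —
   seeds built by concatenating `n` window minimizers (strobes) of length
   `l`, drawn from windows of `w` start positions spaced `v` apart.
   Because minimizers float inside their windows, strobemers tolerate the
   insertions and deletions that defeat spaced seeds. Every strobe is a
   minimizer, so a well-defined *canonical* (strand-independent) strobemer
   exists; strobemers occurring at least `a` times are *solid*, and each
   solid strobemer indexes the read sequences it covers.
2. **Align** each group into a partial-order MSA graph (characters as
   nodes, sequences as paths, matching characters fused).
3. **Call consensus** with a modified heaviest-bundle algorithm: edges
   with weight ≥ t_w (the i-th heaviest, i = mean sequence length) are
   *strong*; the sequence minimising the weakness score
   `s_w = e_m + e_w` (strong edges missed + weak edges carried) seeds a
   bundle of similar sequences whose edges are temporarily boosted, so the
   traceback follows one genomic origin instead of stitching a chimera.
   A consensus is accepted if its bundle B satisfies `|B| ≥ max(g, z·|S|)`
   and every consensus character is supported by ≥ `c` bundle rows.
4. **Split** accepted consensus sequences into k-mers, canonicalise
   (min of k-mer and reverse complement), deduplicate.

The window geometry must satisfy `(n−1)·v − w + l + 1 ≥ k` so every
grouped sequence is at least k long; `v` is solved from that inequality by
default. Defaults: `n=3, l=7, w=11, a=g=c=4, b=0.8, z=0.4`.

## Worked example

Simulate a 20 kb genome at 40× with 1 kb reads and 6% uniform errors
(substitution/insertion/deletion equally likely), then extract 97-mers and
compare with plain exact counting:

```sh
$ strobex simulate --genome-length 20000 --coverage 40 --read-length 1000 \
      --error-rate 0.06 --seed 7 --genome-out genome.fa --reads-out reads.fq
genome=20000bp reads=801 seed=7

$ strobex extract reads.fq -o kmers.txt -k 97
groups=51973 consensus=8921 accepted=5195 kmers=18568 too_short=7

$ strobex evaluate genome.fa reads.fq -o eval.tsv --kmer-lengths 97
             method  k  a  precision  recall  true_positives  reported  truth
strobemer-consensus 97  4   0.945228 0.87755           17551     18568  20000
strobemer-consensus 97  5   0.981401 0.78620           15724     16022  20000
strobemer-consensus 97  6   0.992441 0.66305           13261     13362  20000
        exact-count 97  2   0.895425 0.00685             137       153  20000
        exact-count 97  3   1.000000 0.00030               6         6  20000
        exact-count 97  4        NaN 0.00000               0         0  20000
```

Exact counting recovers fewer than 1% of the genome's 97-mers from these
reads; consensus extraction recovers 88% of them at 95% precision, with
the usual recall/precision trade-off as the abundance threshold `a` (tied
to `g` and `c` in the sweep) rises. `too_short` counts consensus
sequences below k, a rarity by construction of the geometry inequality.

The same machinery is available as a library:

```python
from strobex import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(k=97), reads)   # reads: list[str]
result.kmers.kmers                                   # set of canonical 97-mers
```

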