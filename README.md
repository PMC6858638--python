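# qtrimbench

A simulation benchmark for measuring how **right-side quality trimming**
affects the analysis of Illumina paired-end 16S rRNA amplicon reads: the
fraction of reads that survive merging and quality control (the *good
reads*), the post-trimming overlap geometry, and how close the recovered
community composition comes to a per-sample error-free **gold standard**.

It is aimed at microbiome bioinformaticians who want to choose a trimming
threshold for 2×300 V3-V4 data rationally — by simulating reads with a
known truth and sweeping the threshold — rather than by re-running a full
pipeline many times on real data.

## What it computes

Simulated samples are built from synthetic reference sequences carrying the
degenerate V3-V4 primer pair (341F `CCTACGGGNGGCWGCAG`, 785R
`GACTACHVGGGTATCTAATCC`). Each reference's amplicon (primer start through
reverse-primer site end, ≈465 nt) yields two 310-base read templates; reads
receive positional quality profiles with realistic 3′ decay (R2 worse than
R1) and per-base substitution errors drawn from the phred score
*Q* = −10·log₁₀(*P*ₑ). Every sample has an error-free, constant-Q40 twin:
its gold standard.

The pipeline then mirrors a standard amplicon workflow:

1. **Primer trim** — remove the first 17 (R1) / 21 (R2) bases.
2. **Quality trim** — cut the 3′ end at threshold *t* (Mott maximum-sum
   rule, or literal cut at the first base with *Q* < *t*).
3. **Merge pairs** — scan all overlaps, keep the one with the smallest
   mismatch percentage, reject if it exceeds the *percent maximum
   difference* *p*; reconcile overlap qualities (agree → max(q₁,q₂),
   disagree → higher-quality base with quality |q₁−q₂|).
4. **QC** — drop merged reads with mean quality < 25; survivors are the
   good reads.
5. **Evaluate** — per-sample composition vs. gold standard: false
   positive/negative percentages, binary Jaccard distances, classical PCoA,
   and the Euclidean sample-to-gold distance in the embedded space. The
   calculated overlap after trimming, len(R1′) + len(R2′) − amplicon span,
   is reported per cell; negative values are a gap, making merging
   impossible.

## Worked example

```python
from qtrimbench import SweepConfig, run_experiment

cfg = SweepConfig(q_thr_values=(0, 10, 12, 14, 18, 20), p_values=(8,), rng_seed=1)
df = run_experiment(cfg)
print(df.groupby("q_thr")[["good_fraction", "mean_overlap",
                           "fn_pct", "gold_distance"]].mean().round(3))
```

prints (10 samples, merge threshold *p* = 8):

```
       good_fraction  mean_overlap  fn_pct  gold_distance
q_thr
0              0.002       153.370  89.825          0.899
10             0.814        90.644   0.256          0.008
12             0.897        69.635   0.256          0.008
14             0.919        50.139   0.000          0.000
18             0.559         9.473   4.711          0.118
20             0.094       -10.006  52.577          0.536
```

Reading the table: without trimming almost no pair merges — the overlap
region sits in the low-quality read tails and exceeds the 8 % mismatch
budget — so nearly all references are missed (high FN, large gold
distance). Moderate trimming (thresholds 10–14) removes the bad tails
while leaving 50–90 bases of overlap: ~90 % good reads and near-zero
distance to the gold standard. At threshold 20 the mean calculated
overlap goes negative (a gap), merging collapses, and accuracy is lost
again.

The same sweep is available from the shell:

```sh
qtrimbench sweep --seed 1 --out-dir results/sweep --figures
```

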