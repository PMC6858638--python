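# Methods

## Scope and model

qtrimbench studies one question: how does right-side (3′) quality trimming
of paired-end 2×300 amplicon reads change (a) the number of reads that
survive merging and quality control, and (b) the accuracy of the community
composition recovered from them. Everything is simulated against a known
per-sample truth, so the effect of trimming can be isolated from reference
databases, chimeras, and pipeline idiosyncrasies.

The generative model, per sample:

1. A reference set of random sequences, each embedding one concrete
   realization of the degenerate forward primer (341F, 17 nt) and, downstream,
   one binding site of the reverse primer (785R, 21 nt). The span from
   forward-primer start to reverse-site end — the amplicon, primers
   included — is drawn from Normal(465, 10) nt and clipped to ≥ 311 so that
   two 310-nt read templates (R1 = first 310 bases, R2 = reverse complement
   of the last 310) always exist. 465 nt is the typical V3-V4 length
   between this primer pair; amplicons a little above and below 2×310−465
   produce both comfortable and marginal overlaps, which is exactly the
   regime of interest.
2. A quality-profile pool: for each mate, vectors of per-position phred
   scores drawn from a plateau-then-linear-decay model (defaults below)
   and stored/sampled with replacement, emulating pools of quality strings
   harvested from real FASTQ runs.
3. Reads: a random subset of references (20–60 per sample), a random copy
   count each (uniform 1–100), a pool profile per copy, and per-base
   substitution resampling driven by the quality score. Read ids encode
   `{sample}.{reference}.{copy}`, the provenance channel used by the
   evaluation stage.
4. A gold standard: the same multiset of reads with pristine template
   sequences and constant Q40 — processed by the identical pipeline.

## Error models

The per-base substitution uses `(p_called, p_alt)` with
`p_called + 3·p_alt = 1`:

- `standard_phred` (default): `p_error = 10^(−Q/10)`, so the called base
  keeps `1 − 10^(−Q/10)` and each alternative gets `10^(−Q/10)/3`. This is
  the phred definition and the only model under which high-quality bases
  are almost always correct.
- `as_printed`: the inverted mapping in which the *called* base keeps
  `10^(−Q/10)` itself — at Q=2 that is 0.63, each alternative
  (1−0.63)/3 ≈ 0.123. It is retained, verbatim, as a documented worked
  example of a quality-to-probability mapping sometimes stated this way;
  it is not the default because it makes good bases almost always wrong.
  Both are exposed; they are deliberately not reconciled.
- `none`: the gold-standard path (no resampling).

## Trimming

Primer trimming removes the first 17/21 bases by position (the primers are
part of the simulated reads). Quality trimming then cuts the right side at
threshold *t*:

- `mott` (default): keep the prefix `[0, k)` maximizing `Σ_{i<k} (Q_i − t)`,
  ties broken toward the longest prefix; `k` may be 0. This is the
  classical maximum-sum trimming rule used by mainstream read trimmers;
  the exact behavior of any given external tool is version-dependent, so
  the rule is implemented here explicitly and oracle-tested.
- `first_below`: cut at the first base with `Q < t` — the literal verbal
  definition of right-side threshold trimming.

Pairs in which either mate ends up shorter than `min_len = 50` are
discarded and counted; zero-length reads would break merging, and 50 nt is
well below any informative amplicon fragment.

## Merging and quality control

R2 is reverse-complemented (qualities reversed). Candidate overlaps run
from `min_overlap = 6` to min(len R1, len R2); all are scored in one
4-channel one-hot cross-correlation, and the overlap with the smallest
mismatch percentage wins, ties going to the longer overlap. The pair is
rejected when the best percentage strictly exceeds the percent maximum
difference `p`, so `p = 0` still admits perfect overlaps. Overlap
reconciliation: agreeing bases take `max(q1, q2)`; disagreeing positions
take the higher-quality base with quality `|q1 − q2|` (equal qualities fall
back to R1's base with quality 0). Substitutions only — the simulator
produces no indels, so the merger models none.

Merged reads with mean quality < `min_mean_q = 25` are dropped; the
survivors are the **good reads**, and the good-read fraction is good reads
divided by raw read pairs.

## Evaluation

- Composition is recovered per sample by provenance (default) or by exact
  sequence match against each reference's expected error-free joined
  product (amplicon minus primer regions); non-matching reads are counted
  unassigned. Provenance sidesteps database-dependent assignment, which is
  out of scope here.
- FP% = 100·|observed∖gold|/|observed| (0 when nothing observed);
  FN% = 100·|gold∖observed|/|gold|. The observed set is the denominator for
  FP and the gold set for FN; both raw set sizes are recoverable from the
  composition table if an alternative normalization is wanted.
- Jaccard distance: binary presence/absence by default
  (`1 − |A∩B|/|A∪B|`, via scipy); the quantitative min/max (Ruzicka)
  variant is available as a mode.
- PCoA: classical metric scaling — double-center `−D²/2`, eigendecompose,
  keep eigenvalues > 1e−10 (negative eigenvalues of non-Euclidean Jaccard
  matrices are dropped, no Lingoes/Cailliez correction — the simplest
  defensible rule), scale eigenvectors by √eigenvalue. Samples and gold
  standards are ordinated jointly, and the sample-to-gold distance is the
  Euclidean norm over all retained axes.
- The calculated overlap after trimming is
  `len(R1′) + len(R2′) − (amplicon − 17 − 21)`: trimmed reads measured
  against the primer-trimmed amplicon span, so a negative value is an
  actual gap and merging is genuinely impossible. (Measuring against the
  full amplicon would shift the zero crossing by 38 nt and break that
  equivalence.)

## Default parameters

| parameter | default | why |
|---|---|---|
| amplicon length | Normal(465, 10), ≥ 311 | V3-V4 between 341F/785R is ≈460–470 nt |
| template length | 310 | paired read templates cut from each amplicon end |
| plateau quality | Q38 | modern Illumina base line |
| quality floor | Q2 | Illumina's reserved no-call score |
| decay start / rate | position 150 / 0.2 per base | R1 reaches ≈Q8 by cycle 300: a weak-tail 2×300 run, the regime where trimming decisions matter |
| R2 penalty | 5 | reverse reads are systematically worse |
| profile noise sd | 3 | typical per-position spread |
| refs per sample | uniform 20–60 | moderate-diversity communities |
| copies per ref | uniform 1–100 | spans rare to abundant members |
| q_thr sweep | even 0–20 | threshold grid (0–30 for the longer variant) |
| p values | 4, 8, 12 | merger default 8 with one value each side; full grid 0–40 step 4 supported |
| min_overlap | 6 | merger's minimal informative overlap |
| min_mean_q | 25 | conventional mean-quality cutoff |
| min_len | 50 | discard fragments too short to merge meaningfully |

## What the generator does and does not emulate

Emulated: positional quality decay with R2 worse than R1, per-base
quality-driven substitutions, amplicon-length variation around the
primer pair, abundance variation over two orders of magnitude, error-free
gold twins.

Not emulated: indels, chimeras, PCR and GC bias, quality-dependent length
variation, degenerate-primer mismatch failures, real taxonomic sequence
similarity (references are random, so distinct references are nearly
orthogonal and exact-match assignment is easier than real OTU picking).
Passing tests therefore demonstrate the trimming–merging–geometry
mechanics, not database-level assignment accuracy on real communities.

## Numerical and design choices

- Overlap selection (min mismatch %, ties → longer) and strict-inequality
  rejection are explicit config-documented choices; merger internals of
  external tools are not otherwise specified.
- Mott output length is not guaranteed monotone in the threshold
  (the maximum-sum cut can jump); monotonicity is only asserted for
  `first_below`.
- Degenerate inputs: empty reads are representable, rejected by the merger
  with a reason, and dropped by QC; all-zero composition rows are excluded
  from the distance computation and reported as NaN gold distance.
- Determinism: every stage consumes a `numpy` Generator derived from one
  seed; identical seeds give byte-identical FASTQ output and identical
  sweep tables.

## Problem sizes

The shipped test and acceptance runs use desk-scale worlds: 60 references,
200-profile pools, 10 samples of ≈2 000 read pairs, a 6-point threshold
grid at p = 8, and 5 replicate seeds for the trend check; the error-free
recovery check uses 5 samples. These sizes give stable means (binomial
standard errors on good-read fractions < 1 %) while a full sweep run stays
around a minute per seed.

## Known limitations

- The trend claims are qualitative (directions and collapse), not
  calibrated to any particular instrument run; absolute good-read
  fractions depend strongly on the decay parameters.
- With provenance-based assignment, false positives can only arise from
  cross-sample id confusion (i.e. never, by construction); FP% becomes
  informative with `composition_mode="exact_match"` or any future
  similarity-based assigner.
- The merger scans substitution-only overlaps; reads from indel-bearing
  platforms would need an alignment-based merger.
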