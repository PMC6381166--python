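# Methods

## The two-step gating model

The simulator treats mature piRNA production as two sequential gates applied
to candidate 5′ ends arising inside piRNA clusters:

1. **Processing gate.** The endonucleolytic machinery that defines piRNA 5′
   ends accepts a candidate whose first nucleotide is `x` with relative
   weight `w_proc(x)`, normalized so `w_proc(U) = 1`. This gate is
   independent of the PIWI specificity loop and discriminates mainly against
   purines.
2. **Specificity-loop (SL) gate.** A processed piRNA is loaded and retained
   with probability `a_sl(x)` given its first nucleotide. In the wild type
   the SL discriminates against 1C (`a_sl(C) < 1`); the SL-mutant condition
   models loss of that selectivity by setting every `a_sl` to 1.

Inside a cluster with first-position base probabilities `f(x)` (bases drawn
i.i.d. on the producing strand), the retained-piRNA first-nucleotide
distribution has the closed form

```
p(x) = f(x) · w_proc(x) · a_sl(x) / Σ_m f(m) · w_proc(m) · a_sl(m)
```

implemented in `expected_first_nt_freqs` and used throughout the test suite
as the exact oracle for the sampler.

### Phased sampling

Within a cluster the simulator walks the producing strand 5′→3′:

- A chain starts at a uniform position and scans forward one base at a time
  until a base passes the processing gate; because cluster bases are i.i.d.,
  the accepted base is distributed exactly as `f·w / Σ f·w`.
- The 3′ end of each piRNA comes from a **single coupled cut**: one length
  `L` is proposed from the length distribution, and the cut is accepted with
  the processing weight of the base at 5′ + L — that base is simultaneously
  the candidate 5′ end of the next piRNA. A rejected cut abandons the site
  without emitting a read. This one-shot rule is essential: retrying length
  proposals against the same fixed window of downstream bases would
  renormalize acceptance over whatever bases happen to be there and provably
  biases the first-nucleotide marginal (we measured 1U = 0.618 instead of
  the closed form 0.683); the single-shot rule keeps both the
  first-nucleotide and the length marginals exact, and makes the next 5′ end
  land exactly one piRNA length downstream, which is what produces the ±26
  U peaks in the metagene.
- After an accepted cut the chain continues head-to-tail at the cut with
  probability `phasing_prob`, otherwise it jumps a geometric gap
  (mean `1/gap_p` = 20 nt) and rescans.
- Retention applies two independent gates to each cut piRNA: an optional
  **body gate** `exp(α·(G_body − U_body − 1))` favouring G-rich/U-poor
  bodies (the body excludes position 0, so the first-nucleotide closed form
  is untouched), and the SL gate `a_sl(first nt)`.

The walk never depends on retention outcomes and every cut consumes the same
random draws in both conditions, so wild-type and SL-mutant libraries
generated from the same seed share an identical cut stream and differ only
through SL rejection — the wild-type read set is a subset of the matched
mutant's over the shared stream.

### Default calibration

| parameter | default | rationale |
| --- | --- | --- |
| cluster `f` (T, A, G, C) | 0.30, 0.28, 0.23, 0.19 | U/A-rich source loci against a uniform background |
| `w_proc` (U, A, G, C) | 1.00, 0.18, 0.15, 0.42 | purine depletion during processing |
| `a_sl` wild type (U, A, G, C) | 1, 1, 1, 0.68 | SL discriminates only against 1C |
| length pmf 24–29 nt | 0.08, 0.17, 0.35, 0.22, 0.12, 0.06 | mode 26 nt |
| `phasing_prob` | 0.7 | most piRNAs arise head-to-tail |
| body exponent α | 0.5 | mild body U-depletion / G-enrichment |
| `multimap_frac` | 0.15 | exercises unique/all-mapper filtering |

With these values the closed form gives wild-type p(1U) = 0.683 and
p(1C) = 0.124, SL-mutant p(1U) = 0.646 and p(1C) = 0.172 — hence a
per-cluster 1U bias (o/e) of 0.683/0.30 ≈ 2.28, mutant-over-wild-type 1C
increase of ≈ 39%, and a wild-type/mutant 1C-bias ratio of ≈ 0.72
(≈ `a_sl(C)` up to the normalization shift). The mechanistic rates are not
measured quantities; they are calibrated once so that these closed-form
expectations reproduce the observed summary statistics, and the tests treat
them as fixed study conditions.

### Genome geometry

The default synthetic genome places 12 clusters of 200 kb on two 1.4-Mb
contigs, clusters at least 5 kb apart and from contig ends, strand chosen at
random per cluster (minus-strand clusters carry the reverse complement on
the reference). The 200-kb scale matches large fly piRNA clusters such as
flamenco and, at the default library depth of 10⁵ reads, keeps distinct 5′
sites far from saturation: collapsed (one-count-per-distinct-5′-end)
metagene frequencies then agree with the read-weighted closed form to within
a few thousandths. Much denser configurations (e.g. 10⁵ reads on 50-kb
clusters) saturate U-starting sites first and visibly compress the
collapsed 1U frequency — a real phenomenon of collapsed analyses at high
depth, but not the regime the default conditions target.

`simulate_genome` accepts either one base-frequency vector for all clusters
or one per cluster, which is how the composition-tracking analyses vary
cluster T content (0.22–0.38, other bases rescaled proportionally).

Multimappers are fabricated by duplicating a retained read at a second
random locus: the true-locus alignment stays primary with multiplicity 2,
the fabricated secondary is flagged non-primary. The duplicate's sequence is
the read's sequence, not the sequence at the random locus — the minimal
structure needed to exercise the M = 1 / M ≤ 100 filters.

## Analysis conventions

- **Coordinates** are 0-based half-open everywhere internally; BED is native,
  GTF is converted from 1-based inclusive at the boundary, and SAM flags/POS
  are mapped on read. `U` in inputs becomes `T` internally; first-nucleotide
  outputs are reported as U/A/G/C.
- **Cluster calling** tiles each contig with fixed-phase non-overlapping
  1-kb bins from position 0; a bin is occupied at ≥ 1 unique-read 5′ end
  (both strands pooled) and maximal runs of ≥ 5 occupied bins become
  clusters spanning the full bin run. Fixed bins make the density rule
  deterministic; boundary sensitivity to bin phase is tolerated because
  recovery is judged by interval overlap (Jaccard ≥ 0.8 against truth on
  simulated data; ≈ 0.99 in practice), not exact breakpoints.
- **Metagene profiles** collapse distinct (contig, strand, 5′-coordinate)
  triples to one count each (a `weighted` flag restores read-count
  weighting). Windows are extracted in read orientation; 5′ ends within
  50 nt of a contig edge are dropped and logged rather than N-padded, which
  keeps per-position denominators exact. The default applies the 24–29 nt
  filter first, consistent with the other analyses; a flag disables it.
- **Baseline shift** subtracts each base's median frequency over the 101
  positions; it is presentation-only — a per-base constant shift leaves
  Pearson correlations unchanged, which the suite asserts — so correlations
  are computed on raw frequencies.
- **Phasing peak** is the argmax of a base's frequency in a search window
  that must exclude position 0; exact ties break toward the position closest
  to 0.
- **Bias tables** drop clusters with fewer than 50 assigned reads (the
  multinomial noise floor at which per-cluster frequencies are usable; the
  threshold is a flag). Expected frequencies use the full called cluster
  span, and the two strands' compositions (minus = complemented) are
  combined weighted by the cluster's per-strand read counts — piRNAs define
  which strand "generates", and the weighting degrades gracefully for
  single-strand and mixed clusters. `--strand-policy` exposes plus-strand
  and pooled alternatives since the convention is not canonical.
- **Annotation** assigns a read to a feature when at least half the read
  lies inside it, with precedence TE > exon > intron > intergenic and ties
  broken by longest overlap then leftmost feature; each read is counted
  exactly once, so category counts sum to the library size.

## What the simulator does and does not emulate

It emulates: compositionally biased clusters on both strands, phased 24–29-nt
piRNAs with a 1U-biased 5′ end, coupled 5′/3′ processing leaving U peaks one
piRNA length up- and downstream of collapsed 5′ ends, body U-depletion and
G-enrichment, unique- and multi-mapping reads, and matched wild-type /
SL-mutant libraries differing only in first-nucleotide acceptance.

It does not model sequencing error, adapter artifacts, ping-pong (slicer-
dependent) biogenesis, 3′-trimming heterogeneity, non-i.i.d. genomic
sequence (repeats, motifs, isochores), or expression differences between
clusters beyond length-proportional sampling. Consequently, passing tests
demonstrate correctness of the analysis code and internal consistency of the
gating model — not that real libraries will show the same effect sizes; in
real data the background genomic structure contributes profile variance that
the i.i.d. genome lacks (most visible in the base-C metagene correlation,
which is structure-poor here).

## Numerical choices and problem sizes

Simulated analyses in the tests and the acceptance script use 4×10⁴–2×10⁵
reads per library: large enough that multinomial noise on first-nucleotide
frequencies is ~10⁻³ and the phased U peak is unambiguous, small enough to
run interactively. Probability vectors must sum to 1 within 1e-9; profiles
validate row sums at the same tolerance. All randomness flows from a single
seed per simulate call through `numpy.random.SeedSequence`, with a spawned
substream for multimapper fabrication so that the processing/retention
stream stays condition-aligned. Degenerate inputs (empty read sets, clusters
rejecting every nucleotide, zero-variance correlation inputs, windows off
contig ends) raise or warn explicitly rather than returning silent NaNs,
except where a missing value is the documented answer (undefined Pearson r).

## Known limitations

- The cluster caller's bin phase is fixed at contig position 0; a cluster
  straddling a bin boundary can extend its called span by up to one bin on
  each side, which slightly dilutes expected cluster composition with
  background sequence (visible as a ≲ 1% upward shift of per-cluster 1U
  bias).
- The body gate is a modeling choice: the mechanism behind body U-depletion
  is not specified by the gating hypothesis, and `exp(α·(G−U−1))` is the
  simplest retention form that produces the observed direction without
  touching the first position.
- `interval_jaccard` is quadratic per contig in the number of merged
  intervals — fine at cluster counts, not meant for dense feature sets.
- SAM support is the small-RNA subset (single-M CIGAR, NH tag); spliced or
  clipped alignments are dropped with a logged count, not parsed.
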