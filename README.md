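# pirnabias

Analysis toolkit for the 5′ nucleotide bias of PIWI-interacting RNAs
(piRNAs), with a generative simulator of phased piRNA biogenesis for
end-to-end testing and parameter recovery.

## The scientific problem

Mature piRNAs (24–29 nt small RNAs bound by PIWI-clade Argonaute proteins)
overwhelmingly start with uridine — the **1U bias**. Two mechanisms can
produce it: sequence preference of the endonucleolytic processing machinery
that creates piRNA 5′ ends, and selection by the **specificity loop (SL)**
of the PIWI MID domain that anchors the small RNA's first base. This package
implements the sequencing-side analyses that disentangle the two, for anyone
working with aligned small-RNA libraries from wild-type and SL-mutant PIWI
immunoprecipitates:

- **Read filters** — the standard selection rules: 24–29 nt length window,
  unique mappers (M = 1) vs primary alignments of multimappers (M ≤ 100),
  interval blacklists for structural RNAs.
- **Cluster calling** — piRNA source loci defined as ≥ 1 unique-mapping read
  per kb sustained over ≥ 5 kb.
- **Composition metrics** — length distributions, first-nucleotide
  frequencies f(1x), annotation by transposon / exon / intron category in
  sense and antisense orientation.
- **Metagene profiling** — per-position base frequencies in a 101-nt window
  around collapsed piRNA 5′ ends (positions −50…+50), a genomic background
  model over all candidate cluster positions (optionally stratified by first
  nucleotide), median baseline shifting, per-base Pearson correlation between
  samples, and detection of the phased-processing signature: a U peak one
  piRNA length (±26 nt) from the anchored 5′ ends.
- **Bias analysis** — per cluster, the observed first-nucleotide frequency
  f(1x) of its piRNAs versus the expected genomic frequency f(x) of the
  cluster interval; their ratio o/e is the **nucleotide bias**. A universal
  processing mechanism predicts a constant ~2.3-fold 1U enrichment across
  clusters and a positive correlation between f(1U) and cluster T content.

## The gating simulator

`pirnabias.synth` generates a synthetic genome with U/A-rich piRNA clusters
and simulates phased libraries under a **two-step gating model**:

```
p(1x) = f(x) · w_proc(x) · a_sl(x) / Σ_m f(m) · w_proc(m) · a_sl(m)
```

where `f` is the cluster base composition, `w_proc` the processing-stage
acceptance per first nucleotide (1 for U, < 1 for A/G/C), and `a_sl` the
SL acceptance (wild type discriminates against 1C; the SL-mutant condition
sets all to 1). Consecutive piRNAs are produced head-to-tail: one cut
defines the current 3′ end and the next 5′ end, so 5′-to-5′ distances follow
the piRNA length distribution (mode 26 nt). The closed form above is the
exact oracle for the sampler, and wild-type/mutant libraries simulated from
the same seed share their cut stream, differing only through SL rejection.
See `docs/methods.md` for the model in full.

## Worked example

```sh
pirnabias run-all --out-dir demo --seed 7 --n-reads 50000
```

simulates a genome (12 clusters × 200 kb on two 1.4-Mb contigs), generates
paired wild-type and SL-mutant libraries of 50,000 reads, then runs
filtering, cluster calling, metrics, metagene profiling, and bias analysis
for both conditions. It prints (abridged):

```json
{
  "wt_clusters_called": 12,
  "wt_truth_jaccard": 0.9962,
  "wt_f1U": 0.6855,
  "wt_f1C": 0.1245,
  "wt_downstream_U_peak": 26,
  "wt_median_bias_U": 2.2929,
  "sl_mutant_f1U": 0.6466,
  "sl_mutant_f1C": 0.1708,
  "sl_mutant_median_bias_C": 0.8982,
  "metagene_r_wt_vs_mutant": {"U": 0.9982, "A": 0.9975, "G": 0.9977, "C": 0.8237}
}
```

Reading the numbers: the caller recovers the true clusters almost exactly
(Jaccard 0.996); both conditions keep a strong 1U bias (68.6% vs 64.7%) with
a constant ~2.3-fold per-cluster 1U enrichment; losing SL selectivity raises
1C from 12.5% to 17.1% (≈ +37%, moving the 1C bias from 0.65 toward 1); the
metagene U frequency peaks 26 nt downstream of collapsed 5′ ends (the phased
processing signature); and wild-type and mutant profiles stay highly
correlated for every base, showing the body preferences are SL-independent.
Per-stage TSV/BED/FASTA outputs and a `manifest.json` with parameters and
checksums land in `demo/`.

Every stage is also a subcommand (`simulate`, `filter`, `clusters`,
`metrics`, `metagene`, `bias`) operating on SAM/TSV reads, FASTA genomes,
BED intervals, and GTF-like annotations. The read TSV dialect has columns
`contig start end strand sequence multiplicity is_primary` (0-based
half-open, sequence in read orientation).

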