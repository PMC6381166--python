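"""Per-cluster observed/expected first-nucleotide bias.

For each piRNA cluster the observed quantity is the first-nucleotide
frequency f(1x) of the piRNAs it produces, the expected quantity is the
genomic frequency f(x) of that base over the cluster interval, and their
ratio o/e is the "nucleotide bias".  A processing mechanism with
composition-independent gating predicts a constant bias across clusters
(about 2.3-fold for 1U) and a positive correlation between observed 1U
frequency and cluster T-content.
"""
from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AlignedRead, ClusterInterval, RNA_LABELS, dna_to_u, encode, u_to_dna
from .clusters import assign_reads_to_clusters

_STRAND_POLICIES = ("weighted", "plus", "producing_pooled")


def _interval_base_freqs(genome: Mapping[str, str], contig: str, start: int,
                         end: int) -> np.ndarray:
    """Plus-strand A,C,G,T frequencies of a genomic interval (N excluded)."""
    codes = encode(genome[contig][start:end])
    counts = np.bincount(codes, minlength=5)[:4].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"interval {contig}:{start}-{end} has no determinate bases")
    return counts / total


def cluster_bias_table(
    reads: Sequence[AlignedRead],
    clusters: Sequence[ClusterInterval],
    genome: Mapping[str, str],
    min_reads: int = 50,
    strand_policy: str = "weighted",
) -> pd.DataFrame:
    """Observed vs expected first-nucleotide frequencies per cluster.

    Reads (unique mappers) are assigned to clusters by their 5' end; clusters
    with fewer than ``min_reads`` assigned reads are dropped.  Observed is the
    first-nucleotide frequency of the cluster's reads.  Expected is the
    cluster interval's base composition: per strand (minus strand =
    complemented composition), combined according to ``strand_policy`` —
    ``"weighted"`` (default) weights the two strands by the cluster's read
    counts per strand, ``"plus"`` uses the reference strand, and
    ``"producing_pooled"`` averages both strands (which for composition
    equals a strand-symmetrized expectation).  Returns one row per cluster x
    base with columns ``cluster, base, observed, expected, bias, n_reads``.
    A base with zero expected frequency but nonzero observed yields an
    infinite bias with a warning.
    """
    if strand_policy not in _STRAND_POLICIES:
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    assignment = assign_reads_to_clusters(reads, clusters)
    rows = []
    for ci, cluster in enumerate(clusters):
        idx = np.flatnonzero(assignment == ci)
        if len(idx) < min_reads:
            continue
        counts = dict.fromkeys(RNA_LABELS, 0)
        n_plus = 0
        for i in idx:
            r = reads[i]
            b = r.first_nt
            if b in counts:
                counts[b] += 1
            if r.strand == "+":
                n_plus += 1
        n = sum(counts.values())
        if n < min_reads:
            continue
        observed = {b: counts[b] / n for b in RNA_LABELS}

        plus = _interval_base_freqs(genome, cluster.contig, cluster.start, cluster.end)
        minus = plus[::-1]  # complement composition in A,C,G,T order
        if strand_policy == "plus":
            comp = plus
        elif strand_policy == "producing_pooled":
            comp = (plus + minus) / 2.0
        else:
            n_minus = len(idx) - n_plus
            total = max(n_plus + n_minus, 1)
            comp = (n_plus * plus + n_minus * minus) / total
        expected = {dna_to_u(b): float(comp["ACGT".index(b)]) for b in "ACGT"}

        for b in RNA_LABELS:
            e = expected[b]
            o = observed[b]
            if e == 0 and o > 0:
                warnings.warn(
                    f"cluster {cluster.name}: base {b} absent from interval but "
                    "observed in reads; bias is infinite", stacklevel=2)
                bias = float("inf")
            else:
                bias = o / e if e > 0 else float("nan")
            rows.append((cluster.name, b, o, e, bias, n))
    return pd.DataFrame(rows, columns=["cluster", "base", "observed", "expected",
                                       "bias", "n_reads"])


def bias_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the o/e bias per base across clusters."""
    if table.empty:
        raise ValueError("empty bias table")
    rows = []
    for base in RNA_LABELS:
        vals = table.loc[table["base"] == base, "bias"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if not len(vals):
            rows.append((base, float("nan"), float("nan"), float("nan")))
            continue
        rows.append((base, float(np.median(vals)),
                     float(np.percentile(vals, 25)), float(np.percentile(vals, 75))))
    return pd.DataFrame(rows, columns=["base", "median", "q1", "q3"])


def composition_correlation(table: pd.DataFrame, base: str) -> float:
    """Pearson r across clusters between observed f(1x) and genomic f(x).

    Uses complete pairwise observations only; requires at least three
    clusters.  Zero variance in either series gives NaN with a warning.
    """
    from scipy import stats

    label = dna_to_u(base) if base.upper() == "T" else base.upper()
    sub = table[table["base"] == label]
    x = sub["expected"].to_numpy(dtype=float)
    y = sub["observed"].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 clusters with complete observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"zero variance for base {label}; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
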