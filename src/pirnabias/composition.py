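"""Per-library summary metrics: length distribution, first-nucleotide
frequencies, and annotation of reads by genomic category and transposon
targeting potential."""
from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .core import AlignedRead, Feature, RNA_LABELS, dna_to_u

_CATEGORY_ORDER = ["TE_sense", "TE_antisense", "exon_sense", "exon_antisense",
                   "intron_sense", "intron_antisense", "intergenic"]
_PRECEDENCE = {"TE": 0, "exon": 1, "intron": 2}


@dataclass(frozen=True)
class FirstNtFrequencies:
    """First-position nucleotide frequencies of a read set (RNA labels)."""

    freqs: dict[str, float]
    n: int

    def __getitem__(self, base: str) -> float:
        return self.freqs[dna_to_u(base) if base.upper() == "T" else base.upper()]

    def to_series(self) -> pd.Series:
        return pd.Series(self.freqs, name="frequency")


def length_distribution(reads: Sequence[AlignedRead], lo: int = 22, hi: int = 30,
                        normalize_to: int | None = None) -> pd.Series:
    """Histogram of read lengths over ``[lo, hi]``.

    With ``normalize_to`` the counts are divided by the total mapped-read
    count and rescaled to the given reference library size, matching
    between-library normalization of size profiles.
    """
    if lo > hi:
        raise ValueError(f"lo {lo} > hi {hi}")
    counts = pd.Series(0.0, index=pd.RangeIndex(lo, hi + 1, name="length"))
    for r in reads:
        if lo <= len(r) <= hi:
            counts[len(r)] += 1
    if normalize_to is not None:
        total = len(reads)
        if total == 0:
            raise ValueError("cannot normalize an empty library")
        counts = counts / total * normalize_to
    counts.name = "count"
    return counts


def first_nt_frequencies(reads: Sequence[AlignedRead]) -> FirstNtFrequencies:
    """Tally the first base of each read's sequence (reported as U/A/G/C)."""
    if not reads:
        raise ValueError("empty read set")
    counts = dict.fromkeys(RNA_LABELS, 0)
    for r in reads:
        b = r.first_nt
        if b in counts:
            counts[b] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no reads with a determinate first nucleotide")
    return FirstNtFrequencies({b: counts[b] / n for b in RNA_LABELS}, n)


def annotate_reads(
    reads: Sequence[AlignedRead],
    features: Sequence[Feature],
) -> tuple[dict[str, int], pd.Series]:
    """Classify reads by annotation category and count antisense TE families.

    A read overlaps a feature when at least half of the read length lies
    within it; sense/antisense is strand match/mismatch.  Category precedence
    is TE > exon > intron > intergenic, with ties within a precedence level
    broken by longest overlap, then leftmost feature.  Every read lands in
    exactly one category.  The returned Series counts reads antisense to each
    transposon family.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if len(f) == 0:
            continue
        trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)

    categories = dict.fromkeys(_CATEGORY_ORDER, 0)
    family_counts: dict[str, int] = {}
    for r in reads:
        tree = trees.get(r.contig)
        best: tuple[int, int, int, Feature] | None = None  # (prec, -ovl, start, feat)
        if tree is not None:
            half = len(r)  # overlap*2 >= read length
            for hit in tree.overlap(r.start, r.end):
                f: Feature = hit.data
                ovl = min(r.end, f.end) - max(r.start, f.start)
                if 2 * ovl < half:
                    continue
                key = (_PRECEDENCE[f.kind], -ovl, f.start, f)
                if best is None or key[:3] < best[:3]:
                    best = key
        if best is None:
            categories["intergenic"] += 1
            continue
        f = best[3]
        orientation = "sense" if f.strand == r.strand else "antisense"
        categories[f"{f.kind}_{orientation}"] += 1
        if f.kind == "TE" and orientation == "antisense":
            fam = f.family or "unknown"
            family_counts[fam] = family_counts.get(fam, 0) + 1

    fam = pd.Series(family_counts, dtype="int64", name="antisense_reads").sort_index()
    return categories, fam
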