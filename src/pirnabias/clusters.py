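"""piRNA cluster calling from unique-mapping read 5' ends.

A cluster is a genomic region sustaining at least one unique-mapping read per
kilobase over at least five kilobases.  The rule is made deterministic by
tiling each contig with fixed-phase, non-overlapping ``bin_size`` bins from
position 0: a bin is occupied when at least ``min_reads_per_bin`` unique-read
5' ends (both strands pooled) fall in it, and every maximal run of at least
``min_bins`` consecutive occupied bins is reported as one cluster spanning
the whole run.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np

from .core import AlignedRead, ClusterInterval

__all__ = ["call_clusters", "assign_reads_to_clusters", "interval_jaccard"]


def call_clusters(
    reads: Sequence[AlignedRead],
    contig_lengths: Mapping[str, int],
    bin_size: int = 1000,
    min_bins: int = 5,
    min_reads_per_bin: int = 1,
) -> list[ClusterInterval]:
    """Call clusters from unique-mapper 5' ends by binned read density.

    ``reads`` should already be unique mappers; cluster intervals are
    strand-agnostic and span full bin runs (not trimmed to outermost reads).
    Raises if any read sits on a contig absent from ``contig_lengths``.
    """
    if bin_size < 1 or min_bins < 1 or min_reads_per_bin < 1:
        raise ValueError("bin_size, min_bins and min_reads_per_bin must be >= 1")
    unknown = sorted({r.contig for r in reads} - set(contig_lengths))
    if unknown:
        raise ValueError(f"reads on contigs absent from the genome: {unknown}")

    ends_by_contig: dict[str, list[int]] = {}
    for r in reads:
        ends_by_contig.setdefault(r.contig, []).append(r.five_prime)

    clusters: list[ClusterInterval] = []
    for contig in sorted(ends_by_contig):
        clen = contig_lengths[contig]
        ends = np.asarray(ends_by_contig[contig])
        if (ends < 0).any() or (ends >= clen).any():
            raise ValueError(f"read 5' end outside contig {contig}")
        n_bins = -(-clen // bin_size)
        counts = np.bincount(ends // bin_size, minlength=n_bins)
        occupied = counts >= min_reads_per_bin
        # maximal runs of occupied bins
        padded = np.concatenate([[False], occupied, [False]])
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1)
        for b0, b1 in zip(run_starts, run_ends):
            if b1 - b0 < min_bins:
                continue
            start, end = int(b0) * bin_size, min(int(b1) * bin_size, clen)
            n = int(counts[b0:b1].sum())
            clusters.append(ClusterInterval(
                contig, start, end, unique_read_count=n,
                density=n / ((end - start) / 1000.0),
                name=f"cluster_{len(clusters)}"))
    return clusters


def assign_reads_to_clusters(
    reads: Sequence[AlignedRead],
    clusters: Sequence[ClusterInterval],
) -> np.ndarray:
    """Map each read to the cluster containing its 5' end, or -1.

    Returns an int array parallel to ``reads`` with indices into ``clusters``.
    Clusters must be non-overlapping.
    """
    by_contig: dict[str, list[tuple[int, int, int]]] = {}
    for i, c in enumerate(clusters):
        by_contig.setdefault(c.contig, []).append((c.start, c.end, i))
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    ids: dict[str, np.ndarray] = {}
    for contig, ivs in by_contig.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping clusters on {contig} at {s2}")
        starts[contig] = np.array([iv[0] for iv in ivs])
        ends[contig] = np.array([iv[1] for iv in ivs])
        ids[contig] = np.array([iv[2] for iv in ivs])

    out = np.full(len(reads), -1, dtype=np.int64)
    for i, r in enumerate(reads):
        if r.contig not in starts:
            continue
        p = r.five_prime
        j = int(np.searchsorted(starts[r.contig], p, side="right")) - 1
        if j >= 0 and p < ends[r.contig][j]:
            out[i] = ids[r.contig][j]
    return out


def interval_jaccard(a: Sequence, b: Sequence) -> float:
    """Jaccard index between two interval sets (total overlap / total union).

    Accepts any objects with ``contig``/``start``/``end`` attributes.
    """
    def merged(ivs):
        by: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            by.setdefault(iv.contig, []).append((iv.start, iv.end))
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, spans in by.items():
            spans.sort()
            acc = [list(spans[0])]
            for s, e in spans[1:]:
                if s <= acc[-1][1]:
                    acc[-1][1] = max(acc[-1][1], e)
                else:
                    acc.append([s, e])
            out[contig] = [(s, e) for s, e in acc]
        return out

    ma, mb = merged(a), merged(b)
    inter = 0
    total_a = sum(e - s for spans in ma.values() for s, e in spans)
    total_b = sum(e - s for spans in mb.values() for s, e in spans)
    for contig in set(ma) & set(mb):
        for s1, e1 in ma[contig]:
            for s2, e2 in mb[contig]:
                inter += max(0, min(e1, e2) - max(s1, s2))
    union = total_a + total_b - inter
    return inter / union if union else 0.0
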