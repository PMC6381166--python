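"""Read-selection rules applied before any analysis.

All filters are pure, idempotent, and commute with each other.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

from intervaltree import IntervalTree

from .core import AlignedRead, GenomicInterval

logger = logging.getLogger(__name__)


def filter_by_length(reads: Sequence[AlignedRead], min_len: int = 24,
                     max_len: int = 29) -> list[AlignedRead]:
    """Keep reads with ``min_len <= length <= max_len`` (default 24-29 nt)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [r for r in reads if min_len <= len(r) <= max_len]
    if len(kept) != len(reads):
        logger.info("length filter %d-%d nt: dropped %d of %d reads",
                    min_len, max_len, len(reads) - len(kept), len(reads))
    return kept


def filter_by_mapping(reads: Sequence[AlignedRead], mode: str = "unique",
                      max_multiplicity: int = 100) -> list[AlignedRead]:
    """Select unique mappers (M=1) or primary alignments of multimappers.

    ``mode="unique"`` keeps reads with exactly one genomic alignment;
    ``mode="all_mappers"`` keeps primary alignments with multiplicity up to
    ``max_multiplicity`` (default 100).  Non-primary alignments are dropped
    in both modes.
    """
    if mode == "unique":
        kept = [r for r in reads if r.multiplicity == 1 and r.is_primary]
    elif mode == "all_mappers":
        kept = [r for r in reads
                if r.is_primary and r.multiplicity <= max_multiplicity]
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")
    if len(kept) != len(reads):
        logger.info("mapping filter (%s): dropped %d of %d alignments",
                    mode, len(reads) - len(kept), len(reads))
    return kept


def filter_blacklist(reads: Sequence[AlignedRead],
                     blacklist: Iterable[GenomicInterval]) -> list[AlignedRead]:
    """Remove reads overlapping any blacklist interval (strand-blind).

    Stands in for structural-RNA removal: rRNA/tRNA/snRNA/snoRNA loci are
    supplied as intervals rather than re-aligned against.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in blacklist:
        if len(iv) == 0:
            continue
        trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)
    if not trees:
        return list(reads)
    kept = [r for r in reads
            if r.contig not in trees or not trees[r.contig].overlap(r.start, r.end)]
    if len(kept) != len(reads):
        logger.info("blacklist filter: dropped %d of %d reads",
                    len(reads) - len(kept), len(reads))
    return kept


def filter_contigs(reads: Sequence[AlignedRead],
                   allowed: Iterable[str]) -> list[AlignedRead]:
    """Keep reads on an allow-list of contigs (drops e.g. unplaced scaffolds)."""
    allowed = set(allowed)
    kept = [r for r in reads if r.contig in allowed]
    if len(kept) != len(reads):
        logger.info("contig filter: dropped %d of %d reads",
                    len(reads) - len(kept), len(reads))
    return kept
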