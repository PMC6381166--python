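"""Metagene nucleotide-frequency profiles around piRNA 5' ends.

The central object is a 101-position x 4-base frequency matrix centered on
collapsed piRNA 5' ends (positions -50..+50, 0 = the first piRNA base, the
piRNA body spanning roughly 0..+25).  A genomic background model treats every
cluster position (optionally stratified by first nucleotide) as a candidate
5' end.  Helpers provide median baseline shifting for presentation,
per-base Pearson correlation between profiles, and detection of the phased
processing signature (the U peak one piRNA-length away from position 0).
"""
from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignedRead, COMP_CODE, DNA_BASES, RNA_LABELS, encode, u_to_dna

logger = logging.getLogger(__name__)

FLANK = 50
_CHUNK = 65_536


@dataclass(frozen=True)
class NucleotideProfile:
    """Per-position base frequencies around aligned 5' ends.

    ``freqs`` is a ``(101, 4)`` array in A,C,G,T column order over positions
    -50..+50; ``n_ends`` counts the contributing (collapsed) 5' ends.  For a
    normalized profile each row sums to 1; baseline-shifted profiles
    (``normalized=False``) do not.
    """

    freqs: np.ndarray
    n_ends: int
    normalized: bool = True
    positions: np.ndarray = field(default_factory=lambda: np.arange(-FLANK, FLANK + 1))

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (len(self.positions), 4):
            raise ValueError(f"profile shape {f.shape} != ({len(self.positions)}, 4)")
        if self.normalized and not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("normalized profile rows must sum to 1")

    def base_series(self, base: str) -> np.ndarray:
        """Frequencies of one base (RNA or DNA label) across positions."""
        col = DNA_BASES.index(u_to_dna(base))
        return np.asarray(self.freqs)[:, col]

    def frequency(self, base: str, position: int) -> float:
        idx = int(np.searchsorted(self.positions, position))
        if idx >= len(self.positions) or self.positions[idx] != position:
            raise KeyError(f"position {position} outside profile")
        return float(self.base_series(base)[idx])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: position, base (U/A/G/C), frequency, n."""
        rows = []
        for label in RNA_LABELS:
            series = self.base_series(label)
            for pos, freq in zip(self.positions, series):
                rows.append((int(pos), label, float(freq), self.n_ends))
        return pd.DataFrame(rows, columns=["position", "base", "frequency", "n"])


def _accumulate(counts: np.ndarray, codes: np.ndarray, ends: np.ndarray,
                minus: bool, flank: int) -> int:
    """Add window base counts for 5' ends on one contig/strand; returns #used."""
    n = len(codes)
    valid = (ends >= flank) & (ends < n - flank)
    ends = ends[valid]
    if not len(ends):
        return 0
    offsets = np.arange(-flank, flank + 1)
    n_pos = 2 * flank + 1
    col = np.arange(n_pos)
    for i in range(0, len(ends), _CHUNK):
        chunk = ends[i:i + _CHUNK]
        if minus:
            idx = chunk[:, None] - offsets[None, :]
            mat = COMP_CODE[codes[idx]]
        else:
            idx = chunk[:, None] + offsets[None, :]
            mat = codes[idx]
        flat = (col[None, :] * 5 + mat).ravel()
        counts += np.bincount(flat, minlength=n_pos * 5).reshape(n_pos, 5)[:, :4]
    return len(ends)


def _finalize(counts: np.ndarray, n_ends: int, n_dropped: int,
              what: str) -> NucleotideProfile:
    if n_ends == 0:
        raise ValueError(f"no usable 5' ends for {what} profile")
    if n_dropped:
        logger.info("%s profile: dropped %d 5' ends within %d nt of a contig edge",
                    what, n_dropped, FLANK)
    denom = counts.sum(axis=1, keepdims=True)
    if (denom == 0).any():
        raise ValueError("position with zero determinate bases")
    return NucleotideProfile(freqs=counts / denom, n_ends=n_ends)


def metagene_profile(reads: Sequence[AlignedRead], genome: Mapping[str, str],
                     weighted: bool = False) -> NucleotideProfile:
    """Nucleotide frequencies in the 101-nt window around collapsed 5' ends.

    Each distinct (contig, strand, 5'-coordinate) triple contributes once
    (``weighted=True`` instead weights by read count).  Windows are extracted
    in read orientation — reverse complemented for minus-strand ends, so
    position +1 is the read's second base.  Ends whose window would run off a
    contig are dropped and logged.
    """
    groups: dict[tuple[str, str], dict[int, int]] = {}
    for r in reads:
        if r.contig not in genome:
            raise ValueError(f"read contig {r.contig!r} absent from genome")
        key = (r.contig, r.strand)
        d = groups.setdefault(key, {})
        p = r.five_prime
        d[p] = d.get(p, 0) + 1

    counts = np.zeros((2 * FLANK + 1, 4), dtype=np.int64)
    n_ends = 0
    n_total = 0
    for (contig, strand), pdict in sorted(groups.items()):
        codes = encode(genome[contig])
        if weighted:
            ends = np.repeat(np.fromiter(pdict.keys(), dtype=np.int64),
                             np.fromiter(pdict.values(), dtype=np.int64))
        else:
            ends = np.fromiter(pdict.keys(), dtype=np.int64)
        n_total += len(ends)
        n_ends += _accumulate(counts, codes, ends, strand == "-", FLANK)
    return _finalize(counts, n_ends, n_total - n_ends, "metagene")


def background_profile(clusters: Sequence, genome: Mapping[str, str],
                       stratify_first_nt: str | None = None) -> NucleotideProfile:
    """Genomic background: every cluster position as a candidate 5' end.

    Both strands of every cluster interval are used; with
    ``stratify_first_nt`` only positions whose strand-oriented base equals the
    given base (U/A/G/C) contribute, mirroring the "all possible 1X-starting
    piRNAs" background.  Windows extend beyond cluster boundaries into
    flanking genome but are dropped at contig edges.
    """
    want = None
    if stratify_first_nt is not None:
        want = DNA_BASES.index(u_to_dna(stratify_first_nt))
    counts = np.zeros((2 * FLANK + 1, 4), dtype=np.int64)
    n_ends = 0
    n_total = 0
    for c in clusters:
        codes = encode(genome[c.contig])
        span = np.arange(c.start, c.end, dtype=np.int64)
        for minus in (False, True):
            if want is None:
                ends = span
            else:
                base_at = COMP_CODE[codes[span]] if minus else codes[span]
                ends = span[base_at == want]
            n_total += len(ends)
            n_ends += _accumulate(counts, codes, ends, minus, FLANK)
    return _finalize(counts, n_ends, n_total - n_ends, "background")


def baseline_shift(profile: NucleotideProfile) -> NucleotideProfile:
    """Subtract each base's median frequency across the window.

    Presentation aid that puts the four nucleotide signatures on a common
    baseline; the output rows no longer sum to 1.
    """
    f = np.asarray(profile.freqs)
    shifted = f - np.median(f, axis=0, keepdims=True)
    return NucleotideProfile(freqs=shifted, n_ends=profile.n_ends, normalized=False)


def profile_correlation(profile_a: NucleotideProfile,
                        profile_b: NucleotideProfile) -> dict[str, float]:
    """Per-base Pearson r between two profiles over the position grid.

    Computed on raw frequencies (a per-base baseline shift leaves Pearson r
    unchanged).  A base with zero variance in either profile yields NaN with
    a warning.
    """
    if not np.array_equal(profile_a.positions, profile_b.positions):
        raise ValueError("profiles are on different position grids")
    out: dict[str, float] = {}
    for label in RNA_LABELS:
        x = profile_a.base_series(label)
        y = profile_b.base_series(label)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero variance for base {label}; correlation undefined",
                          stacklevel=2)
            out[label] = float("nan")
        else:
            out[label] = float(stats.pearsonr(x, y).statistic)
    return out


def phasing_peak(profile: NucleotideProfile, search_lo: int, search_hi: int,
                 base: str = "U") -> int:
    """Position of maximal ``base`` frequency within ``[search_lo, search_hi]``.

    The window must lie within the profile and exclude position 0; exact ties
    are broken toward the position closest to 0.  Under phased processing the
    U peak sits one piRNA-length away from the anchor (around +/-26).
    """
    positions = profile.positions
    if search_lo > search_hi:
        raise ValueError("empty search window")
    if search_lo < positions[0] or search_hi > positions[-1]:
        raise ValueError("search window outside profile")
    if search_lo <= 0 <= search_hi:
        raise ValueError("search window must exclude position 0")
    mask = (positions >= search_lo) & (positions <= search_hi)
    vals = profile.base_series(base)[mask]
    pos = positions[mask]
    best = vals.max()
    ties = pos[vals == best]
    return int(min(ties, key=lambda p: (abs(int(p)), int(p))))
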