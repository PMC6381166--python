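"""Core data types and sequence utilities shared across the pipeline.

Coordinate convention: 0-based, half-open everywhere inside the package.
Sequences are DNA (``ACGT``); input ``U`` is normalized to ``T`` on load and
first-nucleotide results are reported with RNA labels (``U`` for ``T``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: DNA alphabet in internal code order (A=0, C=1, G=2, T=3; anything else 4).
DNA_BASES = "ACGT"

#: Reporting order for first-nucleotide tables, matching small-RNA convention.
RNA_LABELS = ("U", "A", "G", "C")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(DNA_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3

#: complement in code space (N stays N)
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (``U`` treated as ``T``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def dna_to_u(base: str) -> str:
    """Map a DNA base to its RNA reporting label (``T`` -> ``U``)."""
    b = base.upper()
    return "U" if b == "T" else b


def u_to_dna(base: str) -> str:
    """Map an RNA reporting label to its DNA base (``U`` -> ``T``)."""
    b = base.upper()
    return "T" if b == "U" else b


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One mapped small-RNA read.

    ``sequence`` is in read orientation (5'->3' of the RNA): for a minus-strand
    alignment it equals the reverse complement of the genomic slice
    ``[start, end)``.  ``multiplicity`` is the number of genomic alignments of
    the underlying read (the M of unique-vs-multimapper filtering);
    ``is_primary`` marks the designated best alignment.
    """

    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    multiplicity: int = 1
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval length "
                f"{self.end - self.start}"
            )
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (strand aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_nt(self) -> str:
        """First nucleotide of the read, as an RNA label (U/A/G/C)."""
        return dna_to_u(self.sequence[0])


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A generic BED-style interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class ClusterInterval:
    """A piRNA-generating genomic interval with read-density metadata.

    ``density`` is unique-mapping read 5' ends per kilobase over the span.
    """

    contig: str
    start: int
    end: int
    unique_read_count: int = 0
    density: float = 0.0
    name: str = "."

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class Feature:
    """A typed annotation interval (transposon / exon / intron) with strand."""

    contig: str
    start: int
    end: int
    strand: str
    kind: str  # "TE" | "exon" | "intron"
    family: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"feature without usable strand: {self.strand!r}")
        if self.kind not in ("TE", "exon", "intron"):
            raise ValueError(f"unknown feature kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start
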