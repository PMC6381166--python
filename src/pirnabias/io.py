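"""Readers and writers for the formats the pipeline touches.

Everything is normalized at this boundary to the internal data model:
0-based half-open coordinates, uppercase DNA with ``U`` mapped to ``T``,
read-orientation sequences.  Supported formats: FASTA (genome), BED6
(intervals/clusters), SAM (subset: flag, pos, single-``M`` CIGAR, NH tag),
GTF-like features, and a plain read TSV with columns
``contig  start  end  strand  sequence  multiplicity  is_primary``.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AlignedRead, ClusterInterval, Feature, GenomicInterval, revcomp

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["contig", "start", "end", "strand", "sequence", "multiplicity", "is_primary"]


# ---------------------------------------------------------------- FASTA

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as ``{contig: sequence}``, uppercased, U->T."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (3-6 columns) as 0-based half-open intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = []
    for row in df.itertuples(index=False):
        row = list(row) + ["."] * (6 - len(row))
        name = "." if pd.isna(row[3]) else str(row[3])
        score = 0.0 if row[4] in (".", None) or pd.isna(row[4]) else float(row[4])
        strand = "." if pd.isna(row[5]) else str(row[5])
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]),
                                   name=name, score=score, strand=strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval | ClusterInterval], path: str | Path) -> None:
    """Write intervals as BED6 (cluster unique-read counts go to the score column)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, ClusterInterval):
                name, score, strand = iv.name, iv.unique_read_count, "."
            else:
                name, score, strand = iv.name, iv.score, iv.strand
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


def clusters_from_bed(intervals: Iterable[GenomicInterval]) -> list[ClusterInterval]:
    """Interpret BED6 intervals (score = unique read count) as clusters."""
    out = []
    for iv in intervals:
        kb = len(iv) / 1000.0
        out.append(ClusterInterval(iv.contig, iv.start, iv.end,
                                   unique_read_count=int(iv.score),
                                   density=(iv.score / kb if kb else 0.0),
                                   name=iv.name))
    return out


# ---------------------------------------------------------------- SAM

def _read_sam(path: str | Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    n_spliced = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for i, aln in enumerate(fh.fetch(until_eof=True), start=1):
            if aln.is_unmapped:
                continue
            cigar = aln.cigartuples
            if cigar is None or len(cigar) != 1 or cigar[0][0] != 0:
                # anything but a single M run (spliced/clipped) is out of scope
                n_spliced += 1
                continue
            seq = aln.query_sequence
            if seq is None:
                raise ValueError(f"{path}: malformed record at alignment line {i}: missing SEQ")
            if aln.reference_name is None or aln.reference_start < 0:
                raise ValueError(f"{path}: malformed record at alignment line {i}")
            seq = seq.upper().replace("U", "T")
            strand = "-" if aln.is_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)  # SAM stores reference-strand sequence
            try:
                mult = int(aln.get_tag("NH"))
            except KeyError:
                mult = 1
            try:
                reads.append(AlignedRead(
                    contig=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_start + cigar[0][1],
                    strand=strand,
                    sequence=seq,
                    multiplicity=mult,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record at alignment line {i}: {exc}") from exc
    if n_spliced:
        logger.info("dropped %d spliced/clipped alignments from %s", n_spliced, path)
    return reads


def write_sam(reads: Iterable[AlignedRead], contig_lengths: Mapping[str, int],
              path: str | Path) -> None:
    names = list(contig_lengths)
    header = pysam.AlignmentHeader.from_references(names, [contig_lengths[n] for n in names])
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"read_{i}"
            a.reference_name = r.contig
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigartuples = [(0, len(r))]
            flag = 0
            if r.strand == "-":
                flag |= 16
            if not r.is_primary:
                flag |= 256
            a.flag = flag
            a.query_sequence = revcomp(r.sequence) if r.strand == "-" else r.sequence
            a.set_tag("NH", r.multiplicity, value_type="i")
            fh.write(a)


# ---------------------------------------------------------------- read TSV

def _read_tsv(path: str | Path) -> list[AlignedRead]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "sequence": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
    reads = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            reads.append(AlignedRead(
                contig=row.contig, start=int(row.start), end=int(row.end),
                strand=row.strand,
                sequence=str(row.sequence).upper().replace("U", "T"),
                multiplicity=int(row.multiplicity),
                is_primary=bool(row.is_primary)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed record at line {i}: {exc}") from exc
    return reads


def write_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.contig, r.start, r.end, r.strand, r.sequence, r.multiplicity, r.is_primary)
         for r in reads], columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path, format: str = "sam") -> list[AlignedRead]:
    """Read aligned small-RNA reads from SAM or the package's TSV dialect."""
    if format == "sam":
        return _read_sam(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown alignment format {format!r}")


def write_alignments(reads: Sequence[AlignedRead], path: str | Path,
                     format: str = "tsv",
                     contig_lengths: Mapping[str, int] | None = None) -> None:
    if format == "sam":
        if contig_lengths is None:
            raise ValueError("SAM output needs contig lengths for the header")
        write_sam(reads, contig_lengths, path)
    elif format == "tsv":
        write_tsv(reads, path)
    else:
        raise ValueError(f"unknown alignment format {format!r}")


# ---------------------------------------------------------------- GTF-like features

_KINDS = {"te": "TE", "transposable_element": "TE", "exon": "exon", "intron": "intron"}


def read_features(path: str | Path) -> list[Feature]:
    """Read a GTF-like annotation into typed features.

    The feature column (3) must be one of ``TE``/``exon``/``intron``
    (repeat-masker style transposon records may also use ``exon`` with a
    ``family_id`` attribute, which is classified as TE).  1-based inclusive
    coordinates are converted to 0-based half-open; the TE family is taken
    from the ``family_id`` attribute, falling back to ``gene_id``.
    """
    out: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                f = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: unparsable feature: {exc}") from exc
            if f.strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: feature without strand")
            family = None
            for key in ("family_id", "gene_id"):
                if key in f.attributes:
                    family = f.attributes[key][0]
                    break
            kind = _KINDS.get(f.featuretype.lower())
            if kind is None:
                raise ValueError(f"{path}:{lineno}: unsupported feature type "
                                 f"{f.featuretype!r} (expected TE/exon/intron)")
            if kind == "exon" and "family_id" in f.attributes:
                kind = "TE"
            if f.start < 1:
                raise ValueError(f"{path}:{lineno}: negative/zero 1-based coordinate")
            out.append(Feature(contig=f.seqid, start=f.start - 1, end=f.end,
                               strand=f.strand, kind=kind, family=family))
    return out


def write_features(features: Iterable[Feature], path: str | Path) -> None:
    """Write features back as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for f in features:
            if f.kind == "TE":
                attrs = f'family_id "{f.family or "unknown"}";'
            else:
                attrs = f'gene_id "{f.family or "."}";'
            fh.write(f"{f.contig}\tpirnabias\t{f.kind}\t{f.start + 1}\t{f.end}\t."
                     f"\t{f.strand}\t.\t{attrs}\n")
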