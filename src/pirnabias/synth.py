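"""Generative model of phased piRNA biogenesis with two-step 5' gating.

The simulator emulates the production of PIWI-bound piRNAs from U/A-rich
genomic source loci ("piRNA clusters") under a two-step gating model:

1. **Processing gate.** Endonucleolytic cuts that create piRNA 5' ends prefer
   uridine and discriminate against purines: a candidate 5' end whose first
   nucleotide is ``n`` is accepted with relative weight ``w_proc[n]``
   (``w_proc[U] = 1`` by convention).  Consecutive piRNAs are produced
   head-to-tail ("phasing"): a single cut defines both the 3' end of the
   current piRNA and the 5' end of the next one, so the distance between
   neighbouring 5' ends equals a piRNA length and the next first nucleotide is
   itself processing-gated.
2. **Specificity-loop (SL) gate.** A processed piRNA is loaded and retained
   with probability ``a_sl[n]`` given its first nucleotide — in the wild type
   the SL discriminates against 1C; the SL-mutant condition sets all
   acceptance probabilities to 1.

Because candidate first nucleotides are drawn i.i.d. from the cluster base
composition ``f``, the first-nucleotide distribution of retained piRNAs has
the closed form

    p(n) = f(n) * w_proc(n) * a_sl(n) / sum_m f(m) * w_proc(m) * a_sl(m)

(:func:`expected_first_nt_freqs`), which serves as the exact oracle for the
sampler.  An optional body-composition gate (exponent ``body_weight``) retains
piRNAs with G-rich / U-poor bodies preferentially; since the body excludes the
first position it leaves the closed form untouched.

Wild-type and SL-mutant libraries simulated from the same seed share the
identical cut stream and differ only through the SL rejection step.
"""
from __future__ import annotations

import bisect
import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AlignedRead, DNA_BASES, decode, dna_to_u, encode, revcomp

logger = logging.getLogger(__name__)

WT = "wt"
SL_MUTANT = "sl_mutant"

#: Default producing-strand base composition of simulated clusters (U/A-rich).
DEFAULT_CLUSTER_BASE_FREQS: dict[str, float] = {"A": 0.28, "C": 0.19, "G": 0.23, "T": 0.30}

#: Default background (non-cluster) genome composition.
DEFAULT_BACKGROUND_BASE_FREQS: dict[str, float] = {b: 0.25 for b in DNA_BASES}

#: Processing-stage first-nucleotide weights (U convention: key T means 1U).
DEFAULT_W_PROC: dict[str, float] = {"T": 1.00, "A": 0.18, "G": 0.15, "C": 0.42}

#: Wild-type specificity-loop acceptance probabilities.
DEFAULT_A_SL: dict[str, float] = {"T": 1.0, "A": 1.0, "G": 1.0, "C": 0.68}

#: Length distribution over 24-29 nt (mode 26).
DEFAULT_LENGTH_PMF: dict[int, float] = {24: 0.08, 25: 0.17, 26: 0.35, 27: 0.22, 28: 0.12, 29: 0.06}

MIN_LEN = 24
MAX_LEN = 29


def normalize_condition(condition: str) -> str:
    c = condition.lower().replace("-", "_")
    if c in (WT, "wildtype", "wild_type"):
        return WT
    if c in (SL_MUTANT, "mutant", "sl"):
        return SL_MUTANT
    raise ValueError(f"unknown condition {condition!r}; expected 'wt' or 'sl_mutant'")


def _as_base_map(freqs: Mapping[str, float], what: str, *, check_sum: bool = True) -> dict[str, float]:
    """Normalize a base->value mapping to DNA keys (accepts U for T)."""
    out = {}
    for k, v in freqs.items():
        b = "T" if k.upper() == "U" else k.upper()
        if b not in DNA_BASES:
            raise ValueError(f"{what}: unknown base {k!r}")
        out[b] = float(v)
    if set(out) != set(DNA_BASES):
        raise ValueError(f"{what}: need all four bases, got {sorted(out)}")
    if any(v < 0 for v in out.values()):
        raise ValueError(f"{what}: negative value")
    if check_sum and abs(sum(out.values()) - 1.0) > 1e-9:
        raise ValueError(f"{what}: values must sum to 1, got {sum(out.values())}")
    return out


@dataclass(frozen=True)
class GatingModel:
    """Parameters of the two-step gating simulator.

    Parameters
    ----------
    cluster_base_freqs
        Base probabilities on the piRNA-producing strand of clusters.
    w_proc
        Processing-stage relative weight per first nucleotide, max 1 at U.
    a_sl
        Specificity-loop acceptance probability per first nucleotide
        (wild type; the SL-mutant condition replaces these with 1).
    length_pmf
        Probability mass over piRNA lengths 24-29 nt.
    phasing_prob
        Probability that the next piRNA starts immediately at the current
        3' cut rather than after a random gap.
    body_weight
        Exponent ``alpha >= 0`` of the optional body gate
        ``exp(alpha * (G_body - U_body - 1))`` retaining G-rich/U-poor bodies.
    multimap_frac
        Fraction of retained reads fabricated as 2-locus multimappers.
    gap_p
        Geometric parameter of the non-phased gap jump (mean gap ``1/gap_p``).
    """

    cluster_base_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_BASE_FREQS))
    w_proc: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_W_PROC))
    a_sl: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_A_SL))
    length_pmf: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_PMF))
    phasing_prob: float = 0.7
    body_weight: float = 0.5
    multimap_frac: float = 0.15
    gap_p: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "cluster_base_freqs",
                           _as_base_map(self.cluster_base_freqs, "cluster_base_freqs"))
        object.__setattr__(self, "w_proc",
                           _as_base_map(self.w_proc, "w_proc", check_sum=False))
        object.__setattr__(self, "a_sl",
                           _as_base_map(self.a_sl, "a_sl", check_sum=False))
        for name in ("w_proc", "a_sl"):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals.values()):
                raise ValueError(f"{name}: values must lie in [0, 1]")
        if abs(self.w_proc["T"] - 1.0) > 1e-9:
            raise ValueError("w_proc[U] must equal 1 by convention")
        pmf = {int(k): float(v) for k, v in self.length_pmf.items()}
        if any(not MIN_LEN <= k <= MAX_LEN for k in pmf):
            raise ValueError(f"length_pmf support must lie in {MIN_LEN}-{MAX_LEN} nt")
        if abs(sum(pmf.values()) - 1.0) > 1e-9:
            raise ValueError("length_pmf must sum to 1")
        object.__setattr__(self, "length_pmf", pmf)
        if not 0.0 <= self.phasing_prob <= 1.0:
            raise ValueError("phasing_prob must lie in [0, 1]")
        if self.body_weight < 0:
            raise ValueError("body_weight must be >= 0")
        if not 0.0 <= self.multimap_frac <= 1.0:
            raise ValueError("multimap_frac must lie in [0, 1]")
        if not 0.0 < self.gap_p <= 1.0:
            raise ValueError("gap_p must lie in (0, 1]")

    @classmethod
    def default(cls) -> "GatingModel":
        """The default wild-type gating calibration."""
        return cls()

    def acceptance(self, condition: str = WT) -> dict[str, float]:
        """Per-base SL acceptance under a condition (all 1 for the mutant)."""
        if normalize_condition(condition) == SL_MUTANT:
            return {b: 1.0 for b in DNA_BASES}
        return dict(self.a_sl)


@dataclass(frozen=True, slots=True)
class TruthCluster:
    """Ground-truth piRNA cluster created by :func:`simulate_genome`."""

    contig: str
    start: int
    end: int
    strand: str
    base_freqs: Mapping[str, float]
    name: str = "."

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth accompanying a simulated library.

    ``reads`` has one row per retained primary read, aligned with the leading
    entries of the returned read list: columns contig/start/end/strand,
    ``first_nt`` (RNA label of the producing-strand first base), ``cluster``
    (index into ``clusters``), ``chain`` and ``cut_index`` (phased-chain
    bookkeeping: consecutive cut indices within a chain are head-to-tail
    neighbours).
    """

    clusters: Sequence[TruthCluster]
    reads: pd.DataFrame
    condition: str
    seed: int


def expected_first_nt_freqs(model: GatingModel, condition: str = WT) -> dict[str, float]:
    """Closed-form first-nucleotide distribution of retained piRNAs.

    ``p(n) = f(n) w(n) a(n) / sum_m f(m) w(m) a(m)`` with ``f`` the cluster
    base composition, ``w`` the processing weights and ``a`` the SL acceptance
    (all 1 for the SL-mutant condition).  Keys are RNA labels U/A/G/C.
    """
    a = model.acceptance(condition)
    num = {b: model.cluster_base_freqs[b] * model.w_proc[b] * a[b] for b in DNA_BASES}
    z = sum(num.values())
    if z <= 0:
        raise ValueError("gating model rejects every first nucleotide")
    return {dna_to_u(b): num[b] / z for b in "TAGC"}


def simulate_genome(
    n_contigs: int = 2,
    contig_len: int = 1_400_000,
    n_clusters: int = 12,
    cluster_len: int = 200_000,
    cluster_base_freqs: Mapping[str, float] | Sequence[Mapping[str, float]] | None = None,
    background_base_freqs: Mapping[str, float] | None = None,
    seed: int = 0,
    min_gap: int = 5_000,
) -> tuple[dict[str, str], list[TruthCluster]]:
    """Generate a synthetic genome with compositionally biased piRNA clusters.

    Bases are drawn i.i.d. from ``background_base_freqs`` outside clusters and
    from ``cluster_base_freqs`` inside them, on each cluster's producing
    strand (minus-strand clusters carry the reverse complement on the
    reference).  ``cluster_base_freqs`` may be a single mapping or one mapping
    per cluster, which allows varying composition across clusters.

    Clusters are distributed round-robin across contigs and separated by at
    least ``min_gap`` nt from each other and the contig ends; a layout that
    does not fit raises ``ValueError``.  Fixed ``seed`` gives a byte-identical
    genome.
    """
    if cluster_base_freqs is None:
        cluster_base_freqs = DEFAULT_CLUSTER_BASE_FREQS
    if isinstance(cluster_base_freqs, Mapping):
        per_cluster = [_as_base_map(cluster_base_freqs, "cluster_base_freqs")] * n_clusters
    else:
        per_cluster = [_as_base_map(m, f"cluster_base_freqs[{i}]")
                       for i, m in enumerate(cluster_base_freqs)]
        if len(per_cluster) != n_clusters:
            raise ValueError(
                f"got {len(per_cluster)} per-cluster base frequency maps for "
                f"{n_clusters} clusters")
    bg = _as_base_map(background_base_freqs or DEFAULT_BACKGROUND_BASE_FREQS,
                      "background_base_freqs")
    if n_contigs < 1 or contig_len < 1 or cluster_len < MIN_LEN:
        raise ValueError("invalid genome geometry")

    per_contig: list[list[int]] = [[] for _ in range(n_contigs)]
    for i in range(n_clusters):
        per_contig[i % n_contigs].append(i)
    for ids in per_contig:
        k = len(ids)
        if k * cluster_len + (k + 1) * min_gap > contig_len:
            raise ValueError(
                f"{k} clusters of {cluster_len} nt with {min_gap} nt gaps do not "
                f"fit in a {contig_len} nt contig")

    rng = np.random.default_rng(seed)
    bg_p = np.array([bg[b] for b in DNA_BASES])
    genome: dict[str, str] = {}
    clusters: list[TruthCluster] = []
    for ci, ids in enumerate(per_contig):
        contig = f"chr{ci + 1}"
        codes = rng.choice(4, size=contig_len, p=bg_p).astype(np.int8)
        k = len(ids)
        slack = contig_len - k * cluster_len - (k + 1) * min_gap
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1))) if k else []
        pos = 0
        for j, cid in enumerate(ids):
            pos += min_gap + int(extra[j])
            start, end = pos, pos + cluster_len
            freqs = per_cluster[cid]
            p = np.array([freqs[b] for b in DNA_BASES])
            strand = "+" if rng.random() < 0.5 else "-"
            produced = rng.choice(4, size=cluster_len, p=p).astype(np.int8)
            if strand == "+":
                codes[start:end] = produced
            else:
                codes[start:end] = (3 - produced)[::-1]
            clusters.append(TruthCluster(contig, start, end, strand, freqs,
                                         name=f"truth_{cid}"))
            pos = end
        genome[contig] = decode(codes)
    clusters.sort(key=lambda c: (c.contig, c.start))
    return genome, clusters


def _scan_accept(codes: list[int], pos: int, limit: int, w: list[float], rng) -> int:
    """First position >= pos whose base passes the processing gate, or -1."""
    while pos <= limit:
        if rng.random() < w[codes[pos]]:
            return pos
        pos += 1
    return -1


def simulate_library(
    genome: Mapping[str, str],
    clusters: Sequence[TruthCluster],
    model: GatingModel | None = None,
    n_reads: int = 100_000,
    condition: str = WT,
    seed: int = 0,
) -> tuple[list[AlignedRead], SyntheticTruth]:
    """Simulate a phased piRNA library from cluster loci under the gating model.

    The walk proceeds 5'->3' along each cluster's producing strand.  A chain
    starts at a uniform position and scans forward until a first nucleotide
    passes the processing gate.  The 3' end of each piRNA comes from a single
    coupled cut: a length is proposed from ``length_pmf`` and the cut is
    accepted with the processing weight of the base one piRNA-length
    downstream (that base being the candidate next 5' end); a rejected cut
    abandons the site without emitting, which keeps both the
    first-nucleotide marginal (``f*w`` before SL gating) and the length
    marginal (``length_pmf``) exact.  After an accepted cut, with probability
    ``phasing_prob`` the chain continues head-to-tail at the cut; otherwise
    it jumps a geometric gap and rescans.  Each cut piRNA is retained in the
    library with probability
    ``exp(alpha*(G_body - U_body - 1)) * a_sl[first nt]`` (``a_sl`` all 1 for
    the SL-mutant condition); the walk is independent of retention, so paired
    conditions with the same seed share their cut stream.

    Returns the library (retained primary reads first, fabricated secondary
    alignments of multimappers appended) and the aligned ground truth.
    """
    if model is None:
        model = GatingModel.default()
    cond = normalize_condition(condition)
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not clusters:
        raise ValueError("empty cluster set")

    ss = np.random.SeedSequence(seed)
    proc_ss, mm_ss = ss.spawn(2)
    rng = np.random.default_rng(proc_ss)
    mm_rng = np.random.default_rng(mm_ss)

    w = [model.w_proc[b] for b in DNA_BASES] + [0.0]  # N never accepted
    a = model.acceptance(cond)
    a_codes = [a[b] for b in DNA_BASES] + [0.0]
    alpha = model.body_weight
    lengths = sorted(model.length_pmf)
    cum_pmf = np.cumsum([model.length_pmf[l] for l in lengths]).tolist()

    # per-cluster producing-strand sequence and G/U prefix sums
    cl_seq: list[str] = []
    cl_codes: list[list[int]] = []
    cl_cum_g: list[np.ndarray] = []
    cl_cum_u: list[np.ndarray] = []
    for c in clusters:
        s = genome[c.contig][c.start:c.end]
        if c.strand == "-":
            s = revcomp(s)
        codes = encode(s)
        cl_seq.append(s)
        cl_codes.append(codes.tolist())
        cl_cum_g.append(np.concatenate([[0], np.cumsum(codes == 2)]))
        cl_cum_u.append(np.concatenate([[0], np.cumsum(codes == 3)]))
    weights = np.array([len(c) for c in clusters], dtype=float)
    cum_w = np.cumsum(weights / weights.sum()).tolist()

    reads: list[AlignedRead] = []
    rows: list[tuple] = []
    chain_id = -1
    attempts = 0
    max_attempts = 200 * n_reads + 10_000

    while len(reads) < n_reads:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "simulation failed to reach the requested read count; "
                "gating parameters may reject nearly everything")
        chain_id += 1
        ci = bisect.bisect_left(cum_w, rng.random())
        codes = cl_codes[ci]
        clen = len(codes)
        limit = clen - MIN_LEN
        pos = _scan_accept(codes, int(rng.integers(0, limit + 1)), limit, w, rng)
        if pos < 0:
            continue
        cut_index = 0
        cum_g, cum_u = cl_cum_g[ci], cl_cum_u[ci]
        c = clusters[ci]
        seq = cl_seq[ci]
        while True:
            # the downstream cut: propose one length from the pmf and accept
            # the cut with the processing weight of the base one piRNA-length
            # downstream (a rejected cut abandons this 5' site, keeping both
            # the first-nucleotide and the length marginals exact)
            d = lengths[bisect.bisect_left(cum_pmf, rng.random())]
            if pos + d > clen:
                break
            if pos + d < clen and not rng.random() < w[codes[pos + d]]:
                break
            first_code = codes[pos]
            if alpha > 0:
                g = int(cum_g[pos + d] - cum_g[pos + 1])
                u = int(cum_u[pos + d] - cum_u[pos + 1])
                p_body = math.exp(alpha * ((g - u) / (d - 1) - 1.0))
            else:
                p_body = 1.0
            u_body = rng.random()
            u_sl = rng.random()
            if u_body < p_body and u_sl < a_codes[first_code]:
                if c.strand == "+":
                    gstart = c.start + pos
                    gend = gstart + d
                else:
                    gend = c.end - pos
                    gstart = gend - d
                reads.append(AlignedRead(c.contig, gstart, gend, c.strand,
                                         seq[pos:pos + d]))
                rows.append((c.contig, gstart, gend, c.strand,
                             dna_to_u(DNA_BASES[first_code]) if first_code < 4 else "N",
                             ci, chain_id, cut_index))
                if len(reads) == n_reads:
                    break
            cut_index += 1
            nxt = pos + d
            if nxt > limit:
                break
            if rng.random() < model.phasing_prob:
                pos = nxt  # next first nt already accepted by the coupled cut
            else:
                gap = int(rng.geometric(model.gap_p))
                pos = _scan_accept(codes, nxt + gap, limit, w, rng)
                if pos < 0:
                    break

    # fabricate multimappers: duplicate a read at a second random locus
    contigs = sorted(genome)
    n_multi = int(round(model.multimap_frac * n_reads))
    secondaries: list[AlignedRead] = []
    if n_multi:
        chosen = mm_rng.choice(n_reads, size=n_multi, replace=False)
        for i in sorted(int(x) for x in chosen):
            r = reads[i]
            reads[i] = replace(r, multiplicity=2)
            contig = contigs[int(mm_rng.integers(len(contigs)))]
            span = len(genome[contig]) - len(r)
            s = int(mm_rng.integers(0, span))
            strand = "+" if mm_rng.random() < 0.5 else "-"
            secondaries.append(AlignedRead(contig, s, s + len(r), strand,
                                           r.sequence, multiplicity=2,
                                           is_primary=False))
    reads.extend(secondaries)
    logger.info("simulated %d primary reads (+%d secondary alignments), condition=%s",
                n_reads, len(secondaries), cond)

    truth = SyntheticTruth(
        clusters=list(clusters),
        reads=pd.DataFrame(rows, columns=["contig", "start", "end", "strand",
                                          "first_nt", "cluster", "chain",
                                          "cut_index"]),
        condition=cond,
        seed=seed,
    )
    return reads, truth
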