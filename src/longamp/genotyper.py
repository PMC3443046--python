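"""Bayesian diploid SNP genotyping on pileups of high-indel long reads.

Per retained base b with error probability e = 10^(-Q/10), the single-allele
likelihood is P(b | a) = 1 - e when b == a, else e/3; the diploid genotype
likelihood averages the two alleles, P(b | a1 a2) = (P(b|a1) + P(b|a2)) / 2,
and retained bases multiply (sum in log space).  Genotype priors follow the
standard diploid SNP convention (1 - 3*theta/2, theta, theta/2) with
heterozygosity theta = 1e-3.

Two adaptations target the indel-dominated error mode: bases below Q10 are
excluded, and a site is not genotyped when more than ``max_deletion_fraction``
of its spanning reads delete it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io_formats import AlignmentRecord

_QUAL_CAP = 9999.0


@dataclass
class GenotyperConfig:
    min_base_quality: int = 10
    max_deletion_fraction: float = 0.5
    heterozygosity: float = 1e-3
    call_confidence: float = 30.0
    min_depth: int = 1

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.call_confidence < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0.0 < self.max_deletion_fraction <= 1.0):
            raise ValueError("max_deletion_fraction must be in (0, 1]")
        if not (0.0 < self.heterozygosity <= 0.01):
            raise ValueError("heterozygosity must be in (0, 0.01]")

    @property
    def priors(self) -> tuple[float, float, float]:
        t = self.heterozygosity
        return (1.0 - 1.5 * t, t, 0.5 * t)


@dataclass
class PileupColumn:
    contig: str
    pos: int  # 0-based
    ref_base: str
    entries: list[tuple[str, int, bool]] = field(default_factory=list)  # (base, qual, is_reverse)
    n_deletion_reads: int = 0

    @property
    def depth(self) -> int:
        return len(self.entries)

    @property
    def deletion_fraction(self) -> float:
        total = self.n_deletion_reads + len(self.entries)
        return self.n_deletion_reads / total if total else 0.0


@dataclass
class GenotypeCall:
    contig: str
    pos: int
    ref_base: str
    alt_allele: str | None
    genotype: str  # hom_ref / het / hom_alt
    pl: tuple[int, int, int] | None
    qual: float
    depth_used: int
    filter_status: str  # PASS / DELETION_FRACTION / LOW_DEPTH
    polymorphic: bool


def _read_base_at(aln: AlignmentRecord, pos: int) -> tuple[str, int] | None | str:
    """Base/quality of the read at reference position pos.

    Returns (base, qual) for an M op, the string "DEL" when the alignment
    deletes the position, and None when the read does not span it (or it
    falls in a soft clip).
    """
    if not (aln.start <= pos < aln.end):
        return None
    i, j = 0, aln.start
    for op, n in aln.cigar:
        if op == "M":
            if j <= pos < j + n:
                k = i + (pos - j)
                q = aln.qualities[k] if aln.qualities is not None else 20
                return aln.bases[k], q
            i += n
            j += n
        elif op in "IS":
            i += n
        elif op == "D":
            if j <= pos < j + n:
                return "DEL"
            j += n
    return None


def build_pileup(alignments: list[AlignmentRecord], ref: str, pos: int, contig: str | None = None) -> PileupColumn:
    """Pileup at one reference position; insertions contribute no entries."""
    if pos < 0 or pos >= len(ref):
        raise ValueError(f"position {pos} outside contig of length {len(ref)}")
    col = PileupColumn(contig=contig or "", pos=pos, ref_base=ref[pos])
    for aln in alignments:
        if contig is not None and aln.contig != contig:
            continue
        hit = _read_base_at(aln, pos)
        if hit is None:
            continue
        if hit == "DEL":
            col.n_deletion_reads += 1
        else:
            base, q = hit
            col.entries.append((base, q, aln.is_reverse))
    return col


def pileup_columns(alignments: list[AlignmentRecord], ref: str, contig: str) -> list[PileupColumn]:
    """All pileup columns of a contig in one pass over the alignments."""
    cols = [PileupColumn(contig=contig, pos=p, ref_base=ref[p]) for p in range(len(ref))]
    for aln in alignments:
        if aln.contig != contig:
            continue
        i, j = 0, aln.start
        for op, n in aln.cigar:
            if op == "M":
                for k in range(n):
                    q = aln.qualities[i] if aln.qualities is not None else 20
                    cols[j].entries.append((aln.bases[i], q, aln.is_reverse))
                    i += 1
                    j += 1
            elif op in "IS":
                i += n
            elif op == "D":
                for k in range(n):
                    cols[j].n_deletion_reads += 1
                    j += 1
    return cols


def genotype_likelihoods(
    column: PileupColumn, alt: str, config: GenotyperConfig = GenotyperConfig()
) -> tuple[tuple[float, float, float] | None, int]:
    """Natural-log likelihoods (hom_ref, het, hom_alt) and depth used.

    Bases below the quality threshold, and bases other than ref/alt, are
    dropped; with zero retained bases the triple is None (LOW_DEPTH).
    """
    ref = column.ref_base
    ll = [0.0, 0.0, 0.0]
    depth = 0
    for base, q, _ in column.entries:
        if q < config.min_base_quality or base not in (ref, alt):
            continue
        depth += 1
        # cap at 3/4 so a quality-0 base is uninformative rather than impossible
        e = min(10.0 ** (-q / 10.0), 0.75)
        p_ref = (1.0 - e) if base == ref else e / 3.0
        p_alt = (1.0 - e) if base == alt else e / 3.0
        ll[0] += math.log(p_ref)
        ll[1] += math.log(0.5 * p_ref + 0.5 * p_alt)
        ll[2] += math.log(p_alt)
    if depth == 0:
        return None, 0
    return (ll[0], ll[1], ll[2]), depth


def call_site(
    column: PileupColumn,
    alt: str,
    config: GenotyperConfig = GenotyperConfig(),
) -> GenotypeCall:
    """Posterior diploid genotype at one site for a fixed alternate allele."""
    if column.deletion_fraction > config.max_deletion_fraction:
        return GenotypeCall(
            contig=column.contig,
            pos=column.pos,
            ref_base=column.ref_base,
            alt_allele=alt,
            genotype="hom_ref",
            pl=None,
            qual=0.0,
            depth_used=0,
            filter_status="DELETION_FRACTION",
            polymorphic=False,
        )
    triple, depth = genotype_likelihoods(column, alt, config)
    if triple is None or depth < config.min_depth:
        return GenotypeCall(
            contig=column.contig,
            pos=column.pos,
            ref_base=column.ref_base,
            alt_allele=alt,
            genotype="hom_ref",
            pl=None,
            qual=0.0,
            depth_used=depth,
            filter_status="LOW_DEPTH",
            polymorphic=False,
        )
    log_prior = np.log(np.asarray(config.priors))
    log_post = np.asarray(triple) + log_prior
    log_post -= logsumexp(log_post)
    genotype = ("hom_ref", "het", "hom_alt")[int(np.argmax(log_post))]
    qual = min(_QUAL_CAP, -10.0 * log_post[0] / math.log(10.0))
    pl_raw = -10.0 * np.asarray(triple) / math.log(10.0)
    pl_raw -= pl_raw.min()
    pl = tuple(int(round(v)) for v in pl_raw)
    return GenotypeCall(
        contig=column.contig,
        pos=column.pos,
        ref_base=column.ref_base,
        alt_allele=alt,
        genotype=genotype,
        pl=pl,
        qual=float(qual),
        depth_used=depth,
        filter_status="PASS",
        polymorphic=bool(qual >= config.call_confidence),
    )


def call_region(
    alignments: list[AlignmentRecord],
    ref: str,
    contig: str,
    config: GenotyperConfig = GenotyperConfig(),
) -> list[GenotypeCall]:
    """Discovery mode: test the most frequent non-reference base at every position.

    Returns the polymorphic calls (QUAL >= call confidence).
    """
    calls: list[GenotypeCall] = []
    for col in pileup_columns(alignments, ref, contig):
        counts: dict[str, int] = {}
        for base, q, _ in col.entries:
            if q >= config.min_base_quality and base != col.ref_base and base in "ACGT":
                counts[base] = counts.get(base, 0) + 1
        if not counts:
            continue
        alt = max(sorted(counts), key=lambda b: counts[b])
        call = call_site(col, alt, config)
        if call.polymorphic and call.genotype != "hom_ref":
            calls.append(call)
    return calls
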