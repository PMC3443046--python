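"""Synthetic diploid amplicon panels and long reads under an indel-dominated error model.

The generator's defaults are the study conditions the toolkit is built for:
per-base insertion/deletion/mismatch rates of 12%/2%/1% distributed uniformly
along the read, a wide log-normal read-length law with mean 700 bases and a
5% tail beyond 2,500 bases, ~70x mean coverage, and a truth panel of 38
heterozygous true de novo SNPs plus 60 artifact sites that are present in the
truth VCF but absent from the DNA.

Every simulated read carries a :class:`TrueAlignment` (the exact per-base
event walk against its source haplotype), which serves as the oracle for the
aligner, profiler, genotyper and reference-bias stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .io_formats import (
    AlignmentRecord,
    SequenceRecord,
    TruthStatus,
    VariantRecord,
    Zygosity,
    reverse_complement,
)

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SimConfig:
    """Study conditions for read simulation.

    Probabilities are per-base event rates of the generative walk; lengths in
    bases; ``depth`` is mean per-amplicon fold coverage.
    """

    p_ins: float = 0.12
    p_del: float = 0.02
    p_mis: float = 0.01
    mean_len: float = 700.0
    frac_gt_2500: float = 0.05
    depth: float = 70.0
    seed: int = 0
    n_true_sites: int = 38
    n_artifact_sites: int = 60
    min_len: int = 50
    length_threshold: float = 2500.0

    def __post_init__(self) -> None:
        for name in ("p_ins", "p_del", "p_mis"):
            p = getattr(self, name)
            if not (0.0 <= p < 1.0):
                raise ValueError(f"{name}={p} outside [0, 1)")
        if self.p_ins + self.p_del + self.p_mis >= 1.0:
            raise ValueError("p_ins + p_del + p_mis must be < 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.mean_len <= 0:
            raise ValueError("mean_len must be positive")


@dataclass
class AmpliconPanel:
    amplicons: list[SequenceRecord]
    gc_profile: list[float] | None = None

    def __post_init__(self) -> None:
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValueError("amplicon names must be unique")
        for a in self.amplicons:
            if len(a) < 500:
                raise ValueError(f"amplicon {a.name} shorter than 500 bases")

    def get(self, name: str) -> SequenceRecord:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def contigs(self) -> dict[str, int]:
        return {a.name: len(a) for a in self.amplicons}


@dataclass
class DiploidSample:
    """Truth variants plus the two haplotype sequences of each amplicon.

    HET variants sit on exactly one haplotype; ARTIFACT-status sites on
    neither (they exist only in the truth VCF, not in the DNA).
    """

    variants: list[VariantRecord]
    haplotypes: dict[str, tuple[str, str]]


@dataclass
class TrueAlignment:
    """Exact generative alignment of one simulated read.

    ``events`` is the per-emitted-base walk in sequencing orientation over
    {M, X, I, D}: M match, X mismatch, I inserted base, D deleted template
    base (consumes template, emits nothing).  ``start``/``end`` are 0-based
    half-open on the amplicon (haplotypes are SNP-only, so haplotype and
    amplicon coordinates coincide).
    """

    read_id: str
    amplicon: str
    haplotype: int
    start: int
    end: int
    is_reverse: bool
    events: str

    def cigar(self) -> list[tuple[str, int]]:
        """Collapse the event walk (in reference orientation) to a CIGAR."""
        ev = self.events[::-1] if self.is_reverse else self.events
        cigar: list[tuple[str, int]] = []
        for e in ev:
            op = "M" if e in "MX" else e
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + 1)
            else:
                cigar.append((op, 1))
        return cigar


def lognormal_params(mean_len: float, frac_gt: float, threshold: float = 2500.0) -> tuple[float, float]:
    """Solve log-normal (mu, sigma) from E[L] = mean_len and P(L > threshold) = frac_gt.

    Substituting mu = ln(mean) - sigma^2/2 into (ln t - mu)/sigma = z with
    z = Phi^-1(1 - frac_gt) gives sigma^2/2 - z sigma + ln(t/mean) = 0; the
    smaller positive root is taken.
    """
    if not (0.0 < frac_gt < 0.5):
        raise ValueError(f"tail fraction {frac_gt} infeasible for a log-normal (need 0 < f < 0.5)")
    if mean_len >= threshold:
        raise ValueError("mean_len must be below the tail threshold")
    z = norm.ppf(1.0 - frac_gt)
    disc = z * z - 2.0 * np.log(threshold / mean_len)
    if disc < 0:
        raise ValueError(
            f"no log-normal satisfies mean={mean_len} with P(L>{threshold})={frac_gt}"
        )
    sigma = z - np.sqrt(disc)
    mu = np.log(mean_len) - sigma * sigma / 2.0
    return float(mu), float(sigma)


def sample_read_length(config: SimConfig, rng: np.random.Generator, sigma: float | None = None) -> int:
    """Draw one read length; ``sigma=0`` degenerates to ``mean_len`` exactly."""
    if sigma == 0.0:
        return max(config.min_len, int(round(config.mean_len)))
    if sigma is None:
        mu, sigma = lognormal_params(config.mean_len, config.frac_gt_2500, config.length_threshold)
    else:
        mu = np.log(config.mean_len) - sigma * sigma / 2.0
    length = int(round(float(rng.lognormal(mu, sigma))))
    return max(config.min_len, length)


def _random_sequence(rng: np.random.Generator, length: int, gc: float | None = None) -> str:
    if gc is None:
        probs = None
    else:
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    idx = rng.choice(4, size=length, p=probs)
    return "".join(BASES[i] for i in idx)


def _spaced_positions(
    rng: np.random.Generator, lo: int, hi: int, k: int, min_sep: int
) -> list[int]:
    """k positions in [lo, hi) pairwise separated by >= min_sep, uniformly."""
    span = hi - lo - (k - 1) * min_sep
    if k > 0 and span < k:
        raise ValueError(f"cannot place {k} sites with separation {min_sep} in [{lo}, {hi})")
    if k == 0:
        return []
    raw = np.sort(rng.choice(span, size=k, replace=False))
    return [int(lo + r + i * min_sep) for i, r in enumerate(raw)]


def make_panel(
    config: SimConfig,
    n_amplicons: int = 4,
    amplicon_len: int = 2000,
    gc_profile: Sequence[float] | None = None,
    edge_margin: int = 200,
    min_separation: int = 10,
) -> tuple[AmpliconPanel, DiploidSample, list[VariantRecord]]:
    """Build a random amplicon panel with planted truth-status SNP sites.

    TRUE_DE_NOVO sites are planted as HET on one haplotype; ARTIFACT sites
    are recorded in the truth set only.  Returns (panel, sample, variants);
    the variant list (sorted by contig, pos) is the truth VCF content.
    """
    rng = np.random.default_rng([config.seed, 101])
    if gc_profile is not None and len(gc_profile) != n_amplicons:
        raise ValueError("gc_profile length must equal n_amplicons")

    n_sites = config.n_true_sites + config.n_artifact_sites
    per_amp_capacity = (amplicon_len - 2 * edge_margin) // min_separation
    if per_amp_capacity * n_amplicons < n_sites or amplicon_len <= 2 * edge_margin:
        raise ValueError(
            f"{n_amplicons} amplicons of {amplicon_len} bp cannot host {n_sites} sites"
        )

    width = max(2, len(str(n_amplicons)))
    amplicons = [
        SequenceRecord(
            name=f"amp{i + 1:0{width}d}",
            bases=_random_sequence(rng, amplicon_len, None if gc_profile is None else gc_profile[i]),
        )
        for i in range(n_amplicons)
    ]

    # Spread sites as evenly as possible across amplicons.
    counts = [n_sites // n_amplicons] * n_amplicons
    for i in range(n_sites % n_amplicons):
        counts[i] += 1

    statuses = [TruthStatus.TRUE_DE_NOVO] * config.n_true_sites + [
        TruthStatus.ARTIFACT
    ] * config.n_artifact_sites
    rng.shuffle(statuses)

    variants: list[VariantRecord] = []
    haplotypes: dict[str, tuple[str, str]] = {}
    cursor = 0
    for amp, k in zip(amplicons, counts):
        positions = _spaced_positions(rng, edge_margin, amplicon_len - edge_margin, k, min_separation)
        hap = [list(amp.bases), list(amp.bases)]
        for pos in positions:
            status = statuses[cursor]
            cursor += 1
            ref = amp.bases[pos]
            alt = BASES[(_BASE_IDX[ref] + 1 + rng.integers(3)) % 4]
            zyg = Zygosity.HET if status is TruthStatus.TRUE_DE_NOVO else None
            variants.append(
                VariantRecord(
                    contig=amp.name,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    truth_status=status,
                    zygosity=zyg,
                )
            )
            if status is TruthStatus.TRUE_DE_NOVO:
                hap[int(rng.integers(2))][pos] = alt
        haplotypes[amp.name] = ("".join(hap[0]), "".join(hap[1]))

    panel = AmpliconPanel(
        amplicons=amplicons,
        gc_profile=list(gc_profile) if gc_profile is not None else None,
    )
    sample = DiploidSample(variants=variants, haplotypes=haplotypes)
    return panel, sample, list(variants)


def _walk_template(
    template: str,
    target_len: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """Emit up to ``target_len`` read bases from ``template``.

    Per template base: with prob p_del skip it (D); else emit it (mismatched
    to a uniform different base with prob p_mis: X, else M), then append
    uniformly random inserted bases in a geometric run with continuation
    prob p_ins (I).  Returns (read, events, template_consumed); leading and
    trailing D events are trimmed (they are unanchored) and do not count as
    consumed template.
    """
    m = len(template)
    # Pre-draw in blocks for speed; the walk itself is sequential.
    del_draw = rng.random(m) < config.p_del
    mis_draw = rng.random(m) < config.p_mis
    mis_base = rng.integers(0, 3, size=m)
    # Geometric run length with continuation prob p_ins (0 allowed).
    if config.p_ins > 0:
        ins_runs = rng.geometric(1.0 - config.p_ins, size=m) - 1
    else:
        ins_runs = np.zeros(m, dtype=np.int64)
    max_ins = int(ins_runs.sum())
    ins_base = rng.integers(0, 4, size=max_ins) if max_ins else np.empty(0, dtype=np.int64)

    read: list[str] = []
    events: list[str] = []
    consumed = 0
    ins_cursor = 0
    for t in range(m):
        if len(read) >= target_len:
            break
        consumed += 1
        if del_draw[t]:
            events.append("D")
            continue
        base = template[t]
        if mis_draw[t]:
            base = BASES[(_BASE_IDX.get(base, 0) + 1 + mis_base[t]) % 4]
            events.append("X")
        else:
            events.append("M")
        read.append(base)
        for _ in range(int(ins_runs[t])):
            if len(read) >= target_len:
                break
            read.append(BASES[ins_base[ins_cursor]])
            ins_cursor += 1
            events.append("I")
    # Trim unanchored terminal deletions; the caller shifts the reference
    # start past the leading ones.
    ev = "".join(events)
    lead = len(ev) - len(ev.lstrip("D"))
    trail = len(ev) - len(ev.rstrip("D"))
    consumed -= lead + trail
    ev = ev.strip("D")
    return "".join(read), ev, consumed, lead


def simulate_reads(
    panel: AmpliconPanel,
    sample: DiploidSample,
    config: SimConfig,
    flat_quality: int = 20,
) -> tuple[list[SequenceRecord], list[TrueAlignment]]:
    """Simulate reads from the diploid sample under the configured error model.

    Per read: haplotype and strand uniform.  Fragment starts are uniform over
    an interval extended by the read length beyond both amplicon ends, with
    the fragment truncated to the amplicon — the sheared-molecule model,
    which tiles coverage uniformly across the whole amplicon instead of
    peaking mid-amplicon.  Reads are drawn until the accumulated reference
    span reaches depth * amplicon_len, so mean fold coverage equals ``depth``
    exactly regardless of truncation and of the indel balance.  Reported base
    qualities are all the flat value ``flat_quality`` (the recalibrator's
    starting prior).
    """
    if not panel.amplicons:
        raise ValueError("empty amplicon panel")
    rng = np.random.default_rng([config.seed, 202])
    mu, sigma = lognormal_params(config.mean_len, config.frac_gt_2500, config.length_threshold)

    reads: list[SequenceRecord] = []
    truths: list[TrueAlignment] = []
    for amp in panel.amplicons:
        haps = sample.haplotypes.get(amp.name, (amp.bases, amp.bases))
        target_ref_bases = config.depth * len(amp)
        total_ref = 0
        i = 0
        while total_ref < target_ref_bases:
            i += 1
            length = max(config.min_len, int(round(float(rng.lognormal(mu, sigma)))))
            length = min(length, len(amp))
            hap_idx = int(rng.integers(2))
            is_reverse = bool(rng.integers(2))
            hap = haps[hap_idx]
            lo = config.min_len - length  # overhanging starts: truncated fragments
            hi = len(hap) - config.min_len
            s = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
            frag_lo, frag_hi = max(0, s), min(len(hap), s + length)
            if is_reverse:
                template = reverse_complement(hap[frag_lo:frag_hi])
            else:
                template = hap[frag_lo:frag_hi]
            bases, events, consumed, lead = _walk_template(template, length, config, rng)
            total_ref += max(consumed, 1)
            if not bases:
                continue
            if is_reverse:
                ref_end = frag_hi - lead
                ref_start = ref_end - consumed
            else:
                ref_start = frag_lo + lead
                ref_end = ref_start + consumed
            read_id = f"{amp.name}_r{i:06d}"
            reads.append(
                SequenceRecord(
                    name=read_id,
                    bases=bases,
                    qualities=[flat_quality] * len(bases),
                )
            )
            truths.append(
                TrueAlignment(
                    read_id=read_id,
                    amplicon=amp.name,
                    haplotype=hap_idx,
                    start=ref_start,
                    end=ref_end,
                    is_reverse=is_reverse,
                    events=events,
                )
            )
    return reads, truths


def reconstruct_read(truth: TrueAlignment, sample: DiploidSample, read: SequenceRecord) -> str:
    """Re-derive the read's base string implied by the truth event walk.

    Event bases for X and I are not stored, so those positions are taken from
    the read itself; M and D positions are taken from the haplotype.  Equality
    with the read therefore checks the event/coordinate bookkeeping exactly
    (counts, order and haplotype agreement at M positions).
    """
    hap = sample.haplotypes[truth.amplicon][truth.haplotype]
    segment = hap[truth.start : truth.end]
    template = reverse_complement(segment) if truth.is_reverse else segment
    out = []
    t = 0
    r = 0
    for e in truth.events:
        if e == "D":
            t += 1
        elif e == "M":
            out.append(template[t])
            t += 1
            r += 1
        elif e == "X":
            if read.bases[r] == template[t]:
                raise ValueError(f"{truth.read_id}: X event but read matches template")
            out.append(read.bases[r])
            t += 1
            r += 1
        elif e == "I":
            out.append(read.bases[r])
            r += 1
        else:
            raise ValueError(f"unknown event {e!r}")
    if t != len(template):
        raise ValueError(f"{truth.read_id}: events consume {t} of {len(template)} template bases")
    return "".join(out)


def event_fractions(truths: Sequence[TrueAlignment]) -> dict[str, float]:
    """Event-mode fractions relative to emitted read bases (M+X+I)."""
    counts = {"M": 0, "X": 0, "I": 0, "D": 0}
    for t in truths:
        for e in t.events:
            counts[e] += 1
    n_read_bases = counts["M"] + counts["X"] + counts["I"]
    if n_read_bases == 0:
        raise ValueError("no emitted bases")
    return {
        "mismatch": counts["X"] / n_read_bases,
        "insertion": counts["I"] / n_read_bases,
        "deletion": counts["D"] / n_read_bases,
    }


def truth_to_alignment(
    truth: TrueAlignment, read: SequenceRecord, flat_quality: int | None = None
) -> AlignmentRecord:
    """Convert a truth walk into an AlignmentRecord against the amplicon reference.

    Bases/qualities are flipped into reference orientation for reverse-strand
    reads.  M covers both matches and mismatches (including planted het
    alleles, which differ from the reference but not the haplotype).
    """
    bases = reverse_complement(read.bases) if truth.is_reverse else read.bases
    quals = read.qualities
    if quals is not None and truth.is_reverse:
        quals = quals[::-1]
    nm = sum(1 for e in truth.events if e in "XID")
    return AlignmentRecord(
        read_id=truth.read_id,
        contig=truth.amplicon,
        start=truth.start,
        is_reverse=truth.is_reverse,
        cigar=truth.cigar(),
        bases=bases,
        qualities=quals,
        nm=nm,
        tags={"XE": truth.events},
    )
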