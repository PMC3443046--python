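"""Readers/writers for FASTA, FASTQ, SAM and VCF with fixed coordinate conventions.

All in-memory coordinates are 0-based half-open; 1-based coordinates appear
only inside the SAM/VCF serializations themselves.  The VCF dialect is
SNP-only (single-base ref/alt) and carries the validation truth status of
each site in ``INFO/STATUS``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")
MAX_QUALITY = 60

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed or out-of-contract sequence/variant files."""


class TruthStatus(str, enum.Enum):
    TRUE_DE_NOVO = "TRUE_DE_NOVO"
    ARTIFACT = "ARTIFACT"
    UNKNOWN = "UNKNOWN"


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM_ALT = "HOM_ALT"


@dataclass
class SequenceRecord:
    """A named sequence over {A,C,G,T,N} with optional PHRED qualities (0-60)."""

    name: str
    bases: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence record needs a non-empty name")
        if not self.bases:
            raise FormatError(f"record {self.name!r}: empty sequence")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise FormatError(f"record {self.name!r}: invalid characters {sorted(bad)}")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise FormatError(
                f"record {self.name!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class VariantRecord:
    """A single-base substitution with optional truth status and zygosity.

    ``pos`` is 0-based (internal convention); serialization to VCF adds 1.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    truth_status: TruthStatus = TruthStatus.UNKNOWN
    zygosity: Zygosity | None = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise FormatError("SNP-only scope: alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"{self.contig}:{self.pos}: ref and alt alleles are equal")
        if self.pos < 0:
            raise FormatError(f"negative position {self.pos}")


@dataclass
class AlignmentRecord:
    """A read aligned to a reference contig.

    ``bases``/``qualities`` are stored in reference orientation (i.e. already
    reverse-complemented for reverse-strand alignments, matching SAM SEQ).
    CIGAR ops are limited to M/I/D/S; read-consuming op lengths (M/I/S) must
    sum to the read length.
    """

    read_id: str
    contig: str
    start: int  # 0-based reference offset
    is_reverse: bool
    cigar: list[tuple[str, int]]
    bases: str
    qualities: list[int] | None = None
    score: int = 0
    nm: int = 0
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in "MIS")
        if consumed != len(self.bases):
            raise FormatError(
                f"{self.read_id}: CIGAR consumes {consumed} read bases, "
                f"read has {len(self.bases)}"
            )
        bad_ops = {op for op, _ in self.cigar} - set("MIDS")
        if bad_ops:
            raise FormatError(f"{self.read_id}: unsupported CIGAR ops {sorted(bad_ops)}")

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + self.reference_length

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _validate_fasta_text(path: Path) -> None:
    # Pre-scan purely to produce line-numbered errors; parsing itself is SeqIO's.
    seen_header = False
    header_line = 0
    has_bases = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if seen_header and not has_bases:
                    raise FormatError(f"{path}: empty sequence for header at line {header_line}")
                if stripped == ">":
                    raise FormatError(f"{path}: malformed (empty) header at line {lineno}")
                seen_header = True
                header_line = lineno
                has_bases = False
            else:
                if not seen_header:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                has_bases = True
    if not seen_header:
        raise FormatError(f"{path}: no FASTA records found (line 1)")
    if not has_bases:
        raise FormatError(f"{path}: empty sequence for header at line {header_line}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; bases are uppercased."""
    path = Path(path)
    _validate_fasta_text(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(name=rec.id, bases=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (PHRED+33)
# ---------------------------------------------------------------------------

def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio_records = []
    for rec in records:
        if rec.qualities is None:
            raise FormatError(f"record {rec.name!r}: FASTQ output requires qualities")
        if any(q < 0 or q > MAX_QUALITY for q in rec.qualities):
            raise FormatError(f"record {rec.name!r}: qualities outside [0, {MAX_QUALITY}]")
        bio = _BioSeqRecord(Seq(rec.bases), id=rec.name, description="")
        bio.letter_annotations["phred_quality"] = list(rec.qualities)
        bio_records.append(bio)
    SeqIO.write(bio_records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            SequenceRecord(
                name=rec.id,
                bases=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def fastq_roundtrip(records: Sequence[SequenceRecord], path: str | Path) -> list[SequenceRecord]:
    """Write records as FASTQ and read them back (lossless for name/bases/quals)."""
    write_fastq(records, path)
    return read_fastq(path)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CIGAR_OP = {v: k for k, v in _CIGAR_CODE.items()}


def write_sam(
    alignments: Iterable[AlignmentRecord],
    references: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Write a minimal valid SAM file (1-based POS produced by pysam)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.name, "LN": len(r.bases)} for r in references],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.bases
            seg.flag = 16 if aln.is_reverse else 0
            seg.reference_id = out.header.get_tid(aln.contig)
            if seg.reference_id < 0:
                raise FormatError(f"{aln.read_id}: unknown contig {aln.contig!r}")
            seg.reference_start = aln.start
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_CODE[op], n) for op, n in aln.cigar]
            if aln.qualities is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in aln.qualities)
                )
            seg.set_tag("NM", int(aln.nm))
            seg.set_tag("AS", int(aln.score))
            for tag, value in aln.tags.items():
                seg.set_tag(tag, value)
            out.write(seg)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            quals = list(seg.query_qualities) if seg.query_qualities is not None else None
            tags = {
                tag: value
                for tag, value in seg.get_tags()
                if tag not in ("NM", "AS")
            }
            alignments.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    start=seg.reference_start,
                    is_reverse=seg.is_reverse,
                    cigar=[(_CIGAR_OP[code], n) for code, n in seg.cigartuples],
                    bases=seg.query_sequence,
                    qualities=quals,
                    score=seg.get_tag("AS") if seg.has_tag("AS") else 0,
                    nm=seg.get_tag("NM") if seg.has_tag("NM") else 0,
                    tags=tags,
                )
            )
    return alignments


# ---------------------------------------------------------------------------
# VCF (SNP-only dialect, INFO/STATUS truth annotation)
# ---------------------------------------------------------------------------

def write_vcf(
    variants: Sequence[VariantRecord],
    contigs: dict[str, int],
    path: str | Path,
) -> None:
    """Write a SNP-only VCF.  ``contigs`` maps contig name to length.

    Variants must be sorted by (contig, pos); truth status goes to
    INFO/STATUS and zygosity (when present) to the single sample's GT.
    """
    order = {name: i for i, name in enumerate(contigs)}
    keys = []
    for v in variants:
        if v.contig not in order:
            raise FormatError(f"variant on unknown contig {v.contig!r}")
        if v.pos >= contigs[v.contig]:
            raise FormatError(f"{v.contig}:{v.pos} outside contig of length {contigs[v.contig]}")
        keys.append((order[v.contig], v.pos))
    if keys != sorted(keys):
        raise FormatError("variants must be sorted by (contig, pos)")

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=STATUS,Number=1,Type=String,Description="Validation truth status">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_sample("SAMPLE")

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig,
                start=v.pos,
                stop=v.pos + 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["STATUS"] = v.truth_status.value
            if v.zygosity is Zygosity.HET:
                rec.samples["SAMPLE"]["GT"] = (0, 1)
            elif v.zygosity is Zygosity.HOM_ALT:
                rec.samples["SAMPLE"]["GT"] = (1, 1)
            else:
                rec.samples["SAMPLE"]["GT"] = (None, None)
            out.write(rec)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    variants = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            if len(rec.alts or ()) != 1:
                raise FormatError(f"{rec.contig}:{rec.pos}: expected exactly one alt allele")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise FormatError(f"{rec.contig}:{rec.pos}: multi-base alleles rejected (SNP-only)")
            status = TruthStatus(rec.info.get("STATUS", "UNKNOWN"))
            zyg = None
            if "SAMPLE" in rec.samples:
                gt = rec.samples["SAMPLE"].get("GT")
                if gt == (0, 1) or gt == (1, 0):
                    zyg = Zygosity.HET
                elif gt == (1, 1):
                    zyg = Zygosity.HOM_ALT
            variants.append(
                VariantRecord(
                    contig=rec.contig,
                    pos=rec.start,  # pysam .start is 0-based
                    ref_allele=ref,
                    alt_allele=alt,
                    truth_status=status,
                    zygosity=zyg,
                )
            )
    return variants
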