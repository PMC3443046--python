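"""Covariate-based empirical base-quality recalibration.

Starting from a flat reported quality (Q20 for simulated long reads), the
observed mismatch rate against the reference is tabulated hierarchically per
read group, then per reported quality, then per cycle (1-based read position
in sequencing orientation) and per dinucleotide (previous base, current base)
within reported quality.  The empirical quality of a bin with n observations
and m mismatches is the additively smoothed

    Q = -10 * log10((m + 1) / (n + 2)),   capped at 60.

Recalibrated base qualities compose the read-group quality with per-level
deltas (each level's empirical quality minus its parent's), applying a delta
only when the level has at least ``min_obs`` observations.  Only M-op bases
outside known variant sites contribute; insertions and deletions are excluded
from the error signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AlignmentRecord, SequenceRecord

MAX_EMPIRICAL_Q = 60.0
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def empirical_quality(n: int, m: int) -> float:
    """Smoothed PHRED-scaled empirical quality of n observations, m mismatches."""
    if n < 0 or m < 0 or m > n:
        raise ValueError(f"invalid counts n={n}, m={m}")
    q = -10.0 * math.log10((m + 1) / (n + 2))
    return min(q, MAX_EMPIRICAL_Q)


@dataclass
class RecalibrationTable:
    """Hierarchical (observations, mismatches) counts keyed by covariates."""

    read_group: dict[str, list[int]] = field(default_factory=dict)
    quality: dict[tuple[str, int], list[int]] = field(default_factory=dict)
    cycle: dict[tuple[str, int, int], list[int]] = field(default_factory=dict)
    dinucleotide: dict[tuple[str, int, str], list[int]] = field(default_factory=dict)

    def add(self, rg: str, q: int, cycle: int, dinuc: str, mismatch: bool) -> None:
        e = 1 if mismatch else 0
        for table, key in (
            (self.read_group, rg),
            (self.quality, (rg, q)),
            (self.cycle, (rg, q, cycle)),
            (self.dinucleotide, (rg, q, dinuc)),
        ):
            cell = table.setdefault(key, [0, 0])
            cell[0] += 1
            cell[1] += e

    def empirical(self, level: str, key) -> float:
        n, m = getattr(self, level)[key]
        return empirical_quality(n, m)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rg, (n, m) in sorted(self.read_group.items()):
            rows.append(("read_group", rg, "", "", "", n, m, empirical_quality(n, m)))
        for (rg, q), (n, m) in sorted(self.quality.items()):
            rows.append(("quality", rg, q, "", "", n, m, empirical_quality(n, m)))
        for (rg, q, c), (n, m) in sorted(self.cycle.items()):
            rows.append(("cycle", rg, q, c, "", n, m, empirical_quality(n, m)))
        for (rg, q, d), (n, m) in sorted(self.dinucleotide.items()):
            rows.append(("dinucleotide", rg, q, "", d, n, m, empirical_quality(n, m)))
        return pd.DataFrame(
            rows,
            columns=["level", "read_group", "reported_q", "cycle", "dinuc", "n", "m", "q_emp"],
        )


def _seq_orientation_base(aln: AlignmentRecord, i: int) -> str:
    """Base at stored (reference-orientation) index i, as sequenced."""
    b = aln.bases[i]
    return _COMP[b] if aln.is_reverse else b


def _covariates(aln: AlignmentRecord, i: int) -> tuple[int, int, str]:
    """(reported_q, 1-based cycle, dinucleotide) for stored index i."""
    read_len = len(aln.bases)
    s = read_len - 1 - i if aln.is_reverse else i  # 0-based sequencing position
    q = aln.qualities[i] if aln.qualities is not None else 20
    cur = _seq_orientation_base(aln, i)
    if s == 0:
        prev = "N"
    elif aln.is_reverse:
        prev = _seq_orientation_base(aln, i + 1)
    else:
        prev = _seq_orientation_base(aln, i - 1)
    return q, s + 1, prev + cur


def build_table(
    alignments: list[AlignmentRecord],
    refs: dict[str, str],
    known_sites: dict[str, set[int]] | None = None,
    read_group: str = "RG1",
) -> RecalibrationTable:
    """Accumulate covariate counts over every M-op base outside known sites."""
    known = known_sites or {}
    table = RecalibrationTable()
    for aln in alignments:
        ref = refs[aln.contig]
        sites = known.get(aln.contig, set())
        i, j = 0, aln.start
        for op, n in aln.cigar:
            if op == "M":
                for _ in range(n):
                    if j not in sites:
                        q, cyc, dinuc = _covariates(aln, i)
                        table.add(read_group, q, cyc, dinuc, aln.bases[i] != ref[j])
                    i += 1
                    j += 1
            elif op in "IS":
                i += n
            elif op == "D":
                j += n
    return table


def _compose_quality(
    table: RecalibrationTable,
    rg: str,
    q: int,
    cyc: int,
    dinuc: str,
    min_obs: int,
) -> int:
    if rg not in table.read_group:
        return q  # no data: keep reported quality
    q_rg = table.empirical("read_group", rg)
    result = q_rg
    parent = q_rg
    cell = table.quality.get((rg, q))
    if cell and cell[0] >= min_obs:
        q_lvl = empirical_quality(*cell)
        result += q_lvl - parent
        parent = q_lvl
    c_cell = table.cycle.get((rg, q, cyc))
    if c_cell and c_cell[0] >= min_obs:
        result += empirical_quality(*c_cell) - parent
    d_cell = table.dinucleotide.get((rg, q, dinuc))
    if d_cell and d_cell[0] >= min_obs:
        result += empirical_quality(*d_cell) - parent
    return int(min(60, max(2, round(result))))


def recalibrate_read(
    read: SequenceRecord,
    table: RecalibrationTable,
    read_group: str = "RG1",
    min_obs: int = 100,
) -> SequenceRecord:
    """Return a copy of the read with recalibrated qualities (clamped to [2, 60])."""
    if read.qualities is None:
        raise ValueError(f"read {read.name}: recalibration requires reported qualities")
    new_quals = []
    for s, base in enumerate(read.bases):
        prev = read.bases[s - 1] if s > 0 else "N"
        new_quals.append(
            _compose_quality(table, read_group, read.qualities[s], s + 1, prev + base, min_obs)
        )
    return SequenceRecord(name=read.name, bases=read.bases, qualities=new_quals)


def recalibrate_alignment(
    aln: AlignmentRecord,
    table: RecalibrationTable,
    read_group: str = "RG1",
    min_obs: int = 100,
) -> AlignmentRecord:
    """Recalibrate an aligned read's qualities in place-compatible copy."""
    if aln.qualities is None:
        raise ValueError(f"{aln.read_id}: recalibration requires qualities")
    new_quals = list(aln.qualities)
    for i in range(len(aln.bases)):
        q, cyc, dinuc = _covariates(aln, i)
        new_quals[i] = _compose_quality(table, read_group, q, cyc, dinuc, min_obs)
    return AlignmentRecord(
        read_id=aln.read_id,
        contig=aln.contig,
        start=aln.start,
        is_reverse=aln.is_reverse,
        cigar=list(aln.cigar),
        bases=aln.bases,
        qualities=new_quals,
        score=aln.score,
        nm=aln.nm,
        tags=dict(aln.tags),
    )
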