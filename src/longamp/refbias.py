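"""Reference-bias diagnostics for indel-tolerant alignment.

When the gap-open penalty sits below the mismatch penalty, the aligner can
represent a true alternate allele at equal or better score as part of an
insertion, leaving the reference base in the pileup: the het allele balance
is pulled below the expected 0.5 even though the "hidden" bases remain in
the data.  This module measures the allele balance at known het sites and
scans insertions near each site for the hidden alternate allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyper import build_pileup
from .io_formats import AlignmentRecord, VariantRecord


class HiddenLabel(str, enum.Enum):
    VISIBLE = "VISIBLE"
    HIDDEN = "HIDDEN"
    ABSENT = "ABSENT"


def _insertions(aln: AlignmentRecord) -> list[tuple[int, str]]:
    """(reference anchor, inserted bases) per I run; the anchor is the
    reference coordinate immediately following the insertion point."""
    out = []
    i, j = 0, aln.start
    for op, n in aln.cigar:
        if op == "M":
            i += n
            j += n
        elif op == "I":
            out.append((j, aln.bases[i : i + n]))
            i += n
        elif op == "D":
            j += n
        elif op == "S":
            i += n
    return out


def hidden_allele_scan(
    alignments: list[AlignmentRecord],
    contig: str,
    pos: int,
    alt: str,
    k: int = 5,
) -> dict[str, HiddenLabel]:
    """Label each read spanning the site VISIBLE / HIDDEN / ABSENT.

    VISIBLE: the pileup base at the site equals alt.  HIDDEN: the pileup base
    does not, but an insertion whose reference anchor lies within k bases of
    the site contains the alt base (exact matches only).  ABSENT: neither.
    """
    labels: dict[str, HiddenLabel] = {}
    for aln in alignments:
        if aln.contig != contig or not (aln.start <= pos < aln.end):
            continue
        base = None
        i, j = 0, aln.start
        for op, n in aln.cigar:
            if op == "M":
                if j <= pos < j + n:
                    base = aln.bases[i + (pos - j)]
                    break
                i += n
                j += n
            elif op in "IS":
                i += n
            elif op == "D":
                if j <= pos < j + n:
                    break
                j += n
        if base == alt:
            labels[aln.read_id] = HiddenLabel.VISIBLE
            continue
        hidden = any(
            abs(anchor - pos) <= k and alt in bases
            for anchor, bases in _insertions(aln)
        )
        labels[aln.read_id] = HiddenLabel.HIDDEN if hidden else HiddenLabel.ABSENT
    return labels


@dataclass
class AlleleBalanceReport:
    per_site: pd.DataFrame
    # columns: contig, pos, alt, n_ref, n_alt, n_other, alt_fraction,
    #          n_hidden, recovered_alt_fraction
    median_alt_fraction: float
    frac_sites_below_half: float
    median_recovered_alt_fraction: float


def allele_balance(
    alignments: list[AlignmentRecord],
    het_sites: list[VariantRecord],
    refs: dict[str, str],
    min_base_quality: int = 10,
    k: int = 5,
) -> AlleleBalanceReport:
    """Ref/alt pileup counts and hidden-allele recovery at known het sites."""
    if not het_sites:
        raise ValueError("no het sites provided")
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_contig.setdefault(aln.contig, []).append(aln)
    rows = []
    for site in het_sites:
        alns = by_contig.get(site.contig, [])
        col = build_pileup(alns, refs[site.contig], site.pos, contig=site.contig)
        n_ref = n_alt = n_other = 0
        for base, q, _ in col.entries:
            if q < min_base_quality:
                continue
            if base == site.ref_allele:
                n_ref += 1
            elif base == site.alt_allele:
                n_alt += 1
            else:
                n_other += 1
        labels = hidden_allele_scan(alns, site.contig, site.pos, site.alt_allele, k=k)
        n_hidden = sum(1 for v in labels.values() if v is HiddenLabel.HIDDEN)
        denom = n_ref + n_alt
        alt_frac = n_alt / denom if denom else float("nan")
        rec_denom = n_ref + n_alt + n_hidden
        rec_frac = (n_alt + n_hidden) / rec_denom if rec_denom else float("nan")
        rows.append(
            {
                "contig": site.contig,
                "pos": site.pos,
                "alt": site.alt_allele,
                "n_ref": n_ref,
                "n_alt": n_alt,
                "n_other": n_other,
                "alt_fraction": alt_frac,
                "n_hidden": n_hidden,
                "recovered_alt_fraction": rec_frac,
            }
        )
    df = pd.DataFrame(rows)
    fracs = df["alt_fraction"].dropna()
    rec = df["recovered_alt_fraction"].dropna()
    return AlleleBalanceReport(
        per_site=df,
        median_alt_fraction=float(np.median(fracs)) if len(fracs) else float("nan"),
        frac_sites_below_half=float((fracs < 0.5).mean()) if len(fracs) else float("nan"),
        median_recovered_alt_fraction=float(np.median(rec)) if len(rec) else float("nan"),
    )
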