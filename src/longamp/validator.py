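"""Genotype-and-validate: force-call truth-VCF sites and score the calls.

Each site of a truth-status VCF (TRUE_DE_NOVO or ARTIFACT) is genotyped with
the VCF's own alternate allele competing against the reference, and the
polymorphic/monomorphic outcome is classified against the recorded status:

    (TRUE_DE_NOVO, polymorphic) -> TP      (TRUE_DE_NOVO, monomorphic) -> FN
    (ARTIFACT,     polymorphic) -> FP      (ARTIFACT,     monomorphic) -> TN

Sites with no usable data (zero coverage, or removed by the deletion-fraction
filter) are NO_DATA and excluded from metric denominators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .genotyper import GenotypeCall, GenotyperConfig, build_pileup, call_site
from .io_formats import AlignmentRecord, TruthStatus, VariantRecord


class Classification(str, enum.Enum):
    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"
    NO_DATA = "NO_DATA"


@dataclass
class ValidationRecord:
    site: VariantRecord
    call: GenotypeCall | None
    classification: Classification


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_no_data: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn + self.n_no_data


def classify_record(truth_status: TruthStatus, called_polymorphic: bool) -> Classification:
    """Total deterministic 2x2 mapping of truth status x call outcome."""
    if truth_status is TruthStatus.TRUE_DE_NOVO:
        return Classification.TP if called_polymorphic else Classification.FN
    if truth_status is TruthStatus.ARTIFACT:
        return Classification.FP if called_polymorphic else Classification.TN
    raise ValueError(f"cannot classify truth status {truth_status}")


def genotype_and_validate(
    alignments: list[AlignmentRecord],
    truth: list[VariantRecord],
    refs: dict[str, str],
    config: GenotyperConfig = GenotyperConfig(),
) -> tuple[list[ValidationRecord], ConfusionMatrix]:
    records: list[ValidationRecord] = []
    cm = ConfusionMatrix()
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        by_contig.setdefault(aln.contig, []).append(aln)
    for site in truth:
        if site.contig not in refs:
            records.append(ValidationRecord(site, None, Classification.NO_DATA))
            cm.n_no_data += 1
            continue
        col = build_pileup(
            by_contig.get(site.contig, []), refs[site.contig], site.pos, contig=site.contig
        )
        call = call_site(col, site.alt_allele, config)
        if call.filter_status != "PASS":
            records.append(ValidationRecord(site, call, Classification.NO_DATA))
            cm.n_no_data += 1
            continue
        cls = classify_record(site.truth_status, call.polymorphic)
        records.append(ValidationRecord(site, call, cls))
        setattr(cm, cls.value.lower(), getattr(cm, cls.value.lower()) + 1)
    return records, cm


@dataclass
class ValidationMetrics:
    """Sensitivity/specificity/PPV/NPV as percentages; None when undefined."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def rounded(self) -> dict[str, int | None]:
        return {
            name: (None if v is None else int(round(v)))
            for name, v in vars(self).items()
        }


def metrics(cm: ConfusionMatrix) -> ValidationMetrics:
    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return ValidationMetrics(
        sensitivity=pct(cm.tp, cm.tp + cm.fn),
        specificity=pct(cm.tn, cm.tn + cm.fp),
        ppv=pct(cm.tp, cm.tp + cm.fp),
        npv=pct(cm.tn, cm.tn + cm.fn),
    )


def validation_report(records: list[ValidationRecord], cm: ConfusionMatrix) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "contig": rec.site.contig,
                "pos": rec.site.pos,
                "ref": rec.site.ref_allele,
                "alt": rec.site.alt_allele,
                "truth_status": rec.site.truth_status.value,
                "genotype": rec.call.genotype if rec.call else "",
                "qual": rec.call.qual if rec.call else float("nan"),
                "depth_used": rec.call.depth_used if rec.call else 0,
                "filter": rec.call.filter_status if rec.call else "OFF_PANEL",
                "classification": rec.classification.value,
            }
        )
    return pd.DataFrame(rows)
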