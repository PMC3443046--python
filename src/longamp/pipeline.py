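"""End-to-end seeded experiments: simulate -> align -> profile -> recalibrate -> call.

Two designs mirror the two amplicon studies the toolkit emulates:

* validation: a panel carrying het TRUE_DE_NOVO sites plus ARTIFACT sites
  absent from the DNA; every truth site is force-called and scored as a
  confusion matrix with sensitivity/specificity/PPV/NPV.
* discovery: de novo calling over every position, compared against the
  planted het sites, with misses partitioned into reference_bias (the alt
  allele is recoverable from nearby insertions), low_coverage, and other.

A single seed governs the whole run (the simulator derives per-stage
substreams), and a manifest records the seed, stage order and output hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .align import ScoringScheme, align_all
from .genotyper import GenotyperConfig, build_pileup, call_region
from .io_formats import (
    TruthStatus,
    write_fasta,
    write_fastq,
    write_sam,
    write_vcf,
)
from .profiler import profile
from .recalibrate import build_table, recalibrate_alignment
from .refbias import HiddenLabel, hidden_allele_scan
from .simulate import SimConfig, make_panel, simulate_reads, truth_to_alignment
from .validator import genotype_and_validate, metrics, validation_report


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    genotyper: GenotyperConfig = field(default_factory=GenotyperConfig)
    min_obs: int = 100
    n_amplicons: int = 4
    amplicon_len: int = 2000
    outdir: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, cfg: PipelineConfig, stages: list[str]) -> None:
    from . import __version__ as version

    manifest = {
        "version": version,
        "seed": cfg.seed,
        "stages": stages,
        "config": {
            "sim": asdict(cfg.sim),
            "scoring": asdict(cfg.scoring),
            "genotyper": asdict(cfg.genotyper),
            "min_obs": cfg.min_obs,
            "n_amplicons": cfg.n_amplicons,
            "amplicon_len": cfg.amplicon_len,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _simulate_and_align(cfg: PipelineConfig, outdir: Path | None):
    panel, sample, truth = make_panel(
        cfg.sim, n_amplicons=cfg.n_amplicons, amplicon_len=cfg.amplicon_len
    )
    reads, truths = simulate_reads(panel, sample, cfg.sim)
    if not reads:
        raise RuntimeError("align stage: no reads were simulated")
    alignments, unaligned = align_all(reads, panel, cfg.scoring)
    if not alignments:
        raise RuntimeError("align stage: no reads aligned")
    refs = {a.name: a.bases for a in panel.amplicons}
    known = {}
    for v in truth:
        known.setdefault(v.contig, set()).add(v.pos)
    table = build_table(alignments, refs, known_sites=known)
    recal = [recalibrate_alignment(a, table, min_obs=cfg.min_obs) for a in alignments]
    prof = profile(alignments, refs)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(panel.amplicons, outdir / "panel.fasta")
        write_vcf(truth, panel.contigs, outdir / "truth.vcf")
        write_fastq(reads, outdir / "reads.fastq")
        write_sam(
            [truth_to_alignment(t, r) for t, r in zip(truths, reads)],
            panel.amplicons,
            outdir / "truth.sam",
        )
        write_sam(alignments, panel.amplicons, outdir / "aligned.sam")
        write_sam(recal, panel.amplicons, outdir / "recalibrated.sam")
        prof.to_frame().to_csv(outdir / "error_profile.tsv", sep="\t", index=False)
        table.to_frame().to_csv(outdir / "recalibration_table.tsv", sep="\t", index=False)
    return panel, sample, truth, reads, truths, recal, prof, refs, table, unaligned


def run_validation_experiment(cfg: PipelineConfig) -> dict:
    """Simulate the validation design and genotype-and-validate every truth site."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    panel, sample, truth, reads, truths, recal, prof, refs, table, unaligned = (
        _simulate_and_align(cfg, outdir)
    )
    records, cm = genotype_and_validate(recal, truth, refs, cfg.genotyper)
    mets = metrics(cm)
    report = validation_report(records, cm)
    if outdir is not None:
        report.to_csv(outdir / "validation_report.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                    "no_data": cm.n_no_data,
                    "sensitivity": mets.sensitivity,
                    "specificity": mets.specificity,
                    "ppv": mets.ppv,
                    "npv": mets.npv,
                }
            ]
        )
        summary.to_csv(outdir / "validation_summary.tsv", sep="\t", index=False)
        _write_manifest(
            outdir, cfg, ["simulate", "align", "profile", "recalibrate", "validate"]
        )
    return {
        "panel": panel,
        "sample": sample,
        "truth": truth,
        "n_reads": len(reads),
        "n_unaligned": len(unaligned),
        "profile": prof,
        "records": records,
        "confusion_matrix": cm,
        "metrics": mets,
        "report": report,
    }


def run_discovery_experiment(cfg: PipelineConfig, low_coverage_depth: int = 10) -> dict:
    """Discovery-mode calling with per-site concordance and miss reasons."""
    outdir = Path(cfg.outdir) if cfg.outdir else None
    panel, sample, truth, reads, truths, recal, prof, refs, table, unaligned = (
        _simulate_and_align(cfg, outdir)
    )
    calls = []
    for amp in panel.amplicons:
        calls.extend(call_region(recal, amp.bases, amp.name, cfg.genotyper))
    called = {(c.contig, c.pos) for c in calls}
    planted = [v for v in truth if v.truth_status is TruthStatus.TRUE_DE_NOVO]
    rows = []
    miss_reasons = {"reference_bias": 0, "low_coverage": 0, "other": 0}
    n_hit = 0
    for site in planted:
        hit = (site.contig, site.pos) in called
        reason = ""
        if hit:
            n_hit += 1
        else:
            col = build_pileup(
                [a for a in recal if a.contig == site.contig],
                refs[site.contig],
                site.pos,
                contig=site.contig,
            )
            depth_used = sum(
                1 for b, q, _ in col.entries if q >= cfg.genotyper.min_base_quality
            )
            if depth_used < low_coverage_depth:
                reason = "low_coverage"
            else:
                labels = hidden_allele_scan(
                    recal, site.contig, site.pos, site.alt_allele
                )
                n_hidden = sum(1 for v in labels.values() if v is HiddenLabel.HIDDEN)
                reason = "reference_bias" if n_hidden >= 2 else "other"
            miss_reasons[reason] += 1
        rows.append(
            {
                "contig": site.contig,
                "pos": site.pos,
                "alt": site.alt_allele,
                "called": hit,
                "miss_reason": reason,
            }
        )
    concordance = pd.DataFrame(rows)
    false_calls = [
        c for c in calls if (c.contig, c.pos) not in {(v.contig, v.pos) for v in planted}
    ]
    if outdir is not None:
        concordance.to_csv(outdir / "discovery_concordance.tsv", sep="\t", index=False)
        _write_manifest(
            outdir, cfg, ["simulate", "align", "profile", "recalibrate", "discover"]
        )
    return {
        "panel": panel,
        "truth": truth,
        "calls": calls,
        "n_sites": len(planted),
        "n_called": n_hit,
        "sensitivity": n_hit / len(planted) if planted else float("nan"),
        "miss_reasons": miss_reasons,
        "false_calls": false_calls,
        "concordance": concordance,
        "profile": prof,
    }
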