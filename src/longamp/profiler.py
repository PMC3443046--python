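"""Error-mode decomposition, per-cycle error rates, read-length and GC-bias statistics.

Rates use aligned read bases (M + I ops, i.e. insertions included) as the
common denominator so the three mode rates sum coherently.  Deletions are
attached to the preceding read position for the positional table.  Read
positions ("cycles") are reported in sequencing orientation: reverse-strand
alignments are re-indexed from the read's 3' reference end.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, FormatError, SequenceRecord


class Event(enum.Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    INSERTION = "INSERTION"
    DELETION = "DELETION"


@dataclass
class ClassifiedEvent:
    cycle: int  # 0-based read position in sequencing orientation
    event: Event
    ref_pos: int | None  # reference coordinate (deleted base for DELETION)


def classify_events(aln: AlignmentRecord, ref: str) -> list[ClassifiedEvent]:
    """Label each read base MATCH/MISMATCH/INSERTION; deletions anchored to
    the preceding read position."""
    events: list[ClassifiedEvent] = []
    i = 0  # read index, reference orientation
    j = aln.start
    read_len = len(aln.bases)

    def cycle(idx: int) -> int:
        return read_len - 1 - idx if aln.is_reverse else idx

    if j + aln.reference_length > len(ref):
        raise FormatError(f"{aln.read_id}: alignment overruns reference")
    for op, n in aln.cigar:
        if op == "M":
            for k in range(n):
                ev = Event.MATCH if aln.bases[i] == ref[j] else Event.MISMATCH
                events.append(ClassifiedEvent(cycle(i), ev, j))
                i += 1
                j += 1
        elif op == "I":
            for k in range(n):
                events.append(ClassifiedEvent(cycle(i), Event.INSERTION, j))
                i += 1
        elif op == "D":
            anchor = max(0, i - 1)
            for k in range(n):
                events.append(ClassifiedEvent(cycle(anchor), Event.DELETION, j))
                j += 1
        elif op == "S":
            i += n
        else:
            raise FormatError(f"{aln.read_id}: unsupported op {op}")
    return events


@dataclass
class ErrorProfile:
    n_aligned_bases: int
    counts: dict[str, int]  # mismatch / insertion / deletion
    rates: dict[str, float]
    per_position: pd.DataFrame  # columns: position, events, observations, rate
    mean_read_length: float
    frac_reads_gt_2500: float

    @property
    def total_rate(self) -> float:
        return sum(self.rates.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mode": mode, "count": self.counts[mode], "rate": self.rates[mode]}
            for mode in ("mismatch", "insertion", "deletion")
        ]
        rows.append(
            {"mode": "total", "count": sum(self.counts.values()), "rate": self.total_rate}
        )
        return pd.DataFrame(rows)


def profile(
    alignments: list[AlignmentRecord],
    refs: dict[str, str],
    known_sites: dict[str, set[int]] | None = None,
    exclude_known: bool = False,
    max_position: int = 1000,
    length_threshold: float = 2500.0,
) -> ErrorProfile:
    """Aggregate classified events over all alignments.

    By default every sequenced base contributes, including bases at known
    variant sites (matching the convention that slightly inflates the
    apparent mismatch rate at het sites); ``exclude_known=True`` drops bases
    and deletions at the listed reference positions.
    """
    if not alignments:
        raise ValueError("no aligned reads to profile")
    known = known_sites or {}
    counts = {"mismatch": 0, "insertion": 0, "deletion": 0}
    n_aligned = 0
    max_len = max(len(a.bases) for a in alignments)
    table_len = min(max_len, max_position)
    pos_events = np.zeros(table_len, dtype=np.int64)
    pos_obs = np.zeros(table_len, dtype=np.int64)
    lengths = []
    for aln in alignments:
        lengths.append(len(aln.bases))
        site_set = known.get(aln.contig, set()) if exclude_known else None
        for ev in classify_events(aln, refs[aln.contig]):
            if site_set is not None and ev.ref_pos in site_set:
                continue
            is_base = ev.event is not Event.DELETION
            if is_base:
                n_aligned += 1
                if ev.cycle < table_len:
                    pos_obs[ev.cycle] += 1
            if ev.event is Event.MISMATCH:
                counts["mismatch"] += 1
            elif ev.event is Event.INSERTION:
                counts["insertion"] += 1
            elif ev.event is Event.DELETION:
                counts["deletion"] += 1
            else:
                continue
            if ev.cycle < table_len:
                pos_events[ev.cycle] += 1
    if n_aligned == 0:
        raise ValueError("no aligned bases")
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_rate = np.where(pos_obs > 0, pos_events / np.maximum(pos_obs, 1), np.nan)
    per_position = pd.DataFrame(
        {
            "position": np.arange(table_len),
            "events": pos_events,
            "observations": pos_obs,
            "rate": pos_rate,
        }
    )
    lengths_arr = np.asarray(lengths)
    return ErrorProfile(
        n_aligned_bases=n_aligned,
        counts=counts,
        rates={k: v / n_aligned for k, v in counts.items()},
        per_position=per_position,
        mean_read_length=float(lengths_arr.mean()),
        frac_reads_gt_2500=float((lengths_arr > length_threshold).mean()),
    )


def position_slope(prof: ErrorProfile) -> float:
    """Weighted least-squares slope of per-position error rate on position."""
    df = prof.per_position
    mask = df["observations"].to_numpy() > 0
    x = df["position"].to_numpy()[mask].astype(float)
    y = df["rate"].to_numpy()[mask]
    w = df["observations"].to_numpy()[mask].astype(float)
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    denom = np.average((x - xbar) ** 2, weights=w)
    if denom == 0:
        return 0.0
    return float(np.average((x - xbar) * (y - ybar), weights=w) / denom)


@dataclass
class ReadLengthStats:
    mean: float
    median: float
    frac_gt_2500: float
    histogram: pd.DataFrame  # columns: bin_start, count (bin width 100)


def read_length_stats(
    reads: list[SequenceRecord], threshold: float = 2500.0, bin_width: int = 100
) -> ReadLengthStats:
    if not reads:
        raise ValueError("no reads")
    lengths = np.asarray([len(r) for r in reads])
    edges = np.arange(0, lengths.max() + bin_width + 1, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1], "count": counts})
    return ReadLengthStats(
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        frac_gt_2500=float((lengths > threshold).mean()),
        histogram=hist,
    )


@dataclass
class GCBiasCurve:
    window_size: int
    bins: pd.DataFrame
    # columns: gc_low, gc_high, n_windows, mean_coverage, relative_coverage,
    #          low_confidence
    global_mean_coverage: float

    def weighted_mean_relative(self) -> float:
        df = self.bins[self.bins["n_windows"] > 0]
        return float(
            np.average(df["relative_coverage"], weights=df["n_windows"])
        )


def gc_bias(
    alignments: list[AlignmentRecord],
    refs: dict[str, str],
    window_size: int = 100,
    bin_width: float = 0.05,
    min_windows: int = 5,
) -> GCBiasCurve:
    """Relative coverage per GC-fraction bin over non-overlapping windows.

    Coverage of a window = aligned reference-consuming bases (M and D ops)
    overlapping it, divided by the window size; relative coverage divides by
    the mean over all windows.
    """
    depth: dict[str, np.ndarray] = {}
    for name, seq in refs.items():
        if window_size > len(seq):
            raise ValueError(f"window_size {window_size} exceeds contig {name} length")
        depth[name] = np.zeros(len(seq) + 1, dtype=np.int64)
    for aln in alignments:
        diff = depth[aln.contig]
        j = aln.start
        for op, n in aln.cigar:
            if op in "MD":
                diff[j] += 1
                diff[j + n] -= 1
                j += n

    gc_vals = []
    cov_vals = []
    for name, seq in refs.items():
        cov = np.cumsum(depth[name][:-1])
        n_win = len(seq) // window_size
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[: n_win * window_size]
        win = arr.reshape(n_win, window_size)
        gc = ((win == ord("G")) | (win == ord("C"))).mean(axis=1)
        wcov = cov[: n_win * window_size].reshape(n_win, window_size).mean(axis=1)
        gc_vals.append(gc)
        cov_vals.append(wcov)
    gc_all = np.concatenate(gc_vals)
    cov_all = np.concatenate(cov_vals)
    global_mean = float(cov_all.mean())

    n_bins = int(round(1.0 / bin_width))
    idx = np.minimum((gc_all / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n_w = int(mask.sum())
        mean_cov = float(cov_all[mask].mean()) if n_w else 0.0
        rel = mean_cov / global_mean if global_mean > 0 else 0.0
        rows.append(
            {
                "gc_low": b * bin_width,
                "gc_high": (b + 1) * bin_width,
                "n_windows": n_w,
                "mean_coverage": mean_cov,
                "relative_coverage": rel,
                "low_confidence": n_w < min_windows,
            }
        )
    return GCBiasCurve(
        window_size=window_size, bins=pd.DataFrame(rows), global_mean_coverage=global_mean
    )
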