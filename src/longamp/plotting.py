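"""Small matplotlib views of the profiler and reference-bias reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .profiler import ErrorProfile, GCBiasCurve, ReadLengthStats
from .refbias import AlleleBalanceReport


def plot_error_profile(prof: ErrorProfile, ax=None):
    """Bar chart of the three error-mode rates plus the per-cycle rate curve."""
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
    modes = ["insertion", "deletion", "mismatch"]
    ax[0].bar(modes, [100 * prof.rates[m] for m in modes])
    ax[0].set_ylabel("% of aligned bases")
    df = prof.per_position
    ax[1].plot(df["position"], 100 * df["rate"], lw=0.8)
    ax[1].set_xlabel("read position")
    ax[1].set_ylabel("error rate (%)")
    return ax


def plot_read_lengths(stats: ReadLengthStats, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    h = stats.histogram
    ax.bar(h["bin_start"], h["count"], width=90, align="edge")
    ax.axvline(stats.mean, color="k", ls="--", label=f"mean {stats.mean:.0f}")
    ax.set_xlabel("read length (bases)")
    ax.set_ylabel("reads")
    ax.legend()
    return ax


def plot_gc_bias(curve: GCBiasCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    df = curve.bins[curve.bins["n_windows"] > 0]
    mid = (df["gc_low"] + df["gc_high"]) / 2
    ax.plot(mid, df["relative_coverage"], marker="o")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("window GC fraction")
    ax.set_ylabel("relative coverage")
    return ax


def plot_allele_balance(report: AlleleBalanceReport, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    df = report.per_site
    ax.hist(df["alt_fraction"].dropna(), bins=20, alpha=0.6, label="aligned")
    ax.axvline(0.5, color="k", lw=0.5)
    ax.axvline(
        report.median_alt_fraction,
        color="C3",
        ls="--",
        label=f"median {report.median_alt_fraction:.2f}",
    )
    ax.set_xlabel("alt allele fraction at het sites")
    ax.set_ylabel("sites")
    ax.legend()
    return ax
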