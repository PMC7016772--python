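"""Read-level GC content versus base quality, and the footprint of quality
filtering on the GC composition of a read set.

Some sequencing chemistries call GC-rich reads with lower confidence, so
quality filtering removes those reads disproportionately and the surviving
read set is depleted of high-GC sequence — a second, software-side route by
which GC bias enters coverage.  This module computes per-read GC and median
Phred, boxplot summaries per 1% GC bin, and the per-bin proportion ratio
between a quality-filtered and an unfiltered read set.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .windows import gc_bin_of

logger = logging.getLogger(__name__)

Reads = Sequence[tuple[str, np.ndarray]]

BOXPLOT_COLUMNS = ["gc_bin", "n_reads", "median", "q1", "q3", "p10", "p90"]
RATIO_COLUMNS = [
    "gc_bin",
    "proportion_filtered",
    "proportion_unfiltered",
    "ratio",
    "abundant",
]

#: A GC bin is "abundant" when it holds at least this fraction of the
#: unfiltered reads; sparse bins give noisy ratios and are flagged.
ABUNDANCE_THRESHOLD = 0.001


def _read_gc_percent(sequence: str) -> float:
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        return float("nan")
    return 100.0 * gc / (gc + at)


def read_gc_and_median_quality(reads: Reads) -> pd.DataFrame:
    """Per-read GC bin and median Phred score.

    GC is computed over unambiguous bases; the median is over all bases
    (mean of the central pair for even lengths).  Reads with no unambiguous
    bases are skipped and counted in the log.
    """
    if not reads:
        raise ValueError("no reads supplied")
    gc_bins: list[int] = []
    medians: list[float] = []
    skipped = 0
    for seq, quals in reads:
        gc = _read_gc_percent(seq)
        if np.isnan(gc):
            skipped += 1
            continue
        gc_bins.append(int(gc_bin_of(gc)))
        medians.append(float(np.median(np.asarray(quals, dtype=float))))
    if skipped:
        logger.info("%d reads without unambiguous bases skipped", skipped)
    if not gc_bins:
        raise ValueError("every read lacked unambiguous bases")
    return pd.DataFrame({"gc_bin": gc_bins, "median_phred": medians})


def bin_quality_stats(per_read: pd.DataFrame) -> pd.DataFrame:
    """Boxplot statistics of median Phred per 1% GC bin.

    Median, quartiles and the 10th/90th percentiles use linear interpolation
    between order statistics.
    """
    rows = []
    for gc_bin, group in per_read.groupby("gc_bin"):
        q = np.percentile(group["median_phred"].to_numpy(), [10, 25, 50, 75, 90])
        rows.append((int(gc_bin), len(group), q[2], q[1], q[3], q[0], q[4]))
    return pd.DataFrame(rows, columns=BOXPLOT_COLUMNS)


def median_phred_filter(reads: Reads, min_median: float) -> list[tuple[str, np.ndarray]]:
    """Keep reads whose median Phred score is at least *min_median*.

    Convenience for simulation-driven comparisons; real pipelines filter
    upstream with dedicated trimming tools.
    """
    return [
        (seq, quals)
        for seq, quals in reads
        if float(np.median(np.asarray(quals, dtype=float))) >= min_median
    ]


def gc_proportions(reads: Reads, bin_width: float = 1.0) -> pd.Series:
    """Proportion of reads falling in each GC bin (bins sum to 1)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    gcs = np.array([_read_gc_percent(seq) for seq, _ in reads])
    gcs = gcs[~np.isnan(gcs)]
    if gcs.size == 0:
        raise ValueError("no reads with unambiguous bases")
    bins = np.floor(gcs / bin_width + 0.5).astype(int)
    counts = pd.Series(bins).value_counts().sort_index()
    return counts / counts.sum()


def filter_proportion_ratios(
    filtered_reads: Reads,
    unfiltered_reads: Reads,
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Per-GC-bin proportion of filtered reads divided by that of unfiltered.

    A ratio below 1 in a bin means quality filtering removed reads of that
    GC content disproportionately.  Bins absent from the unfiltered set have
    an undefined (NaN) ratio; the ``abundant`` flag marks bins holding at
    least 0.1% of the unfiltered reads, where the ratio is trustworthy.
    """
    prop_f = gc_proportions(filtered_reads, bin_width)
    prop_u = gc_proportions(unfiltered_reads, bin_width)
    all_bins = sorted(set(prop_f.index) | set(prop_u.index))
    pf = prop_f.reindex(all_bins, fill_value=0.0)
    pu = prop_u.reindex(all_bins, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pu > 0, pf / pu, np.nan)
    return pd.DataFrame(
        {
            "gc_bin": all_bins,
            "proportion_filtered": pf.to_numpy(),
            "proportion_unfiltered": pu.to_numpy(),
            "ratio": ratio,
            "abundant": pu.to_numpy() >= ABUNDANCE_THRESHOLD,
        }
    )


def plot_quality_boxes(stats: pd.DataFrame, path) -> None:
    """Boxplot-style summary of median read quality per GC bin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for _, row in stats.iterrows():
        g = row["gc_bin"]
        ax.vlines(g, row["p10"], row["p90"], color="0.6", lw=0.8)
        ax.add_patch(
            plt.Rectangle(
                (g - 0.4, row["q1"]), 0.8, row["q3"] - row["q1"],
                facecolor="lightsteelblue", edgecolor="0.3", lw=0.5,
            )
        )
        ax.hlines(row["median"], g - 0.4, g + 0.4, color="darkorange", lw=1.2)
    ax.set_xlabel("read GC content bin (%)")
    ax.set_ylabel("median Phred score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_proportion_ratios(ratios: pd.DataFrame, path) -> None:
    """Bar chart of filtered/unfiltered proportion ratios; abundant bins
    (>= 0.1% of unfiltered reads) in full colour, sparse bins faded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    populated = ratios.dropna(subset=["ratio"])
    scale = np.clip(
        populated["proportion_unfiltered"].to_numpy() / ABUNDANCE_THRESHOLD, 0.0, 1.0
    )
    colors = [(0.0, 0.1, 0.6, 0.15 + 0.85 * s) for s in scale]
    ax.bar(populated["gc_bin"], populated["ratio"], color=colors, width=0.9)
    ax.axhline(1.0, color="red", lw=0.8, ls="--")
    ax.set_xlabel("read GC content bin (%)")
    ax.set_ylabel("proportion ratio (filtered / unfiltered)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
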