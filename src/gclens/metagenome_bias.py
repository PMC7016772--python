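"""Metagenome-mode GC-bias quantification.

Metagenome contigs come from organisms of unknown, unequal abundance, so
coverage cannot be normalized to a single reference GC bin shared by all
contigs.  Instead, bias is measured *within* each contig: windows are binned
by GC, per-bin average coverages are computed per contig, and the coverage
ratio of every ordered pair of GC bins present in the same contig is taken.
Those ratios are averaged across all contigs containing both bins, and the
log10 of the average is reported — a positive entry (i, j) means windows of
GC content i are better covered than windows of GC content j, regardless of
which organism each contig came from.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATRIX_COLUMNS = ["numerator_gc", "denominator_gc", "log10_mean_ratio", "n_contigs"]


def contig_bin_means(
    window_table: pd.DataFrame,
    min_windows_per_bin: int = 1,
) -> dict[str, dict[int, float]]:
    """Average coverage of each populated 1% GC bin, separately per contig.

    Bins with zero mean depth are excluded (they cannot enter a ratio), as
    are bins with fewer than *min_windows_per_bin* windows.
    """
    result: dict[str, dict[int, float]] = {}
    for contig, group in window_table.groupby("contig", sort=False):
        agg = group.groupby("gc_bin")["mean_depth"].agg(["mean", "size"])
        agg = agg[(agg["size"] >= min_windows_per_bin) & (agg["mean"] > 0)]
        result[str(contig)] = {int(b): float(m) for b, m in agg["mean"].items()}
    return result


def ratio_matrix(
    per_contig_bin_means: Mapping[str, Mapping[int, float]],
    geometric_mean: bool = False,
) -> pd.DataFrame:
    """Cross-contig average of within-contig GC-bin coverage ratios.

    For every contig and every ordered pair of GC bins (i, j) populated in
    it, the ratio ``mean(bin i) / mean(bin j)`` is formed.  Ratios for a pair
    are averaged arithmetically across contributing contigs and the log10 of
    that average is stored together with the contig count.  Diagonal entries
    are exactly 0 with ``n_contigs`` = number of contigs containing the bin.

    With the arithmetic mean the matrix is not exactly antisymmetric for
    more than one contig: by AM-GM, ``M[i,j] + M[j,i] >= 0`` with equality
    only when the pair's ratio is identical in every contributing contig.
    ``geometric_mean=True`` averages the ratios geometrically instead, which
    restores exact antisymmetry.
    """
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    any_pair = False
    for contig, bin_means in per_contig_bin_means.items():
        bins = sorted(bin_means)
        if len(bins) >= 2:
            any_pair = True
        for i in bins:
            for j in bins:
                r = bin_means[i] / bin_means[j]
                key = (i, j)
                if geometric_mean:
                    sums[key] = sums.get(key, 0.0) + np.log10(r)
                else:
                    sums[key] = sums.get(key, 0.0) + r
                counts[key] = counts.get(key, 0) + 1
    if not any_pair:
        raise ValueError(
            "no contig has two populated GC bins; cannot form coverage ratios"
        )
    values: dict[tuple[int, int], float] = {}
    for (i, j), total in sorted(sums.items()):
        n = counts[(i, j)]
        if i == j:
            values[(i, j)] = 0.0
        elif i > j and (geometric_mean or n == 1):
            # mirror is an exact negation: enforce it structurally so
            # antisymmetry holds to the last bit
            values[(i, j)] = -values[(j, i)]
        elif geometric_mean:
            values[(i, j)] = total / n
        else:
            values[(i, j)] = float(np.log10(total / n))
    rows = [
        (i, j, values[(i, j)], counts[(i, j)]) for (i, j) in sorted(values)
    ]
    return pd.DataFrame(rows, columns=MATRIX_COLUMNS)


def matrix_pivot(matrix: pd.DataFrame) -> pd.DataFrame:
    """Wide (numerator x denominator) view of the log10 mean ratios."""
    return matrix.pivot(
        index="numerator_gc", columns="denominator_gc", values="log10_mean_ratio"
    )


def export_matrix(
    matrix: pd.DataFrame,
    tsv_path: str | Path,
    heatmap_path: str | Path | None = None,
) -> None:
    """Write the long-format TSV and, optionally, a static heatmap.

    The heatmap encodes the log10 mean ratio as colour and fades cells
    supported by few contigs.
    """
    if matrix.empty:
        raise ValueError("cannot export an empty ratio matrix")
    matrix.to_csv(tsv_path, sep="\t", index=False, lineterminator="\n")
    if heatmap_path is None:
        return

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = matrix_pivot(matrix)
    support = matrix.pivot(
        index="numerator_gc", columns="denominator_gc", values="n_contigs"
    )
    values = wide.to_numpy(dtype=float)
    alpha = np.clip(support.to_numpy(dtype=float) / 10.0, 0.2, 1.0)
    vmax = np.nanmax(np.abs(values)) or 1.0

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    im = ax.imshow(
        values,
        origin="lower",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        alpha=np.where(np.isnan(values), 0.0, alpha),
        extent=[
            wide.columns.min() - 0.5,
            wide.columns.max() + 0.5,
            wide.index.min() - 0.5,
            wide.index.max() + 0.5,
        ],
        aspect="auto",
    )
    fig.colorbar(im, ax=ax, label="log10 mean coverage ratio")
    ax.set_xlabel("denominator GC bin (%)")
    ax.set_ylabel("numerator GC bin (%)")
    fig.tight_layout()
    fig.savefig(heatmap_path, dpi=150)
    plt.close(fig)


def import_matrix(tsv_path: str | Path) -> pd.DataFrame:
    """Read back a matrix written by :func:`export_matrix`."""
    table = pd.read_csv(tsv_path, sep="\t")
    missing = set(MATRIX_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"matrix TSV missing columns: {sorted(missing)}")
    return table[MATRIX_COLUMNS].astype(
        {"numerator_gc": int, "denominator_gc": int, "n_contigs": int}
    )
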