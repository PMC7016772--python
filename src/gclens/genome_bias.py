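"""Genome-mode GC-bias quantification.

For a single organism, every retained contig is assumed equally abundant, so
coverage differences between windows of different GC content measure bias
introduced by library preparation and sequencing.  The procedure: bin the
windows by GC (1% bins), divide every window's depth by the average depth of
the 49%-GC reference bin, take log10 of each bin's average normalized
coverage, and fit a weighted quadratic in GC percent.  The curvature and
vertex of that parabola summarise the workflow's bias profile; a flat fit
(a ~ 0) means unbiased coverage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .io_formats import SECONDARY_OR_SUPPLEMENTARY, FeatureInterval

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_BIN = 49
DEFAULT_MIN_BIN_WINDOWS = 3

PROFILE_COLUMNS = ["gc_bin", "n_windows", "mean_norm", "sd_norm", "log10_mean"]


@dataclass(frozen=True)
class QuadraticFit:
    """Weighted quadratic fit ``y = a*g^2 + b*g + c`` of log10 normalized
    coverage on GC percent, with standard errors and weighted R^2."""

    a: float
    b: float
    c: float
    r_squared: float
    n_bins: int
    total_weight: float
    stderr_a: float
    stderr_b: float
    stderr_c: float

    def predict(self, gc_percent: np.ndarray | float) -> np.ndarray | float:
        g = np.asarray(gc_percent, dtype=float)
        out = self.a * g**2 + self.b * g + self.c
        return float(out) if np.ndim(gc_percent) == 0 else out

    @property
    def vertex(self) -> float:
        """GC percent of optimal coverage (parabola apex)."""
        if self.a == 0:
            return float("nan")
        return -self.b / (2.0 * self.a)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")


@dataclass(frozen=True)
class FeatureRatio:
    """Mean depth over annotated intervals relative to the rest of the
    same contigs (e.g. rRNA loci against the genomic background)."""

    feature_mean_depth: float
    background_mean_depth: float

    @property
    def ratio(self) -> float:
        return self.feature_mean_depth / self.background_mean_depth


def normalize_windows(
    window_table: pd.DataFrame,
    reference_bin: int = DEFAULT_REFERENCE_BIN,
    min_ref_windows: int = DEFAULT_MIN_BIN_WINDOWS,
) -> pd.DataFrame:
    """Divide every window's depth by the reference GC bin's average depth.

    The default anchor is the 49% bin, which moderately GC-poor through
    GC-rich bacterial genomes all populate.  After normalization the
    reference bin's mean is 1.0 by construction.  The raw depth is kept in a
    ``raw_depth`` column.

    Raises
    ------
    ValueError
        If the reference bin holds fewer than *min_ref_windows* windows of
        positive depth; the message lists candidate bins that would qualify.
    """
    in_ref = (window_table["gc_bin"] == reference_bin) & (
        window_table["mean_depth"] > 0
    )
    n_ref = int(in_ref.sum())
    if n_ref < min_ref_windows:
        counts = (
            window_table.loc[window_table["mean_depth"] > 0]
            .groupby("gc_bin")["mean_depth"]
            .size()
        )
        candidates = sorted(counts.index[counts >= min_ref_windows].tolist())
        raise ValueError(
            f"reference GC bin {reference_bin} has {n_ref} windows with "
            f"positive depth (need >= {min_ref_windows}); candidate bins: "
            f"{candidates}"
        )
    ref_mean = float(window_table.loc[in_ref, "mean_depth"].mean())
    out = window_table.copy()
    out["raw_depth"] = out["mean_depth"]
    out["mean_depth"] = out["mean_depth"] / ref_mean
    out.attrs = dict(window_table.attrs)
    out.attrs["reference_bin"] = reference_bin
    out.attrs["reference_mean_depth"] = ref_mean
    return out


def bin_profile(
    normalized_table: pd.DataFrame,
    min_windows_per_bin: int = DEFAULT_MIN_BIN_WINDOWS,
) -> pd.DataFrame:
    """Per-GC-bin summary of normalized coverage.

    Each surviving bin records its window count, the arithmetic mean and
    sample standard deviation (n-1 denominator) of normalized coverage, and
    the log10 of that mean.  Bins with fewer than *min_windows_per_bin*
    windows are dropped, as are bins whose mean is not positive (log10
    undefined).
    """
    grouped = normalized_table.groupby("gc_bin")["mean_depth"]
    profile = pd.DataFrame(
        {
            "gc_bin": grouped.size().index.astype(int),
            "n_windows": grouped.size().to_numpy(),
            "mean_norm": grouped.mean().to_numpy(),
            "sd_norm": grouped.std(ddof=1).fillna(0.0).to_numpy(),
        }
    )
    profile = profile[profile["n_windows"] >= min_windows_per_bin]
    dropped_zero = int((profile["mean_norm"] <= 0).sum())
    if dropped_zero:
        logger.warning("%d GC bins with non-positive mean coverage dropped", dropped_zero)
        profile = profile[profile["mean_norm"] > 0]
    profile = profile.reset_index(drop=True)
    if len(profile) < 3:
        raise ValueError(
            f"only {len(profile)} GC bins with >= {min_windows_per_bin} windows; "
            "cannot characterise a quadratic bias curve"
        )
    profile["log10_mean"] = np.log10(profile["mean_norm"])
    return profile


def fit_quadratic(profile: pd.DataFrame) -> QuadraticFit:
    """Weighted least-squares quadratic of ``log10_mean`` on GC percent.

    Weights are the per-bin window counts, so well-populated bins dominate
    the fit.  R^2 is computed with the same weights, about the weighted mean.
    Standard errors come from the usual WLS covariance with the residual
    variance estimated on ``n_bins - 3`` degrees of freedom.
    """
    g = profile["gc_bin"].to_numpy(dtype=float)
    y = profile["log10_mean"].to_numpy(dtype=float)
    w = profile["n_windows"].to_numpy(dtype=float)
    if len(g) < 3:
        raise ValueError("need at least 3 GC bins to fit a quadratic")
    if np.unique(g).size < 3:
        raise ValueError("rank-deficient design: fewer than 3 distinct GC bins")

    X = np.column_stack([g**2, g, np.ones_like(g)])
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design in quadratic fit")
    a, b, c = (float(v) for v in coef)

    resid = y - X @ coef
    ss_res = float(np.sum(w * resid**2))
    wmean = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - wmean) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    dof = len(g) - 3
    xtwx_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    if dof > 0:
        sigma2 = ss_res / dof
        se = np.sqrt(np.diag(xtwx_inv) * sigma2)
    else:
        se = np.zeros(3)

    return QuadraticFit(
        a=a,
        b=b,
        c=c,
        r_squared=float(r_squared),
        n_bins=len(g),
        total_weight=float(np.sum(w)),
        stderr_a=float(se[0]),
        stderr_b=float(se[1]),
        stderr_c=float(se[2]),
    )


def feature_background_ratio(
    depth_tracks: Mapping[str, np.ndarray],
    feature_intervals: Sequence[FeatureInterval],
) -> FeatureRatio:
    """Mean depth over the union of intervals vs. the rest of those contigs.

    Only contigs carrying at least one interval contribute background
    positions, so the ratio contrasts features against their own genomic
    context rather than against unrelated contigs.
    """
    if not feature_intervals:
        raise ValueError("no feature intervals supplied")
    masks: dict[str, np.ndarray] = {}
    for iv in feature_intervals:
        if iv.contig not in depth_tracks:
            raise ValueError(f"interval contig {iv.contig!r} has no depth track")
        track_len = len(depth_tracks[iv.contig])
        if iv.end > track_len:
            raise ValueError(
                f"interval {iv.contig}:{iv.start}-{iv.end} exceeds contig "
                f"length {track_len}"
            )
        mask = masks.setdefault(iv.contig, np.zeros(track_len, dtype=bool))
        mask[iv.start : iv.end] = True

    feat_sum = feat_n = bg_sum = bg_n = 0.0
    for contig, mask in masks.items():
        depths = np.asarray(depth_tracks[contig], dtype=float)
        feat_sum += float(depths[mask].sum())
        feat_n += int(mask.sum())
        bg_sum += float(depths[~mask].sum())
        bg_n += int((~mask).sum())
    if feat_n == 0:
        raise ValueError("feature interval union is empty")
    if bg_n == 0:
        raise ValueError("no background positions remain outside the features")
    background_mean = bg_sum / bg_n
    if background_mean <= 0:
        raise ValueError("background mean depth is zero; ratio undefined")
    return FeatureRatio(
        feature_mean_depth=feat_sum / feat_n,
        background_mean_depth=background_mean,
    )


def amplicon_read_ratio(
    alignment_path: str | Path,
    reference_pair: tuple[str, str],
) -> float:
    """Ratio of primary-aligned read counts between two reference sequences.

    Used for spiked two-amplicon experiments where equal molar input should
    yield equal read counts; a ratio far from 1 directly measures the
    workflow's preference for one amplicon's GC content.  A zero denominator
    count returns ``inf`` with a warning.
    """
    ref_a, ref_b = reference_pair
    counts = {ref_a: 0, ref_b: 0}
    with pysam.AlignmentFile(str(alignment_path)) as handle:
        for read in handle.fetch(until_eof=True):
            if read.is_unmapped or (read.flag & SECONDARY_OR_SUPPLEMENTARY):
                continue
            if read.reference_name in counts:
                counts[read.reference_name] += 1
    if counts[ref_b] == 0:
        warnings.warn(
            f"no primary alignments on denominator reference {ref_b!r}; "
            "ratio is infinite",
            stacklevel=2,
        )
        return float("inf")
    return counts[ref_a] / counts[ref_b]


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile[PROFILE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def plot_profile(
    profile: pd.DataFrame,
    path: str | Path,
    fit: QuadraticFit | None = None,
    mean_gc: float | None = None,
    title: str | None = None,
) -> None:
    """Dot plot of log10 normalized coverage per GC bin.

    Error bars show +/-1 sd of normalized coverage (asymmetric on the log
    axis); dot intensity scales with log window count; a vertical line marks
    the assembly's mean GC and a dashed horizontal line the zero level.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    g = profile["gc_bin"].to_numpy(dtype=float)
    mean = profile["mean_norm"].to_numpy()
    sd = profile["sd_norm"].to_numpy()
    y = np.log10(mean)
    lower = np.where(mean - sd > 0, y - np.log10(np.clip(mean - sd, 1e-300, None)), 0.0)
    upper = np.log10(mean + sd) - y

    intensity = np.log10(profile["n_windows"].to_numpy(dtype=float) + 1)
    intensity = intensity / intensity.max()
    colors = [(0.1, 0.2, 0.8, 0.25 + 0.75 * v) for v in intensity]
    ax.errorbar(g, y, yerr=[lower, upper], fmt="none", ecolor="0.6", elinewidth=0.8)
    ax.scatter(g, y, c=colors, s=22, zorder=3)
    if fit is not None:
        gg = np.linspace(g.min(), g.max(), 200)
        ax.plot(gg, fit.predict(gg), color="crimson", lw=1.2,
                label=f"quadratic fit (R$^2$={fit.r_squared:.2f})")
        ax.legend(frameon=False, fontsize=8)
    if mean_gc is not None:
        ax.axvline(mean_gc, color="green", lw=1.0)
    ax.axhline(0.0, color="red", lw=0.8, ls="--")
    ax.set_xlabel("GC content of window (%)")
    ax.set_ylabel("log10 normalized coverage")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
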