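"""Sliding-window GC content and mean coverage.

Every bias statistic downstream consumes the window table produced here:
one row per window with its GC percentage (over unambiguous bases), the
1%-wide GC bin it falls in, and the arithmetic mean read depth across the
window.  Windows tile each contig from position 0; a trailing partial
window is discarded, and windows with fewer than ``min_unambiguous_frac``
A/C/G/T bases are dropped so that N-rich stretches of draft assemblies
cannot distort the GC axis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ContigSeq

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "contig",
    "start",
    "end",
    "gc_percent",
    "gc_bin",
    "mean_depth",
    "n_unambiguous",
]

DEFAULT_WINDOW_WIDTH = 500
DEFAULT_MIN_UNAMBIGUOUS_FRAC = 0.9


def gc_bin_of(gc_percent: np.ndarray | float) -> np.ndarray | int:
    """Assign a GC percentage to its 1%-wide bin (round half up).

    Bins are centred on integers, so a 48.5% window lands in bin 49 and a
    49.0% window anchors the normalization bin exactly.
    """
    binned = np.floor(np.asarray(gc_percent, dtype=float) + 0.5).astype(int)
    if np.ndim(gc_percent) == 0:
        return int(binned)
    return binned


def window_gc(sequence: str, start: int, width: int) -> tuple[float, int]:
    """GC percentage and unambiguous-base count of one window.

    GC is computed over A/C/G/T bases only.  Returns ``(nan, 0)`` when the
    window contains no unambiguous bases.
    """
    if start < 0 or start + width > len(sequence):
        raise ValueError("window does not fit within the sequence")
    sub = sequence[start : start + width]
    gc = sub.count("G") + sub.count("C")
    at = sub.count("A") + sub.count("T")
    n_unambiguous = gc + at
    if n_unambiguous == 0:
        return float("nan"), 0
    return 100.0 * gc / n_unambiguous, n_unambiguous


def _sequence_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-base indicators: is G/C, is unambiguous (A/C/G/T)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    return is_gc, is_acgt


def _window_sums(values: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    csum = np.concatenate(([0], np.cumsum(values, dtype=np.float64)))
    return csum[starts + width] - csum[starts]


def make_windows(
    assembly: Sequence[ContigSeq],
    depth_tracks: Mapping[str, np.ndarray],
    width: int = DEFAULT_WINDOW_WIDTH,
    stride: int | None = None,
    min_unambiguous_frac: float = DEFAULT_MIN_UNAMBIGUOUS_FRAC,
) -> pd.DataFrame:
    """Tile every contig with fixed-width windows and summarise GC and depth.

    Parameters
    ----------
    assembly
        Contigs to window.  Every contig must have a depth track.
    depth_tracks
        Per-base read depth, one array per contig, index 0 = first base.
    width
        Window width in bases (default 500).
    stride
        Step between window starts; defaults to ``width`` (non-overlapping).
        ``stride=1`` gives the fully sliding per-base track.
    min_unambiguous_frac
        Windows whose unambiguous fraction falls below this are dropped.

    Returns
    -------
    pandas.DataFrame
        Columns ``contig, start, end, gc_percent, gc_bin, mean_depth,
        n_unambiguous``; ``attrs`` carry ``window_width`` and ``stride``.
        ``mean_depth`` averages per-base depth over the *full* window
        (including any N positions).
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if stride is None:
        stride = width
    if stride < 1:
        raise ValueError("stride must be >= 1")

    frames: list[pd.DataFrame] = []
    for contig in assembly:
        if contig.name not in depth_tracks:
            raise ValueError(f"no depth track for contig {contig.name!r}")
        depths = np.asarray(depth_tracks[contig.name])
        if len(depths) != contig.length:
            raise ValueError(
                f"depth track length {len(depths)} != contig length "
                f"{contig.length} for {contig.name!r}"
            )
        if width > contig.length:
            logger.info(
                "contig %s shorter than window width %d: no windows",
                contig.name,
                width,
            )
            continue
        starts = np.arange(0, contig.length - width + 1, stride, dtype=np.int64)
        is_gc, is_acgt = _sequence_arrays(contig.sequence)
        gc_counts = _window_sums(is_gc, starts, width)
        acgt_counts = _window_sums(is_acgt, starts, width)
        depth_sums = _window_sums(depths, starts, width)

        valid = acgt_counts / width >= min_unambiguous_frac
        valid &= acgt_counts > 0
        starts = starts[valid]
        gc_counts = gc_counts[valid]
        acgt_counts = acgt_counts[valid]
        depth_sums = depth_sums[valid]

        gc_percent = 100.0 * gc_counts / acgt_counts
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig.name,
                    "start": starts,
                    "end": starts + width,
                    "gc_percent": gc_percent,
                    "gc_bin": gc_bin_of(gc_percent),
                    "mean_depth": depth_sums / width,
                    "n_unambiguous": acgt_counts.astype(np.int64),
                }
            )
        )

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            WINDOW_COLUMNS,
            [str, np.int64, np.int64, float, np.int64, float, np.int64],
        )})
    table.attrs["window_width"] = width
    table.attrs["stride"] = stride
    return table


def per_base_track(
    assembly: Sequence[ContigSeq],
    depth_tracks: Mapping[str, np.ndarray],
    width: int = 50,
    min_unambiguous_frac: float = DEFAULT_MIN_UNAMBIGUOUS_FRAC,
) -> pd.DataFrame:
    """Fully sliding (stride 1) GC/coverage track for external plotting."""
    table = make_windows(
        assembly,
        depth_tracks,
        width=width,
        stride=1,
        min_unambiguous_frac=min_unambiguous_frac,
    )
    return table[["contig", "start", "gc_percent", "mean_depth"]].copy()


def per_base_track_export(
    assembly: Sequence[ContigSeq],
    depth_tracks: Mapping[str, np.ndarray],
    path: str | Path,
    width: int = 50,
) -> pd.DataFrame:
    track = per_base_track(assembly, depth_tracks, width=width)
    track.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return track


def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
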