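"""Length and robust-coverage filtering of contigs before genome-mode analysis.

Multicopy plasmids, prophages and collapsed repeats show depths far from the
rest of the assembly.  They are flagged with a modified z-score built on the
median absolute deviation (MAD), which tolerates the very outliers it is
hunting, and removed together with short contigs before any bias statistic
is computed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ContigSeq

logger = logging.getLogger(__name__)

#: Consistency constant making the MAD estimate the normal sigma.
MAD_CONSISTENCY = 0.6745
#: Consistency constant for the mean-absolute-deviation fallback.
MEAN_AD_CONSISTENCY = 1.253314

DEFAULT_MIN_CONTIG_LENGTH = 10_000
DEFAULT_Z_THRESHOLD = 10.0

REPORT_COLUMNS = ["contig", "length", "mean_depth", "modified_z", "action", "reason"]


def modified_zscores(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Modified z-scores: ``0.6745 * (x - median) / MAD``.

    When the MAD is zero (at least half the values identical) the score falls
    back to ``(x - median) / (1.253314 * meanAD)``; if the mean absolute
    deviation is also zero every score is 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("modified_zscores requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("modified_zscores requires finite values")
    med = np.median(x)
    abs_dev = np.abs(x - med)
    mad = np.median(abs_dev)
    if mad > 0:
        return MAD_CONSISTENCY * (x - med) / mad
    mean_ad = np.mean(abs_dev)
    if mean_ad > 0:
        return (x - med) / (MEAN_AD_CONSISTENCY * mean_ad)
    return np.zeros_like(x)


def filter_contigs(
    assembly: Sequence[ContigSeq],
    depth_tracks: Mapping[str, np.ndarray],
    min_length: int = DEFAULT_MIN_CONTIG_LENGTH,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    exclude: Sequence[str] = (),
) -> tuple[list[str], pd.DataFrame]:
    """Drop short, explicitly excluded, and aberrantly covered contigs.

    The filter runs in three passes: contigs shorter than *min_length* are
    discarded; contigs named in *exclude* are discarded (e.g. known plasmids
    whose stoichiometry with the chromosome is uncertain); then a two-sided
    modified z-score on the mean per-base depth of the survivors removes
    contigs with ``|z| > z_threshold``.

    Returns the retained contig names and a per-contig report with one row
    per input contig recording the action taken and why.
    """
    rows: list[dict] = []
    exclude_set = set(exclude)
    survivors: list[tuple[str, int, float]] = []
    for contig in assembly:
        if contig.name not in depth_tracks:
            raise ValueError(f"no depth track for contig {contig.name!r}")
        mean_depth = float(np.mean(depth_tracks[contig.name]))
        if contig.name in exclude_set:
            rows.append(
                dict(contig=contig.name, length=contig.length, mean_depth=mean_depth,
                     modified_z=np.nan, action="removed", reason="explicit exclude")
            )
        elif contig.length < min_length:
            rows.append(
                dict(contig=contig.name, length=contig.length, mean_depth=mean_depth,
                     modified_z=np.nan, action="removed",
                     reason=f"length < {min_length}")
            )
        else:
            survivors.append((contig.name, contig.length, mean_depth))

    if not survivors:
        raise ValueError(
            "no contigs survive length/exclude filtering; "
            f"min_length={min_length}, excluded={sorted(exclude_set)}"
        )

    scores = modified_zscores([depth for _, _, depth in survivors])
    retained: list[str] = []
    for (name, length, depth), z in zip(survivors, scores):
        if abs(z) > z_threshold:
            action, reason = "removed", f"|modified z| = {abs(z):.2f} > {z_threshold}"
        else:
            action, reason = "retained", ""
            retained.append(name)
        rows.append(
            dict(contig=name, length=length, mean_depth=depth,
                 modified_z=float(z), action=action, reason=reason)
        )

    if not retained:
        raise ValueError(
            "all contigs flagged as coverage outliers; inspect the filter report"
        )

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    n_removed = int((report["action"] == "removed").sum())
    logger.info(
        "contig filter: %d input, %d retained, %d removed",
        len(assembly), len(retained), n_removed,
    )
    return retained, report
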