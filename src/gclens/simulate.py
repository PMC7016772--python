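"""Synthetic assemblies, depth tracks, alignments and reads with a known,
injected GC bias.

The simulator is the ground truth for the whole package: it draws genomes
with a controlled GC landscape (including GC-poor chromosomes carrying a few
GC-balanced rRNA-like islands), places sequencing fragments with a
configurable GC-dependent relative efficiency, and emits FASTQ reads whose
Phred scores degrade above a GC threshold.  Because the injected bias
function is known exactly, every downstream statistic can be checked for
parameter recovery rather than merely for internal consistency.

Bias acts on the *fragment's* GC content, mimicking selection during
library preparation; window-level analyses then observe the smoothed
consequence of that per-fragment selection, just as they would on real data.

All randomness flows through :func:`numpy.random.default_rng` (PCG64), a
named, seedable generator, so identical specs and seeds give byte-identical
outputs on any platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ContigSeq, FeatureInterval

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 150

_BASES = np.frombuffer(b"GCAT", dtype="S1")


@dataclass(frozen=True)
class BiasModel:
    """GC-dependent relative sampling efficiency of sequencing fragments.

    ``log10_efficiency(g)`` is the log10 relative efficiency e(g) of a
    fragment with GC percent g; efficiencies are scaled so the optimum is 1
    (e = 0) and everything else lies in (0, 1].

    kind
        ``"none"`` (e = 0 everywhere), ``"quadratic"``
        (e(g) = a*g^2 + b*g + c with c fixed so max e over [0, 100] is 0) or
        ``"table"`` (explicit gc_bin -> efficiency map applied as a step
        function: a fragment uses the efficiency of the nearest listed bin).
    """

    kind: str = "none"
    a: float = 0.0
    b: float = 0.0
    table: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "quadratic", "table"):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "table":
            if not self.table:
                raise ValueError("table bias requires a gc_bin -> efficiency map")
            effs = np.asarray(list(self.table.values()), dtype=float)
            if np.any(effs <= 0) or np.any(effs > 1):
                raise ValueError("table efficiencies must lie in (0, 1]")

    @property
    def c(self) -> float:
        """Intercept fixing the quadratic's maximum over [0, 100] at 0."""
        if self.kind != "quadratic":
            return 0.0
        grid = np.array([0.0, 100.0])
        if self.a < 0:
            vertex = -self.b / (2.0 * self.a)
            if 0.0 <= vertex <= 100.0:
                grid = np.append(grid, vertex)
        return -float(np.max(self.a * grid**2 + self.b * grid))

    def log10_efficiency(self, gc_percent: np.ndarray | float) -> np.ndarray | float:
        g = np.asarray(gc_percent, dtype=float)
        if self.kind == "none":
            e = np.zeros_like(g)
        elif self.kind == "quadratic":
            e = self.a * g**2 + self.b * g + self.c
            e = np.minimum(e, 0.0)
        else:
            bins = np.array(sorted(self.table), dtype=float)
            log_eff = np.log10(np.array([self.table[int(k)] for k in bins]))
            nearest = np.clip(
                np.searchsorted(bins[:-1] + np.diff(bins) / 2.0, np.atleast_1d(g)),
                0,
                len(bins) - 1,
            )
            e = log_eff[nearest].reshape(np.shape(g))
        if np.ndim(gc_percent) == 0:
            return float(e)
        return e

    def ground_truth(self) -> dict:
        out: dict = {"kind": self.kind}
        if self.kind == "quadratic":
            out.update(a=self.a, b=self.b, c=self.c)
        elif self.kind == "table":
            out["table"] = {int(k): float(v) for k, v in self.table.items()}
        return out


@dataclass(frozen=True)
class IslandSpec:
    """An interval whose bases are redrawn at their own target GC — e.g. a
    GC-balanced rRNA-like island inside a GC-poor chromosome."""

    start: int
    end: int
    gc: float
    label: str = "island"


@dataclass(frozen=True)
class ContigSpec:
    name: str
    segments: tuple[tuple[float, int], ...]  # (target GC percent, length)
    islands: tuple[IslandSpec, ...] = ()

    @property
    def length(self) -> int:
        return sum(length for _, length in self.segments)


@dataclass(frozen=True)
class GenomeSpec:
    contigs: tuple[ContigSpec, ...]
    seed: int = 0

    def island_intervals(self) -> list[FeatureInterval]:
        return [
            FeatureInterval(c.name, isl.start, isl.end, isl.label)
            for c in self.contigs
            for isl in c.islands
        ]


@dataclass(frozen=True)
class QualityModel:
    """Phred-score model for simulated reads.

    Base quality is flat at ``base_phred`` for reads below
    ``degrade_above_gc`` percent GC and drops by ``degrade_slope`` Phred
    units per GC point above it; per-base Gaussian noise with sd
    ``noise_sd`` is added and scores are clipped to [2, 41].
    """

    base_phred: int = 38
    degrade_above_gc: float = 65.0
    degrade_slope: float = 5.0
    noise_sd: float = 3.0

    def phred_center(self, gc_percent: np.ndarray | float) -> np.ndarray | float:
        g = np.asarray(gc_percent, dtype=float)
        center = self.base_phred - self.degrade_slope * np.maximum(
            0.0, g - self.degrade_above_gc
        )
        if np.ndim(gc_percent) == 0:
            return float(center)
        return center


def _draw_bases(rng: np.random.Generator, length: int, gc_percent: float) -> np.ndarray:
    """i.i.d. bases with P(G or C) = gc/100, split evenly G/C and A/T."""
    p_gc = gc_percent / 100.0
    probs = [p_gc / 2.0, p_gc / 2.0, (1.0 - p_gc) / 2.0, (1.0 - p_gc) / 2.0]
    return rng.choice(_BASES, size=length, p=probs)


def simulate_genome(spec: GenomeSpec, seed: int | None = None) -> list[ContigSeq]:
    """Draw an assembly from a :class:`GenomeSpec`.

    Segment bases are i.i.d. at the segment's target GC; islands overwrite
    their intervals afterwards.  Overlapping islands on one contig are a
    hard error.  Deterministic given the seed (``spec.seed`` by default).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    contigs: list[ContigSeq] = []
    for cspec in spec.contigs:
        pieces = [
            _draw_bases(rng, length, gc) for gc, length in cspec.segments
        ]
        arr = np.concatenate(pieces) if pieces else np.array([], dtype="S1")
        last_end = -1
        for isl in sorted(cspec.islands, key=lambda i: i.start):
            if isl.start < last_end:
                raise ValueError(f"overlapping islands on contig {cspec.name!r}")
            if isl.end > len(arr):
                raise ValueError(
                    f"island {isl.start}-{isl.end} exceeds contig {cspec.name!r}"
                )
            arr[isl.start : isl.end] = _draw_bases(rng, isl.end - isl.start, isl.gc)
            last_end = isl.end
        contigs.append(ContigSeq(cspec.name, arr.tobytes().decode("ascii")))
    return contigs


def _fragment_gc(sequence: str, read_length: int) -> np.ndarray:
    """GC percent of every fragment start position (stride 1)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.float64)
    is_acgt = is_gc + ((arr == ord("A")) | (arr == ord("T"))).astype(np.float64)
    cg = np.concatenate(([0.0], np.cumsum(is_gc)))
    ca = np.concatenate(([0.0], np.cumsum(is_acgt)))
    starts = np.arange(len(arr) - read_length + 1)
    gc_counts = cg[starts + read_length] - cg[starts]
    acgt_counts = ca[starts + read_length] - ca[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(acgt_counts > 0, 100.0 * gc_counts / acgt_counts, np.nan)


def sample_fragments(
    assembly: Sequence[ContigSeq],
    bias_model: BiasModel,
    n_fragments: int,
    read_length: int = DEFAULT_READ_LENGTH,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Sample fragment start positions with probability proportional to
    ``10^e(fragment GC)``.  Returns sorted start arrays per contig.

    Contigs shorter than *read_length* are skipped with a warning.  Fragments
    whose window is entirely ambiguous get the mean weight.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    usable = [c for c in assembly if c.length >= read_length]
    for c in assembly:
        if c.length < read_length:
            logger.warning(
                "contig %s shorter than read length %d: skipped", c.name, read_length
            )
    if not usable:
        raise ValueError("no contig is at least one read length long")

    weights: list[np.ndarray] = []
    offsets: list[int] = [0]
    for contig in usable:
        gc = _fragment_gc(contig.sequence, read_length)
        w = np.power(10.0, bias_model.log10_efficiency(np.nan_to_num(gc, nan=50.0)))
        weights.append(w)
        offsets.append(offsets[-1] + len(w))
    all_weights = np.concatenate(weights)
    p = all_weights / all_weights.sum()
    draws = rng.choice(len(all_weights), size=n_fragments, replace=True, p=p)

    fragments: dict[str, np.ndarray] = {}
    for i, contig in enumerate(usable):
        mask = (draws >= offsets[i]) & (draws < offsets[i + 1])
        fragments[contig.name] = np.sort(draws[mask] - offsets[i])
    return fragments


def expected_fragment_count(
    assembly: Sequence[ContigSeq],
    mean_depth: float,
    read_length: int = DEFAULT_READ_LENGTH,
) -> int:
    """Fragment count whose unbiased expectation of depth is *mean_depth*."""
    total = sum(c.length for c in assembly if c.length >= read_length)
    return int(round(mean_depth * total / read_length))


def depth_from_fragments(
    assembly: Sequence[ContigSeq],
    fragments: Mapping[str, np.ndarray],
    read_length: int = DEFAULT_READ_LENGTH,
) -> dict[str, np.ndarray]:
    """Accumulate per-base depth from fragment start positions."""
    tracks: dict[str, np.ndarray] = {}
    for contig in assembly:
        diff = np.zeros(contig.length + 1, dtype=np.int64)
        starts = fragments.get(contig.name)
        if starts is not None and len(starts):
            np.add.at(diff, starts, 1)
            np.add.at(diff, starts + read_length, -1)
        tracks[contig.name] = np.cumsum(diff[:-1])
    return tracks


def simulate_depth(
    assembly: Sequence[ContigSeq],
    bias_model: BiasModel,
    mean_depth: float,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    return_fragments: bool = False,
):
    """Simulate a per-base depth track under the given GC bias.

    The number of fragments is fixed so that, absent bias, expected depth
    equals *mean_depth*; multinomial placement then yields Poisson-like
    per-window noise.  With ``return_fragments=True`` the sampled start
    positions are returned as well (for alignment or FASTQ emission).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    n = expected_fragment_count(assembly, mean_depth, read_length)
    fragments = sample_fragments(assembly, bias_model, n, read_length, rng=rng)
    tracks = depth_from_fragments(assembly, fragments, read_length)
    if return_fragments:
        return tracks, fragments
    return tracks


def fragments_to_alignments(
    assembly: Sequence[ContigSeq],
    fragments: Mapping[str, np.ndarray],
    path: str | Path,
    read_length: int = DEFAULT_READ_LENGTH,
) -> None:
    """Write fragments as a coordinate-sorted, indexed BAM (or plain SAM).

    Each fragment becomes one forward-strand, ungapped primary alignment
    with MAPQ 60.  A ``.sam`` suffix writes SAM text without an index.
    """
    import pysam

    path = Path(path)
    seqs = {c.name: c.sequence for c in assembly}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in assembly],
    }
    mode = "w" if path.suffix == ".sam" else "wb"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for tid, contig in enumerate(assembly):
            starts = fragments.get(contig.name)
            if starts is None:
                continue
            for k, start in enumerate(starts.tolist()):
                a = pysam.AlignedSegment()
                a.query_name = f"{contig.name}_frag{k}"
                a.query_sequence = seqs[contig.name][start : start + read_length]
                a.flag = 0
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{read_length}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                out.write(a)
    if mode == "wb":
        pysam.index(str(path))


def simulate_fastq(
    assembly: Sequence[ContigSeq],
    bias_model: BiasModel,
    quality_model: QualityModel,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
) -> list[tuple[str, str, np.ndarray]]:
    """Simulate reads with GC-biased sampling and GC-dependent qualities.

    Returns (name, sequence, Phred array) triples ready for
    :func:`gclens.io_formats.write_fastq`.  Deterministic given the seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    fragments = sample_fragments(
        assembly, bias_model, n_reads, read_length, rng=rng
    )
    seqs = {c.name: c.sequence for c in assembly}
    reads: list[tuple[str, str, np.ndarray]] = []
    for contig_name in sorted(fragments):
        starts = fragments[contig_name]
        for k, start in enumerate(starts.tolist()):
            seq = seqs[contig_name][start : start + read_length]
            gc = seq.count("G") + seq.count("C")
            at = seq.count("A") + seq.count("T")
            gc_percent = 100.0 * gc / (gc + at) if gc + at else 50.0
            center = quality_model.phred_center(gc_percent)
            quals = np.clip(
                np.rint(rng.normal(center, quality_model.noise_sd, size=len(seq))),
                2,
                41,
            ).astype(np.int64)
            reads.append((f"{contig_name}_read{k}", seq, quals))
    return reads


# ---------------------------------------------------------------------------
# Canned genome shapes used throughout the documentation and test suite.


def gc_poor_genome_with_islands(
    length: int = 2_000_000,
    background_gc: float = 29.0,
    n_islands: int = 9,
    island_length: int = 5_000,
    island_gc: float = 55.0,
    seed: int = 0,
) -> GenomeSpec:
    """A GC-poor chromosome carrying evenly spaced GC-balanced islands.

    Emulates the structure of a GC-poor bacterial chromosome whose rRNA
    loci sit at balanced GC: the sentinel case where GC bias turns into
    dramatic relative over-coverage of the islands.
    """
    spacing = length // (n_islands + 1)
    islands = tuple(
        IslandSpec(
            start=(i + 1) * spacing,
            end=(i + 1) * spacing + island_length,
            gc=island_gc,
            label=f"island_{i + 1}",
        )
        for i in range(n_islands)
    )
    contig = ContigSpec(
        name="chr1", segments=((background_gc, length),), islands=islands
    )
    return GenomeSpec(contigs=(contig,), seed=seed)


def gc_gradient_genome(
    length: int = 2_000_000,
    gc_min: float = 30.0,
    gc_max: float = 70.0,
    n_segments: int = 40,
    seed: int = 0,
    name: str = "chr1",
) -> GenomeSpec:
    """A chromosome whose segments sweep a GC range, populating many bins.

    The workhorse for bias-curve fitting: every 1% GC bin between roughly
    *gc_min* and *gc_max* receives windows, so a quadratic bias curve is
    identifiable.
    """
    seg_len = length // n_segments
    gcs = np.linspace(gc_min, gc_max, n_segments)
    segments = tuple((float(g), seg_len) for g in gcs)
    return GenomeSpec(contigs=(ContigSpec(name=name, segments=segments),), seed=seed)


def metagenome_spec(
    n_contigs: int = 60,
    contig_length: int = 30_000,
    gc_min: float = 25.0,
    gc_max: float = 75.0,
    within_contig_spread: float = 4.0,
    seed: int = 0,
) -> GenomeSpec:
    """A mock metagenome: contigs of spread-out mean GC, each with internal
    GC structure so that several 1% bins are populated per contig."""
    gcs = np.linspace(gc_min, gc_max, n_contigs)
    contigs = []
    third = contig_length // 3
    for i, g in enumerate(gcs):
        lo = float(np.clip(g - within_contig_spread, 0.0, 100.0))
        hi = float(np.clip(g + within_contig_spread, 0.0, 100.0))
        segments = (
            (lo, third),
            (float(g), third),
            (hi, contig_length - 2 * third),
        )
        contigs.append(ContigSpec(name=f"contig_{i + 1:03d}", segments=segments))
    return GenomeSpec(contigs=tuple(contigs), seed=seed)
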