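"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based, half-open.  Formats that use 1-based
coordinates (the per-base depth TSV emitted by standard depth tools) are
converted at this boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

SECONDARY_OR_SUPPLEMENTARY = 0x900  # flag mask excluded from depth counting


@dataclass(frozen=True)
class ContigSeq:
    """A single assembly contig: uppercase sequence over {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureInterval:
    """A labelled genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    label: str = "feature"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )


def _clean_sequence(name: str, raw: str) -> str:
    seq = raw.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    bad = ~np.isin(arr, [b"A", b"C", b"G", b"T", b"N"])
    n_bad = int(bad.sum())
    logger.warning(
        "contig %s: %d non-ACGTN characters replaced with N", name, n_bad
    )
    arr = arr.copy()
    arr[bad] = b"N"
    return arr.tobytes().decode("ascii")


def read_fasta(path: str | Path) -> list[ContigSeq]:
    """Read an assembly FASTA into a list of :class:`ContigSeq`.

    Lowercase bases are uppercased; IUPAC ambiguity codes (and any other
    non-ACGTN character) collapse to ``N`` with a logged warning.  Duplicate
    contig names and empty files are hard errors.
    """
    contigs: list[ContigSeq] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate contig name {record.id!r} in {path}")
        seen.add(record.id)
        contigs.append(ContigSeq(record.id, _clean_sequence(record.id, str(record.seq))))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def write_fasta(contigs: Iterable[ContigSeq], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in contigs]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def contig_lengths(contigs: Sequence[ContigSeq]) -> dict[str, int]:
    return {c.name: c.length for c in contigs}


def read_depth_tsv(
    path: str | Path, assembly: Sequence[ContigSeq]
) -> dict[str, np.ndarray]:
    """Parse a 3-column per-base depth table (contig, 1-based position, depth).

    This is the all-positions dialect written by ``samtools depth -a``;
    positions (or whole contigs) absent from the file are filled with depth 0,
    so every contig in *assembly* yields a track of exactly its length.
    """
    lengths = contig_lengths(assembly)
    tracks = {name: np.zeros(length, dtype=np.int64) for name, length in lengths.items()}
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": np.int64, "depth": np.int64},
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed depth TSV {path}: {exc}") from exc
    if table.empty:
        return tracks
    for name, group in table.groupby("contig", sort=False):
        if name not in lengths:
            raise ValueError(f"depth TSV contig {name!r} not present in assembly")
        pos = group["pos"].to_numpy()
        if pos.min() < 1 or pos.max() > lengths[name]:
            raise ValueError(
                f"depth TSV position out of range for contig {name!r} "
                f"(length {lengths[name]})"
            )
        depth = group["depth"].to_numpy()
        if (depth < 0).any():
            raise ValueError(f"negative depth for contig {name!r}")
        tracks[name][pos - 1] = depth
    return tracks


def write_depth_tsv(tracks: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base depths in the all-positions 1-based dialect."""
    with open(path, "w") as handle:
        for name in tracks:
            depths = np.asarray(tracks[name])
            lines = "\n".join(
                f"{name}\t{i + 1}\t{d}" for i, d in enumerate(depths.tolist())
            )
            handle.write(lines + "\n")


def depth_from_alignments(
    bam_path: str | Path, assembly: Sequence[ContigSeq]
) -> dict[str, np.ndarray]:
    """Per-base depth from a BAM/SAM file, counting primary alignments only.

    Records with the secondary (0x100) or supplementary (0x800) flag bit set
    are skipped, as are unmapped records.  Reference positions spanned by a
    deletion in the read do not gain depth.
    """
    lengths = contig_lengths(assembly)
    tracks = {name: np.zeros(length, dtype=np.int64) for name, length in lengths.items()}
    with pysam.AlignmentFile(str(bam_path)) as handle:
        for read in handle.fetch(until_eof=True):
            if read.is_unmapped or (read.flag & SECONDARY_OR_SUPPLEMENTARY):
                continue
            name = read.reference_name
            if name not in tracks:
                raise ValueError(
                    f"alignment contig {name!r} not present in assembly"
                )
            positions = read.get_reference_positions()  # excludes deletions
            if positions:
                np.add.at(tracks[name], np.asarray(positions, dtype=np.int64), 1)
    return tracks


def read_fastq(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read 4-line FASTQ records into (sequence, Phred score array) pairs.

    Qualities are decoded from Phred+33.  Truncated records or mismatched
    sequence/quality lengths raise a :class:`ValueError`.
    """
    reads: list[tuple[str, np.ndarray]] = []
    try:
        for record in SeqIO.parse(str(path), "fastq"):
            quals = np.asarray(record.letter_annotations["phred_quality"], dtype=np.int64)
            reads.append((str(record.seq).upper(), quals))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc
    if not reads:
        raise ValueError(f"no FASTQ records found in {path}")
    return reads


def write_fastq(
    reads: Iterable[tuple[str, str, np.ndarray]], path: str | Path
) -> None:
    """Write (name, sequence, Phred array) triples as Phred+33 FASTQ."""
    with open(path, "w") as handle:
        for name, seq, quals in reads:
            quals = np.asarray(quals)
            if len(seq) != len(quals):
                raise ValueError(f"read {name!r}: sequence/quality length mismatch")
            qstring = "".join(chr(int(q) + 33) for q in quals)
            handle.write(f"@{name}\n{seq}\n+\n{qstring}\n")


def read_bed(path: str | Path) -> list[FeatureInterval]:
    """Read 3+1-column BED intervals (contig, start, end[, label])."""
    intervals: list[FeatureInterval] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >=3 BED columns")
            label = fields[3] if len(fields) > 3 else "feature"
            intervals.append(
                FeatureInterval(fields[0], int(fields[1]), int(fields[2]), label)
            )
    return intervals


def write_bed(intervals: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\n")
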