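"""Gene annotations and coverage tracks.

Coordinates are 0-based half-open everywhere in memory (BED convention on
disk; GTF's 1-based closed intervals are converted on read).  A
:class:`CoverageTrack` is a sorted list of non-overlapping scored intervals,
the in-memory form of a bedGraph; positions not covered by any interval count
as zero coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "CoverageTrack",
    "read_bed",
    "write_bed",
    "read_gtf",
    "read_bedgraph",
    "write_bedgraph",
    "read_bigwig",
]


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene interval with strand (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start position (right edge for reverse strand)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start


class CoverageTrack:
    """Piecewise-constant coverage on one chromosome.

    Parameters are parallel arrays of interval starts, ends (bp, half-open)
    and values.  Intervals must be sorted and non-overlapping; gaps read as
    zero coverage.
    """

    def __init__(self, chrom: str, starts, ends, values) -> None:
        self.chrom = chrom
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.values = np.asarray(values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts/ends/values must have equal length")
        if (self.ends <= self.starts).any():
            raise ValueError("intervals must have positive length")
        if (np.diff(self.starts) < 0).any() or (self.starts[1:] < self.ends[:-1]).any():
            raise ValueError("intervals must be sorted and non-overlapping")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __eq__(self, other) -> bool:  # exact round-trip equality
        return (
            isinstance(other, CoverageTrack)
            and self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
            and np.array_equal(self.values, other.values)
        )

    def mean(self, start: int, end: int) -> float:
        """Base-pair-weighted mean coverage over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        lo = np.maximum(self.starts, start)
        hi = np.minimum(self.ends, end)
        w = np.clip(hi - lo, 0, None)
        return float((w * self.values).sum() / (end - start))

    def binned(self, start: int, end: int, n_bins: int) -> np.ndarray:
        """Base-pair-weighted mean coverage in ``n_bins`` equal bins of [start, end).

        Bin edges may fall at fractional base pairs (e.g. a 3l domain split in
        60); overlaps are weighted by exact fractional length.
        """
        edges = np.linspace(start, end, n_bins + 1)
        out = np.zeros(n_bins)
        for s, e, v in zip(self.starts, self.ends, self.values):
            if e <= edges[0] or s >= edges[-1]:
                continue
            lo = np.maximum(edges[:-1], s)
            hi = np.minimum(edges[1:], e)
            out += np.clip(hi - lo, 0, None) * v
        return out / np.diff(edges)


# -- file formats ------------------------------------------------------------

def read_bed(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "id", "score", "strand"],
                     usecols=range(6))
    return [
        GeneRecord(chrom=r.chrom, start=int(r.start), end=int(r.end),
                   strand=str(r.strand), id=str(r.id))
        for r in df.itertuples()
    ]


def write_bed(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


def read_gtf(path: str | Path, feature: str = "gene") -> list[GeneRecord]:
    """Read gene records from a GTF file (1-based closed -> 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "feature", "start", "end",
                            "score", "strand", "frame", "attributes"])
    df = df[df.feature == feature]
    genes = []
    for r in df.itertuples():
        attrs = dict(
            kv.strip().split(" ", 1)
            for kv in str(r.attributes).rstrip(";").split(";")
            if kv.strip()
        )
        gid = attrs.get("gene_id", f"{r.chrom}:{r.start}").strip('"')
        genes.append(GeneRecord(chrom=r.chrom, start=int(r.start) - 1,
                                end=int(r.end), strand=str(r.strand), id=gid))
    return genes


def read_bedgraph(path: str | Path, chrom: str | None = None) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if chrom is None:
        chroms = df.chrom.unique()
        if len(chroms) != 1:
            raise ValueError("multiple chromosomes present; pass chrom=")
        chrom = chroms[0]
    df = df[df.chrom == chrom].sort_values("start")
    return CoverageTrack(chrom, df.start.to_numpy(), df.end.to_numpy(),
                         df.value.to_numpy())


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.17g}\n")


def read_bigwig(path: str | Path, chrom: str) -> CoverageTrack:
    """Optional bigWig reader (requires pyBigWig)."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading bigWig files requires pyBigWig") from exc
    bw = pyBigWig.open(str(path))
    try:
        ivals = bw.intervals(chrom) or []
    finally:
        bw.close()
    starts = [i[0] for i in ivals]
    ends = [i[1] for i in ivals]
    vals = [i[2] for i in ivals]
    return CoverageTrack(chrom, starts, ends, vals)
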