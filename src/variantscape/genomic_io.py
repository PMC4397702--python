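"""Genomic interval / signal containers and the plain-text formats they use.

Coordinates are 0-based half-open (BED convention) everywhere. Signal lives in
fixed-width bins as a piecewise-constant level per bin; bedGraph records are
averaged into bins on read, so a read/write round trip at the native bin width
is lossless. All readers are gzip-transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GenomicInterval", "GeneModel", "SignalTrack",
    "read_bed", "write_bed", "read_genes", "write_genes",
    "read_bedgraph", "write_bedgraph", "rpkm_normalize",
]

STRANDS = (".", "+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware 5'/3' ends."""

    interval: GenomicInterval
    biotype: str = "mRNA"  # mRNA | lncRNA

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tts(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3-BED6; missing fields take their defaults."""
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                out.append(GenomicInterval(
                    f[0], int(f[1]), int(f[2]),
                    f[3] if len(f) > 3 else ".",
                    float(f[4]) if len(f) > 4 else 0.0,
                    f[5] if len(f) > 5 else "."))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
    return out


def write_bed(intervals, path) -> None:
    with _open(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                     f"{iv.score:g}\t{iv.strand}\n")


def read_genes(path) -> list[GeneModel]:
    """Read the 4/6-column gene table: chrom, start, end, strand[, name, biotype]."""
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]),
                                     f[4] if len(f) > 4 else ".",
                                     strand=f[3])
                out.append(GeneModel(iv, f[5] if len(f) > 5 else "mRNA"))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed gene line {lineno}: {exc}") from exc
    return out


def write_genes(genes, path) -> None:
    with _open(path, "wt") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                     f"{iv.name}\t{g.biotype}\n")


@dataclass
class SignalTrack:
    """Binned coverage: per-chromosome arrays of one value per ``bin_width`` bp."""

    values: dict[str, np.ndarray]
    bin_width: int
    library_size: float | None = None
    strand: str | None = None
    normalized: bool = False

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of bin values fully or partly inside [start, end), pro-rated."""
        arr = self.values[chrom]
        b = self.bin_width
        lo, hi = max(start, 0), min(end, len(arr) * b)
        if lo >= hi:
            return 0.0
        first, last = lo // b, (hi - 1) // b
        s = float(arr[first:last + 1].sum())
        s -= arr[first] * (lo - first * b) / b
        s -= arr[last] * ((last + 1) * b - hi) / b
        return s


def read_bedgraph(path, bin_width: int, chrom_sizes: dict[str, int] | None = None,
                  library_size: float | None = None, strand: str | None = None
                  ) -> SignalTrack:
    """Read a bedGraph into bins, averaging each record's value over the bins
    it covers (a record spanning whole bins contributes its value to each).

    Overlapping records are rejected; values must be a single level per bp.
    """
    recs: dict[str, list[tuple[int, int, float]]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}: {exc}"
                                 ) from exc
            recs.setdefault(chrom, []).append((start, end, value))
    values: dict[str, np.ndarray] = {}
    for chrom, rows in recs.items():
        rows.sort()
        for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping bedGraph records on {chrom} "
                                 f"at {s2} < {e1}")
        size = (chrom_sizes or {}).get(chrom, rows[-1][1])
        nbins = -(-size // bin_width)
        arr = np.zeros(nbins)
        for start, end, value in rows:
            first, last = start // bin_width, (end - 1) // bin_width
            for b in range(first, last + 1):
                lo = max(start, b * bin_width)
                hi = min(end, (b + 1) * bin_width)
                arr[b] += value * (hi - lo) / bin_width
        values[chrom] = arr
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            values.setdefault(chrom, np.zeros(-(-size // bin_width)))
    return SignalTrack(values, bin_width, library_size=library_size, strand=strand)


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write bins as bedGraph, merging runs of equal values; zero runs omitted."""
    b = track.bin_width
    with _open(path, "wt") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            run_start, run_val = 0, arr[0] if len(arr) else 0.0
            for i in range(1, len(arr) + 1):
                v = arr[i] if i < len(arr) else None
                if v != run_val:
                    if run_val != 0.0:
                        fh.write(f"{chrom}\t{run_start * b}\t{i * b}\t{run_val:g}\n")
                    run_start, run_val = i, v


def rpkm_normalize(track: SignalTrack, scale: float = 1.0) -> SignalTrack:
    """Reads-per-kilobase-per-million normalization of binned counts:

        value = count * 1e9 / (bin_width * library_size) * scale

    ``library_size`` defaults to the track's total count. ``scale`` is a global
    display constant (every downstream statistic here is invariant to it).
    Normalizing twice is an error.
    """
    if track.normalized:
        raise ValueError("track is already normalized")
    library = track.library_size if track.library_size else track.total()
    if library <= 0:
        raise ValueError("library size must be positive")
    factor = 1e9 / (track.bin_width * library) * scale
    values = {c: v * factor for c, v in track.values.items()}
    return replace(track, values=values, library_size=library, normalized=True)
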