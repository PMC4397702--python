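"""Promoter-distal anchor selection and anchor/gene-centered profile matrices.

Anchors are open-chromatin intervals (DHS-like); the distal filter keeps those
whose center is more than ``min_dist`` bp from every annotated TSS and TTS and
whose interval overlaps no gene body (mRNA or lncRNA), the universe on which
all clustering and enrichment statistics downstream operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomic_io import GeneModel, GenomicInterval, SignalTrack

log = logging.getLogger(__name__)

__all__ = ["AnchorSet", "ProfileMatrix", "filter_distal", "profile_matrix",
           "stack_profiles", "meta_gene_profiles"]


@dataclass
class AnchorSet:
    anchors: list[GenomicInterval]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def centers(self) -> np.ndarray:
        return np.array([a.center for a in self.anchors])


def filter_distal(dhs: list[GenomicInterval], genes: list[GeneModel],
                  min_dist: int = 2000) -> AnchorSet:
    """Keep DHSs distal (> min_dist bp) to every TSS and TTS and outside all
    gene bodies (any-bp overlap with a body excludes)."""
    ends_by_chrom: dict[str, list[int]] = {}
    bodies: dict[str, IntervalTree] = {}
    for g in genes:
        iv = g.interval
        ends_by_chrom.setdefault(iv.chrom, []).extend((g.tss, g.tts))
        bodies.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    ends = {c: np.sort(np.array(v)) for c, v in ends_by_chrom.items()}

    kept = []
    for a in dhs:
        c = a.center
        pts = ends.get(a.chrom)
        if pts is not None and len(pts):
            i = np.searchsorted(pts, c)
            near = min((abs(c - pts[j]) for j in (i - 1, i) if 0 <= j < len(pts)))
            if near <= min_dist:
                continue
        tree = bodies.get(a.chrom)
        if tree is not None and tree.overlap(a.start, a.end):
            continue
        kept.append(a)
    if not kept:
        log.warning("distal filter retained no anchors")
    log.info("distal filter: %d of %d anchors retained", len(kept), len(dhs))
    return AnchorSet(kept, {"min_dist": min_dist, "n_input": len(dhs),
                            "n_retained": len(kept)})


@dataclass
class ProfileMatrix:
    """anchors x bins signal per track around anchor centers.

    ``data[track]`` has shape (n_anchors, 2W/b); bin j covers
    [center - W + j*b, center - W + (j+1)*b). Rows are stored unoriented;
    orientation is applied downstream.
    """

    data: dict[str, np.ndarray]
    anchors: list[GenomicInterval]
    window: int
    bin_width: int
    track_names: list[str]

    @property
    def n_bins(self) -> int:
        return 2 * self.window // self.bin_width

    def concat(self) -> np.ndarray:
        """(n_anchors, n_tracks * n_bins) row-wise concatenation in track order."""
        return np.hstack([self.data[t] for t in self.track_names])


def _rows_for_centers(track: SignalTrack, chroms, centers, W: int, b: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Profile rows for (chrom, center) anchor points; returns (rows, kept mask).

    Centers off the bin grid are handled by linear weighting of the two
    overlapping bin slices (exact mean under piecewise-constant signal).
    """
    if W % b:
        raise ValueError("window must be a multiple of the bin width")
    half = W // b
    n = 2 * half
    rows = np.zeros((len(centers), n))
    kept = np.zeros(len(centers), bool)
    for i, (chrom, c) in enumerate(zip(chroms, centers)):
        arr = track.values.get(chrom)
        if arr is None:
            continue
        cbin, shift = divmod(int(c), b)
        a0 = cbin - half
        if shift == 0:
            if a0 < 0 or a0 + n > len(arr):
                continue
            rows[i] = arr[a0:a0 + n]
        else:
            if a0 < 0 or a0 + n + 1 > len(arr):
                continue
            w = shift / b
            rows[i] = (1 - w) * arr[a0:a0 + n] + w * arr[a0 + 1:a0 + n + 1]
        kept[i] = True
    return rows, kept


def profile_matrix(track: SignalTrack, anchors: AnchorSet, W: int = 2000,
                   b: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Single-track profile rows for all anchors; returns (rows, kept mask).
    Anchors whose window leaves the chromosome are dropped (mask False)."""
    chroms = [a.chrom for a in anchors.anchors]
    return _rows_for_centers(track, chroms, anchors.centers, W, b)


def stack_profiles(tracks: dict[str, SignalTrack], anchors: AnchorSet,
                   W: int = 2000, b: int = 100) -> ProfileMatrix:
    """Multi-track ProfileMatrix over the anchors retained by *every* track."""
    per_track = {}
    kept_all = np.ones(len(anchors), bool)
    for name, tr in tracks.items():
        rows, kept = profile_matrix(tr, anchors, W, b)
        per_track[name] = rows
        kept_all &= kept
    dropped = int((~kept_all).sum())
    if dropped:
        log.info("stack_profiles: dropped %d anchors at chromosome edges", dropped)
    kept_anchors = [a for a, k in zip(anchors.anchors, kept_all) if k]
    data = {name: rows[kept_all] for name, rows in per_track.items()}
    return ProfileMatrix(data, kept_anchors, W, b, list(tracks))


def meta_gene_profiles(tracks: dict[str, SignalTrack], genes: list[GeneModel],
                       expression: dict[str, float], W_tss: int = 2000,
                       W_tts: int = 500, b: int = 100, n_quantiles: int = 5
                       ) -> pd.DataFrame:
    """Average TSS/TTS profiles per expression quantile per track.

    Genes are split into ``n_quantiles`` equal-size groups by expression rank
    (quantile 1 = lowest). Minus-strand profiles are reversed so bin order runs
    5'->3'. Genes without an expression value are excluded (count logged).
    Returns a tidy frame (track, site, quantile, bin, value).
    """
    named = [g for g in genes if g.interval.name in expression]
    skipped = len(genes) - len(named)
    if skipped:
        log.info("meta_gene_profiles: %d genes without expression excluded", skipped)
    if not named:
        raise ValueError("no genes with expression values")
    expr = np.array([expression[g.interval.name] for g in named])
    ranks = pd.Series(expr).rank(method="first")
    quantile = pd.qcut(ranks, n_quantiles, labels=False).to_numpy() + 1

    chroms = [g.interval.chrom for g in named]
    minus = np.array([g.interval.strand == "-" for g in named])
    rows_out = []
    for site, W in (("tss", W_tss), ("tts", W_tts)):
        centers = np.array([getattr(g, site) for g in named])
        for track_name, tr in tracks.items():
            rows, kept = _rows_for_centers(tr, chroms, centers, W, b)
            rows[minus] = rows[minus, ::-1]
            for q in range(1, n_quantiles + 1):
                sel = kept & (quantile == q)
                if not sel.any():
                    continue
                mean = rows[sel].mean(axis=0)
                for j, v in enumerate(mean):
                    rows_out.append((track_name, site, q, j, v))
    return pd.DataFrame(rows_out, columns=["track", "site", "quantile", "bin",
                                           "value"])
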