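"""Hypergeometric enrichment of TF peak sets within anchor clusters.

An anchor "overlaps" a TF iff any peak intersects the window
[center - flank, center + flank) (half-open). With N total anchors, K_pop of
them overlapping, and k of a cluster's n anchors overlapping, the enrichment
p-value is the upper hypergeometric tail P(X >= k); Benjamini-Hochberg
q-values are reported alongside for multiplicity across all (TF, cluster)
rows, raw p being what the original criterion used.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .anchors_profiles import AnchorSet
from .genomic_io import GenomicInterval

log = logging.getLogger(__name__)

__all__ = ["overlap_counts", "hypergeom_pvalue", "bh_adjust", "enrichment_table"]


def overlap_counts(anchors: AnchorSet, peaks: list[GenomicInterval],
                   flank: int = 500) -> np.ndarray:
    """Boolean per anchor: does any peak intersect [center - flank, center + flank)?"""
    starts = [(p.chrom, p.start) for p in peaks]
    if starts != sorted(starts):
        log.info("overlap_counts: peak input unsorted; sorting internally")
        peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    hit = np.zeros(len(anchors), bool)
    for i, a in enumerate(anchors.anchors):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        c = a.center
        lo = max(c - flank, 0)
        if lo < c + flank and tree.overlap(lo, c + flank):
            hit[i] = True
    return hit


def hypergeom_pvalue(N: int, K_pop: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for k overlaps among n cluster
    anchors drawn from N anchors of which K_pop overlap."""
    if not (0 <= K_pop <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent population counts N={N}, K={K_pop}, n={n}")
    if not (max(0, n + K_pop - N) <= k <= min(n, K_pop)):
        raise ValueError(f"impossible overlap count k={k} for N={N}, "
                         f"K={K_pop}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K_pop, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def enrichment_table(anchors: AnchorSet, finals: np.ndarray,
                     tf_peaks: dict[str, list[GenomicInterval]],
                     flank: int = 500) -> pd.DataFrame:
    """Per (TF, cluster) hypergeometric enrichment over the distal-anchor
    universe. Columns: tf, cluster, N, K_pop, n, k, fold, p, q."""
    if len(anchors) != len(finals):
        raise ValueError("anchors and cluster labels differ in length")
    N = len(anchors)
    rows = []
    for tf, peaks in sorted(tf_peaks.items()):
        hit = overlap_counts(anchors, peaks, flank)
        K_pop = int(hit.sum())
        for fid in sorted(set(finals)):
            sel = finals == fid
            n, k = int(sel.sum()), int(hit[sel].sum())
            fold = (k / n) / (K_pop / N) if K_pop and n else float("nan")
            p = hypergeom_pvalue(N, K_pop, n, k) if K_pop else 1.0
            rows.append((tf, fid, N, K_pop, n, k, fold, p))
    table = pd.DataFrame(rows, columns=["tf", "cluster", "N", "K_pop", "n", "k",
                                        "fold", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table
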