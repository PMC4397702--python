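"""PolII skew, stranded eRNA bias, and between-cluster eRNA comparisons.

Once anchors carry an orientation (from mirror-paired histone-variant
clusters), two concordance questions follow: does PolII occupancy skew the
same way, and does nascent bidirectional transcription (eRNA, from stranded
GRO-seq-type signal) lean toward that orientation? Per-anchor statistics:

* PolII asymmetry A on orientation-aligned profile rows (left-oriented rows
  bin-reversed first), so A > 0 means "skewed toward the variant orientation".
* strand bias B = (P - M)/(P + M + eps) over the anchor window, sign flipped
  for left-oriented anchors so B > 0 likewise means "toward orientation".

Cluster-level eRNA totals (P + M) are compared with a one-sided Mann-Whitney
U test: exact null distribution for small samples without ties, normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anchors_profiles import AnchorSet, ProfileMatrix
from .clustering import ClusterResult, asymmetry_score, oriented_rows
from .genomic_io import SignalTrack

__all__ = ["DirectionalityReport", "ComparisonResult", "polii_skew",
           "strand_bias", "compare_cluster_signal"]

EPS = 1e-12


@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    method: str
    alternative: str
    tie_warning: bool = False


@dataclass
class DirectionalityReport:
    cluster_skew: pd.DataFrame           # per final cluster: mean PolII A, n
    concordance: float                   # asymmetric anchors with A_polII > 0
    per_anchor_polii_A: np.ndarray
    strand_bias: pd.DataFrame | None = None   # per cluster: mean B, CI
    per_anchor_B: np.ndarray | None = None
    comparisons: list[ComparisonResult] = field(default_factory=list)


def polii_skew(polii_rows: np.ndarray | ProfileMatrix, oriented: ClusterResult,
               track: str = "PolII") -> DirectionalityReport:
    """Per-cluster PolII skew on orientation-aligned rows plus overall
    concordance (fraction of asymmetric-cluster anchors whose aligned PolII
    asymmetry is positive, i.e. matches the variant orientation)."""
    if isinstance(polii_rows, ProfileMatrix):
        if track not in polii_rows.data:
            raise ValueError(f"missing PolII track {track!r}")
        polii_rows = polii_rows.data[track]
    if oriented.orientation is None:
        raise ValueError("cluster result carries no orientations; "
                         "run classify_and_orient first")
    if polii_rows.shape[0] != len(oriented.labels):
        raise ValueError("PolII matrix and clustering cover different anchors")

    aligned = oriented_rows(polii_rows, oriented.orientation)
    A = np.array([asymmetry_score(r) for r in aligned])
    finals = oriented.final_labels()
    rows = []
    for fid in sorted(set(finals)):
        sel = finals == fid
        asym = bool((oriented.orientation[sel] != 0).any())
        rows.append((fid, float(A[sel].mean()), int(sel.sum()),
                     "asymmetric" if asym else "symmetric"))
    table = pd.DataFrame(rows, columns=["cluster", "mean_polii_A", "n", "call"])
    asym_sel = oriented.orientation != 0
    concordance = float((A[asym_sel] > 0).mean()) if asym_sel.any() else float("nan")
    return DirectionalityReport(table, concordance, A)


def strand_bias(plus: SignalTrack, minus: SignalTrack, anchors: AnchorSet,
                oriented: ClusterResult, window: int = 2000,
                n_boot: int = 1000, seed: int = 0
                ) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-anchor strand bias B and per-cluster mean with a bootstrap CI.

    P and M are the plus/minus totals over [center - window, center + window);
    B = (P - M)/(P + M + eps), sign-flipped for left-oriented anchors so B > 0
    means transcription leaning toward the variant orientation. Anchors with
    P + M = 0 get B = 0 (flagged via the returned mask in the table's
    ``n_zero`` column). The CI is a seeded percentile bootstrap.
    """
    if oriented.orientation is None:
        raise ValueError("orientations missing; run classify_and_orient first")
    if len(anchors) != len(oriented.labels):
        raise ValueError("anchor set and clustering cover different anchors")
    B = np.zeros(len(anchors))
    zero = np.zeros(len(anchors), bool)
    for i, a in enumerate(anchors.anchors):
        c = a.center
        P = plus.window_sum(a.chrom, c - window, c + window)
        M = minus.window_sum(a.chrom, c - window, c + window)
        if P + M == 0:
            zero[i] = True
            continue
        B[i] = (P - M) / (P + M + EPS)
    flip = oriented.orientation == -1
    B[flip] = -B[flip]

    rng = np.random.default_rng(seed)
    finals = oriented.final_labels()
    rows = []
    for fid in sorted(set(finals)):
        sel = finals == fid
        vals = B[sel]
        boots = np.array([vals[rng.integers(0, len(vals), len(vals))].mean()
                          for _ in range(n_boot)])
        rows.append((fid, float(vals.mean()),
                     float(np.quantile(boots, 0.025)),
                     float(np.quantile(boots, 0.975)),
                     int(sel.sum()), int(zero[sel].sum())))
    table = pd.DataFrame(rows, columns=["cluster", "mean_B", "ci_lo", "ci_hi",
                                        "n", "n_zero"])
    return B, table


def compare_cluster_signal(a: np.ndarray, b: np.ndarray,
                           alternative: str = "less") -> ComparisonResult:
    """One-sided Mann-Whitney U on per-anchor totals of two clusters.

    ``alternative="less"`` tests whether cluster *a*'s values are
    stochastically smaller than *b*'s. The exact null distribution is used
    when min(n) <= 20 and there are no ties; otherwise the normal
    approximation with continuity correction. Two identical constant samples
    yield p = 0.5 with a tie warning.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both clusters must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("identical constant samples; p = 0.5", stacklevel=2)
        return ComparisonResult(len(a) * len(b) / 2.0, 0.5, len(a), len(b),
                                "degenerate", alternative, tie_warning=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            len(a), len(b), method, alternative,
                            tie_warning=has_ties)


def pairwise_cluster_comparisons(totals: np.ndarray, finals: np.ndarray
                                 ) -> pd.DataFrame:
    """All ordered (a < b by mean) one-sided comparisons between final clusters
    on per-anchor totals; returns a tidy frame sorted by p-value."""
    rows = []
    ids = sorted(set(finals))
    for i, ca in enumerate(ids):
        for cb in ids[i + 1:]:
            va, vb = totals[finals == ca], totals[finals == cb]
            lo, hi, vlo, vhi = ((ca, cb, va, vb) if va.mean() <= vb.mean()
                                else (cb, ca, vb, va))
            r = compare_cluster_signal(vlo, vhi, "less")
            rows.append((lo, hi, r.statistic, r.pvalue, r.n_a, r.n_b, r.method))
    return (pd.DataFrame(rows, columns=["cluster_low", "cluster_high", "U",
                                        "pvalue", "n_low", "n_high", "method"])
            .sort_values("pvalue", ignore_index=True))
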