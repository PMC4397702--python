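"""Profile clustering, mirror-image pairing, asymmetry scoring, orientation.

Anchors are clustered on the concatenation of their per-track profiles with
K-means under the correlation distance d(x, y) = 1 - |r(x, y)| (Pearson r of
the concatenated vectors; the absolute value treats anti-correlated shapes as
similar). Groups whose centroids are bin-reversals of each other describe the
same element class seen in opposite genomic orientations; they are paired and
merged, one member designated "right" (signal skewed to increasing
coordinates) and its partner "left". Merging K groups with P mirror pairs
yields K - P final clusters.

The asymmetry score of a profile is A = (R - L) / (R + L + eps) with L and R
the total signal strictly left/right of the window center; A is in [-1, 1]
and exactly antisymmetric under bin reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anchors_profiles import ProfileMatrix

__all__ = ["ClusterResult", "AsymmetryReport", "kmeans_profiles", "mirror_pair",
           "asymmetry_score", "asymmetry_report", "classify_and_orient"]

EPS = 1e-12


@dataclass
class ClusterResult:
    labels: np.ndarray                  # (n,) group ids 1..K
    centroids: dict[int, np.ndarray]    # group id -> concatenated profile
    K: int
    seed: int
    metric: str
    track_names: list[str]
    n_bins: int
    zero_variance: np.ndarray = None    # (n,) rows flagged for the tie-break rule
    mirror_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    merged_clusters: dict[int, tuple[int, ...]] = field(default_factory=dict)
    orientation: np.ndarray = None      # (n,) +1 right / -1 left / 0 none
    pair_sides: dict[int, str] = field(default_factory=dict)  # group -> left|right

    @property
    def n_final_clusters(self) -> int:
        return len(self.merged_clusters) if self.merged_clusters else self.K

    def final_labels(self) -> np.ndarray:
        """Per-anchor final (merged) cluster ids; identity if no merge yet."""
        if not self.merged_clusters:
            return self.labels.copy()
        group_to_final = {g: fid for fid, groups in self.merged_clusters.items()
                          for g in groups}
        return np.array([group_to_final[g] for g in self.labels])


def _zscore(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    flat = sd == 0
    Z = (X - mu) / np.where(flat, 1.0, sd)[:, None]
    Z[flat] = 0.0
    return Z, flat


def _distances(Zx: np.ndarray, Zc: np.ndarray, metric: str) -> np.ndarray:
    r = np.clip(Zx @ Zc.T / Zx.shape[1], -1.0, 1.0)
    return 1.0 - np.abs(r) if metric == "abs_pearson" else 1.0 - r


def kmeans_profiles(matrix: ProfileMatrix, K: int = 16, seed: int = 0,
                    max_iter: int = 100, metric: str = "abs_pearson"
                    ) -> ClusterResult:
    """K-means on concatenated per-track profiles under correlation distance.

    Centroids are member means; iteration stops at label convergence or
    ``max_iter``. Initialization is a k-means++-style farthest-point seeding
    driven by ``seed``. Empty clusters are re-seeded from the point farthest
    from its current centroid. Zero-variance rows (correlation undefined) are
    assigned to the Euclidean-nearest centroid and flagged.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if metric not in ("abs_pearson", "pearson"):
        raise ValueError(f"unknown metric {metric!r}")
    X = matrix.concat()
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of anchors {n}")
    rng = np.random.default_rng(seed)
    Zx, flat = _zscore(X)
    ok = np.flatnonzero(~flat)
    if len(ok) == 0:
        raise ValueError("all rows have zero variance")

    # k-means++ seeding on the correlation distance, restricted to usable rows
    first = rng.choice(ok)
    centers = [first]
    d2 = _distances(Zx[ok], Zx[[first]], metric)[:, 0] ** 2
    for _ in range(1, K):
        total = d2.sum()
        if total <= 0:
            probe = rng.choice(ok)
            centers.append(int(probe))
            continue
        pick = ok[rng.choice(len(ok), p=d2 / total)]
        centers.append(int(pick))
        d2 = np.minimum(d2, _distances(Zx[ok], Zx[[pick]], metric)[:, 0] ** 2)
    C = X[centers].copy()

    labels = np.full(n, -1)
    for _ in range(max_iter):
        Zc, cflat = _zscore(C)
        D = _distances(Zx, Zc, metric)
        new = D.argmin(axis=1)
        if flat.any():  # tie-break rule: Euclidean nearest centroid
            De = ((X[flat][:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
            new[flat] = De.argmin(axis=1)
        # re-seed empty clusters from the worst-fit point
        for k in range(K):
            if not (new == k).any():
                worst = int(np.argmax(D[np.arange(n), new]))
                C[k] = X[worst]
                new[worst] = k
        if (new == labels).all():
            break
        labels = new
        for k in range(K):
            C[k] = X[labels == k].mean(axis=0)

    centroids = {k + 1: C[k].copy() for k in range(K)}
    return ClusterResult(labels + 1, centroids, K, seed, metric,
                         list(matrix.track_names), matrix.n_bins,
                         zero_variance=flat)


def _per_track(vec: np.ndarray, n_tracks: int) -> np.ndarray:
    return vec.reshape(n_tracks, -1)


def _mirror_score(ca: np.ndarray, cb: np.ndarray, n_tracks: int) -> float:
    """Pearson r between centroid_a and centroid_b after reversing the bin
    order of each of centroid_b's per-track blocks. Scoring the concatenated
    vectors keeps the score on the same footing as the clustering metric
    (tracks with no signal carry no weight)."""
    b = _per_track(cb, n_tracks)[:, ::-1].ravel()
    if ca.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(ca, b)[0, 1])


def mirror_pair(result: ClusterResult, min_corr: float = 0.8) -> ClusterResult:
    """Pair groups whose centroids are mutual bin-reversals (greedy matching on
    descending mirror score, score >= min_corr, ties to lower group ids) and
    merge each pair into one final cluster. Finding no pairs is valid."""
    nt = len(result.track_names)
    groups = sorted(result.centroids)
    cand = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            m = _mirror_score(result.centroids[a], result.centroids[b], nt)
            if m >= min_corr:
                cand.append((a, b, m))
    cand.sort(key=lambda t: (-t[2], t[0], t[1]))
    used: set[int] = set()
    pairs = []
    for a, b, m in cand:
        if a in used or b in used:
            continue
        pairs.append((a, b, m))
        used.update((a, b))

    merged: dict[int, tuple[int, ...]] = {}
    partner = {}
    for a, b, _ in pairs:
        partner[a] = b
        partner[b] = a
    fid = 0
    seen: set[int] = set()
    for g in groups:
        if g in seen:
            continue
        fid += 1
        if g in partner:
            merged[fid] = (g, partner[g])
            seen.update((g, partner[g]))
        else:
            merged[fid] = (g,)
            seen.add(g)
    return replace(result, mirror_pairs=pairs, merged_clusters=merged)


def asymmetry_score(profile: np.ndarray, eps: float = EPS) -> float:
    """A = (R - L)/(R + L + eps); L/R are sums strictly left/right of center
    (odd bin counts exclude the center bin). A = 0 exactly when R + L = 0."""
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("profile must be a 1-D vector with >= 2 bins")
    half = len(p) // 2
    L = float(p[:half].sum())
    R = float(p[half + 1:].sum()) if len(p) % 2 else float(p[half:].sum())
    if L + R == 0:
        return 0.0
    return (R - L) / (R + L + eps)


def _has_signal(profile: np.ndarray, enrichment: float = 3.0) -> bool:
    """A track carries signal in a cluster when its centroid peak rises above
    its own baseline (median bin, i.e. background) by ``enrichment``-fold.
    Scale-invariant, so RPKM display constants cannot change the call."""
    med = float(np.median(profile))
    peak = float(profile.max())
    if med <= 0:
        return peak > 0
    return peak > enrichment * med


@dataclass
class AsymmetryReport:
    per_cluster: dict[tuple[int, str], float]   # (group, track) -> A of centroid
    per_anchor: np.ndarray                      # (n,) A on the scoring track
    scoring_track: str
    threshold: float
    calls: dict[int, str] = field(default_factory=dict)  # group -> symmetric|asymmetric


def asymmetry_report(result: ClusterResult, matrix: ProfileMatrix,
                     track_priority: tuple[str, ...] = ("H3.3", "H2A.Z"),
                     threshold: float = 0.2) -> AsymmetryReport:
    """Asymmetry scores per (group, track) on centroids and per anchor on the
    first priority track with nonzero centroid signal in any group."""
    nt = len(result.track_names)
    per_cluster = {}
    for g, c in result.centroids.items():
        for name, row in zip(result.track_names, _per_track(c, nt)):
            per_cluster[(g, name)] = asymmetry_score(row)

    scoring = next((t for t in track_priority
                    if t in result.track_names
                    and any(_has_signal(_per_track(result.centroids[g], nt)
                                        [result.track_names.index(t)])
                            for g in result.centroids)),
                   result.track_names[0])
    per_anchor = np.array([asymmetry_score(row) for row in matrix.data[scoring]])

    calls = {}
    for g in result.centroids:
        a = _cluster_score(result, g, per_cluster, track_priority)
        calls[g] = "asymmetric" if abs(a) >= threshold else "symmetric"
    return AsymmetryReport(per_cluster, per_anchor, scoring, threshold, calls)


def _cluster_score(result: ClusterResult, g: int,
                   per_cluster: dict[tuple[int, str], float],
                   track_priority: tuple[str, ...]) -> float:
    """Asymmetry of group g on the first priority track carrying signal in its
    centroid, falling back to the largest-|A| signal-bearing track, then to the
    first track."""
    nt = len(result.track_names)
    blocks = _per_track(result.centroids[g], nt)
    with_signal = [t for t, blk in zip(result.track_names, blocks)
                   if _has_signal(blk)]
    for t in track_priority:
        if t in with_signal:
            return per_cluster[(g, t)]
    if with_signal:
        return max((per_cluster[(g, t)] for t in with_signal), key=abs)
    return per_cluster[(g, result.track_names[0])]


def classify_and_orient(result: ClusterResult, report: AsymmetryReport,
                        track_priority: tuple[str, ...] = ("H3.3", "H2A.Z"),
                        ) -> ClusterResult:
    """Assign per-anchor orientation from the group-level asymmetry calls.

    Within a mirror pair the group whose priority-track A is larger is "right"
    (+1), its partner "left" (-1). An unpaired asymmetric group orients by the
    sign of its A; symmetric groups get orientation 0 ("none").
    """

    def score(g: int) -> float:
        return _cluster_score(result, g, report.per_cluster, track_priority)

    group_orient: dict[int, int] = {}
    sides: dict[int, str] = {}
    paired = {g for a, b, _ in result.mirror_pairs for g in (a, b)}
    for a, b, _ in result.mirror_pairs:
        sa, sb = score(a), score(b)
        right, left = (a, b) if sa >= sb else (b, a)
        group_orient[right], group_orient[left] = 1, -1
        sides[right], sides[left] = "right", "left"
    for g in result.centroids:
        if g in paired:
            continue
        if report.calls.get(g) == "asymmetric":
            group_orient[g] = 1 if score(g) >= 0 else -1
        else:
            group_orient[g] = 0
    orientation = np.array([group_orient[g] for g in result.labels])
    return replace(result, orientation=orientation, pair_sides=sides)


def oriented_rows(rows: np.ndarray, orientation: np.ndarray) -> np.ndarray:
    """Bin-reverse the rows of left-oriented anchors (for pooled displays and
    orientation-aligned statistics)."""
    out = rows.copy()
    left = orientation == -1
    out[left] = out[left, :, ::-1] if rows.ndim == 3 else out[left, ::-1]
    return out
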