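"""Correlation-metric K-means, mirror pairing, asymmetry, and orientation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from variantscape.anchors_profiles import ProfileMatrix
from variantscape.clustering import (asymmetry_report, asymmetry_score,
                                     classify_and_orient, kmeans_profiles,
                                     mirror_pair, oriented_rows, _distances,
                                     _zscore)
from variantscape.genomic_io import GenomicInterval


def matrix_from(data: dict[str, np.ndarray], W=2000, b=100) -> ProfileMatrix:
    n = next(iter(data.values())).shape[0]
    anchors = [GenomicInterval("chrT", 10_000 + 6000 * i,
                               10_000 + 6000 * i + 200) for i in range(n)]
    return ProfileMatrix(data, anchors, W, b, list(data))


def bump(nbins=40, offset_bins=0, amp=10.0, sigma_bins=3.0):
    x = np.arange(nbins)
    return amp * np.exp(-(x - ((nbins - 1) / 2 + offset_bins)) ** 2
                        / (2 * sigma_bins ** 2))


def planted_matrix(archetype_rows, per=20, noise=0.3, seed=0,
                   tracks=("H3.3", "H2A.Z")):
    """Rows per archetype with Gaussian noise; returns (matrix, truth)."""
    rng = np.random.default_rng(seed)
    data = {t: [] for t in tracks}
    truth = []
    for k, arch in enumerate(archetype_rows):
        for _ in range(per):
            for t in tracks:
                data[t].append(arch[t] + rng.normal(0, noise, len(arch[t])))
            truth.append(k)
    return matrix_from({t: np.array(v) for t, v in data.items()}), np.array(truth)


class TestKMeans:
    def test_separable_archetypes_recovered_exactly(self):
        archs = [{"H3.3": bump(offset_bins=o), "H2A.Z": bump(offset_bins=-o)}
                 for o in (-8, -3, 3, 8)]
        mat, truth = planted_matrix(archs, per=15, noise=0.2)
        res = kmeans_profiles(mat, K=4, seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_equals_one_groups_everything(self):
        mat, _ = planted_matrix([{"H3.3": bump(), "H2A.Z": bump()}], per=10)
        res = kmeans_profiles(mat, K=1, seed=0)
        assert set(res.labels) == {1}

    def test_k_larger_than_n_rejected(self):
        mat, _ = planted_matrix([{"H3.3": bump(), "H2A.Z": bump()}], per=3)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(mat, K=5)

    def test_deterministic_given_seed(self):
        archs = [{"H3.3": bump(offset_bins=o), "H2A.Z": bump()} for o in (-5, 5)]
        mat, _ = planted_matrix(archs, per=10, noise=1.0)
        a = kmeans_profiles(mat, K=2, seed=3)
        b = kmeans_profiles(mat, K=2, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_variance_rows_are_flagged_and_assigned(self):
        archs = [{"H3.3": bump(offset_bins=-5)}, {"H3.3": bump(offset_bins=5)}]
        mat, _ = planted_matrix(archs, per=5, noise=0.1, tracks=("H3.3",))
        mat.data["H3.3"][0] = 2.0  # constant row
        res = kmeans_profiles(mat, K=2, seed=0)
        assert res.zero_variance[0]
        assert res.labels[0] in (1, 2)

    def test_reaches_global_optimum_on_enumerable_problem(self):
        # 8 rows, K=2: the best of 20 restarts must attain the optimum found
        # by exhaustive enumeration of all 2-partitions
        archs = [{"H3.3": bump(offset_bins=-6)}, {"H3.3": bump(offset_bins=6)}]
        mat, _ = planted_matrix(archs, per=4, noise=1.5, seed=5,
                                tracks=("H3.3",))
        X = mat.concat()

        def objective(labels):
            total = 0.0
            for k in set(labels):
                members = X[np.array(labels) == k]
                c = members.mean(axis=0)
                zc, _ = _zscore(c[None, :])
                zm, _ = _zscore(members)
                total += _distances(zm, zc, "abs_pearson").sum()
            return total

        best_enum = min(
            objective([0 if i in left else 1 for i in range(8)])
            for r in range(1, 8)
            for left in itertools.combinations(range(8), r))
        best_kmeans = min(
            objective(list(kmeans_profiles(mat, K=2, seed=s).labels))
            for s in range(20))
        assert best_kmeans <= best_enum + 1e-9


class TestMirrorPairs:
    def test_exact_reverse_centroids_pair_with_score_one(self):
        archs = [{"H3.3": bump(offset_bins=6), "H2A.Z": bump(offset_bins=3)},
                 {"H3.3": bump(offset_bins=-6), "H2A.Z": bump(offset_bins=-3)},
                 {"H3.3": bump(), "H2A.Z": bump()}]
        mat, _ = planted_matrix(archs, per=10, noise=0.0)
        res = mirror_pair(kmeans_profiles(mat, K=3, seed=0))
        assert len(res.mirror_pairs) == 1
        a, b, m = res.mirror_pairs[0]
        assert m == pytest.approx(1.0, abs=1e-9)
        assert res.n_final_clusters == 2

    def test_symmetric_cluster_does_not_self_pair(self):
        archs = [{"H3.3": bump(), "H2A.Z": bump()},
                 {"H3.3": bump(amp=0.0) + 1.0, "H2A.Z": bump(offset_bins=10)}]
        mat, _ = planted_matrix(archs, per=10, noise=0.05)
        res = mirror_pair(kmeans_profiles(mat, K=2, seed=0))
        # the symmetric centroid mirrors itself perfectly, but self-pairing
        # is forbidden and the two clusters are not mirror images
        assert all(a != b for a, b, _ in res.mirror_pairs)

    def test_no_pairs_is_a_valid_outcome(self):
        archs = [{"H3.3": bump(), "H2A.Z": bump()},
                 {"H3.3": bump(offset_bins=10), "H2A.Z": bump()}]
        mat, _ = planted_matrix(archs, per=10, noise=0.05)
        res = mirror_pair(kmeans_profiles(mat, K=2, seed=0), min_corr=0.99)
        assert res.mirror_pairs == []
        assert res.n_final_clusters == 2

    def test_label_permutation_leaves_pairing_equivalent(self):
        archs = [{"H3.3": bump(offset_bins=6), "H2A.Z": bump(offset_bins=6)},
                 {"H3.3": bump(offset_bins=-6), "H2A.Z": bump(offset_bins=-6)},
                 {"H3.3": bump(), "H2A.Z": bump()}]
        mat, truth = planted_matrix(archs, per=10, noise=0.1)
        res = mirror_pair(kmeans_profiles(mat, K=3, seed=0))
        import dataclasses
        perm = {1: 3, 2: 1, 3: 2}
        permuted = dataclasses.replace(
            res, labels=np.array([perm[g] for g in res.labels]),
            centroids={perm[g]: c for g, c in res.centroids.items()},
            mirror_pairs=[], merged_clusters={})
        re_paired = mirror_pair(permuted)
        expected = {frozenset((perm[a], perm[b])) for a, b, _ in res.mirror_pairs}
        got = {frozenset((a, b)) for a, b, _ in re_paired.mirror_pairs}
        assert got == expected


class TestAsymmetry:
    def test_symmetric_profile_scores_zero(self):
        assert asymmetry_score(bump()) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example_three_bins(self):
        assert asymmetry_score(np.array([0.0, 1.0, 3.0])) == \
            pytest.approx(1.0, abs=1e-9)
        assert asymmetry_score(np.array([3.0, 1.0, 0.0])) == \
            pytest.approx(-1.0, abs=1e-9)

    def test_all_mass_right_gives_plus_one(self):
        p = np.zeros(40)
        p[30] = 5.0
        assert asymmetry_score(p) == pytest.approx(1.0, abs=1e-9)

    def test_empty_profile_scores_exactly_zero(self):
        assert asymmetry_score(np.zeros(40)) == 0.0

    @given(arrays(float, st.integers(2, 41),
                  elements=st.floats(0, 1e6, allow_nan=False)))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_antisymmetry_under_reversal(self, p):
        assert asymmetry_score(p[::-1]) == pytest.approx(-asymmetry_score(p),
                                                         abs=1e-12)
        assert abs(asymmetry_score(p)) <= 1.0


class TestOrientation:
    @staticmethod
    def oriented(per=12, noise=0.2, flip=False):
        right = {"H3.3": bump(offset_bins=5), "H2A.Z": bump(offset_bins=5)}
        left = {"H3.3": bump(offset_bins=-5), "H2A.Z": bump(offset_bins=-5)}
        sym = {"H3.3": bump(), "H2A.Z": bump()}
        mat, truth = planted_matrix([right, left, sym], per=per, noise=noise)
        if flip:
            for t in mat.data:
                mat.data[t] = mat.data[t][:, ::-1]
        res = mirror_pair(kmeans_profiles(mat, K=3, seed=0))
        report = asymmetry_report(res, mat)
        return classify_and_orient(res, report), truth, report

    def test_planted_right_offset_yields_right_orientation(self):
        res, truth, report = self.oriented()
        assert (res.orientation[truth == 0] == 1).all()
        assert (res.orientation[truth == 1] == -1).all()
        assert (res.orientation[truth == 2] == 0).all()

    def test_mirror_partners_have_equal_magnitude_asymmetry(self):
        res, truth, report = self.oriented()
        (a, b, _), = res.mirror_pairs
        assert report.per_cluster[(a, "H3.3")] == pytest.approx(
            -report.per_cluster[(b, "H3.3")], abs=0.1)

    def test_reversing_all_rows_flips_orientations_and_negates_scores(self):
        res_f, truth, rep_f = self.oriented()
        res_r, _, rep_r = self.oriented(flip=True)
        np.testing.assert_array_equal(res_r.orientation, -res_f.orientation)
        np.testing.assert_allclose(rep_r.per_anchor, -rep_f.per_anchor,
                                   atol=1e-12)

    def test_oriented_rows_reverses_only_left_anchors(self):
        rows = np.arange(12, dtype=float).reshape(3, 4)
        out = oriented_rows(rows, np.array([1, -1, 0]))
        np.testing.assert_array_equal(out[0], rows[0])
        np.testing.assert_array_equal(out[1], rows[1][::-1])
        np.testing.assert_array_equal(out[2], rows[2])
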