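"""From-scratch agglomerative clustering vs examples and the scipy oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy as sch

from abcds import cut, linkage, pairwise_distances, select_k_largest_gap


def partitions_equal(a, b) -> bool:
    """Same partition up to label permutation (bijection between labels)."""
    fwd, bwd = {}, {}
    for x, y in zip(a, b):
        if fwd.setdefault(x, y) != y or bwd.setdefault(y, x) != x:
            return False
    return True


class TestPairwiseDistances:
    def test_single_point(self):
        assert pairwise_distances([(1.0, 2.0, 3.0)]).shape == (1, 1)

    def test_3_4_5_triangle(self):
        d = pairwise_distances([(0, 0, 0), (3, 4, 0)])
        assert d[0, 1] == pytest.approx(5.0)

    def test_domain_extremes(self):
        d = pairwise_distances([(6, 3, 4), (54, 27, 36)])
        assert d[0, 1] == pytest.approx(np.sqrt(3904), abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([(0, 0, np.nan), (1, 1, 1)])


class TestLinkage:
    def test_single_leaf(self):
        dend = linkage([(1.0, 1.0, 1.0)])
        assert dend.n_leaves == 1 and dend.merges == ()

    @pytest.mark.parametrize("method", ["ward", "complete", "average"])
    def test_two_points_merge_at_their_distance(self, method):
        dend = linkage([(0, 0, 0), (3, 4, 0)], method=method)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(5.0)

    def test_complete_linkage_chain(self):
        # 1-D points {0, 1, 10}: merge {0,1} at 1, then with {10} at 10
        dend = linkage([[0.0], [1.0], [10.0]], method="complete")
        (l0, r0, h0, s0), (l1, r1, h1, s1) = dend.merges
        assert {l0, r0} == {0, 1} and h0 == pytest.approx(1.0) and s0 == 2
        assert {l1, r1} == {2, 3} and h1 == pytest.approx(10.0) and s1 == 3

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown linkage"):
            linkage([[0.0], [1.0]], method="single")

    @pytest.mark.parametrize("method", ["ward", "complete", "average"])
    def test_heights_monotone_and_sizes_conserved(self, method, rng):
        pts = rng.normal(size=(30, 3))
        dend = linkage(pts, method=method)
        h = dend.heights
        assert np.all(np.diff(h) >= -1e-9)
        assert dend.merges[-1][3] == 30

    @pytest.mark.parametrize("method", ["ward", "complete", "average"])
    def test_scipy_oracle_small(self, method, rng):
        """Heights and all-k partitions match scipy on random instances."""
        for _ in range(25):
            n = int(rng.integers(3, 25))
            pts = rng.normal(size=(n, 3)) * 5
            dend = linkage(pts, method=method)
            Z = sch.linkage(pts, method=method)
            assert np.allclose(dend.heights, Z[:, 2], atol=1e-9)
            for k in range(1, n + 1):
                assert partitions_equal(
                    cut(dend, k).labels, sch.fcluster(Z, k, criterion="maxclust")
                )

    def test_ward_legacy_flavor_differs(self, rng):
        """Legacy Ward (recurrence on raw distances) is a distinct tree scale."""
        pts = rng.normal(size=(12, 3))
        modern = linkage(pts, "ward").heights
        legacy = linkage(pts, "ward", ward_flavor="legacy").heights
        assert not np.allclose(modern, legacy)
        assert np.all(np.diff(legacy) >= -1e-9)

    def test_tie_break_deterministic(self):
        # four collinear points with tied nearest pairs: (0,1) before (2,3)
        dend = linkage([[0.0], [1.0], [5.0], [6.0]], method="complete")
        assert (dend.merges[0][0], dend.merges[0][1]) == (0, 1)
        assert (dend.merges[1][0], dend.merges[1][1]) == (2, 3)

    def test_permutation_invariance(self, rng):
        """Distinct distances: input order never changes the partition."""
        pts = rng.normal(size=(15, 3)) * 10 + rng.random((15, 3))
        for method in ("ward", "complete", "average"):
            base = linkage(pts, method=method)
            perm = rng.permutation(15)
            permuted = linkage(pts[perm], method=method)
            for k in (2, 3, 5):
                lab_base = np.asarray(cut(base, k).labels)
                lab_perm = np.asarray(cut(permuted, k).labels)
                assert partitions_equal(lab_base[perm], lab_perm)


class TestCut:
    @pytest.fixture
    def dend(self):
        return linkage([[0.0], [1.0], [10.0]], method="complete")

    def test_k1_and_kn(self, dend):
        assert set(cut(dend, 1).labels) == {1}
        assert cut(dend, 3).labels == (1, 2, 3)

    def test_k2_partition(self, dend):
        assert cut(dend, 2).labels == (1, 1, 2)

    def test_labels_first_appearance_order(self, rng):
        pts = rng.normal(size=(20, 3))
        labels = cut(linkage(pts, "ward"), 4).labels
        firsts = []
        for lab in labels:
            if lab not in firsts:
                firsts.append(lab)
        assert firsts == [1, 2, 3, 4]

    def test_refinement_property(self, rng):
        """cut(k+1) refines cut(k): cluster members never re-mix."""
        pts = rng.normal(size=(25, 3))
        dend = linkage(pts, "average")
        for k in range(1, 25):
            coarse = cut(dend, k).labels
            fine = cut(dend, k + 1).labels
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c

    def test_k_out_of_range(self, dend):
        with pytest.raises(ValueError):
            cut(dend, 0)
        with pytest.raises(ValueError):
            cut(dend, 4)


class TestSelectK:
    def test_documented_gap_example(self):
        # heights (1, 1.5, 20), n = 4: gap for k=2 is 18.5 -> k = 2
        from abcds.cluster import Dendrogram

        dend = Dendrogram(
            n_leaves=4,
            merges=((0, 1, 1.0, 2), (2, 3, 1.5, 2), (4, 5, 20.0, 4)),
            leaf_ids=("a", "b", "c", "d"),
        )
        assert select_k_largest_gap(dend, 2, 3) == 2

    def test_equidistant_heights_tie_to_k_min(self):
        from abcds.cluster import Dendrogram

        dend = Dendrogram(
            n_leaves=4,
            merges=((0, 1, 1.0, 2), (2, 3, 2.0, 2), (4, 5, 3.0, 4)),
            leaf_ids=("a", "b", "c", "d"),
        )
        assert select_k_largest_gap(dend, 2, 3) == 2

    def test_two_planted_blobs_recovered(self):
        """Two well-separated blobs, n = 40 -> k = 2 in >= 99% of replicates."""
        hits = 0
        reps = 100
        for seed in range(reps):
            r = np.random.default_rng(seed)
            pts = np.vstack(
                [r.normal(0, 1, size=(20, 3)), r.normal(12, 1, size=(20, 3))]
            )
            dend = linkage(pts, "ward")
            hits += select_k_largest_gap(dend, 2, 8) == 2
        assert hits >= 0.99 * reps

    def test_too_few_leaves(self):
        dend = linkage([[0.0], [1.0]], method="ward")
        with pytest.raises(ValueError):
            select_k_largest_gap(dend, 2, 1)
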