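"""Clustering, NMI (+ baseline), purity, dendrogram correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsaphylo import (
    DistanceMatrix,
    common_nodes_corr,
    cophenetic_corr,
    hclust,
    nmi,
    nmi_baseline,
    purity,
)
from rsaphylo.compare import CompareError, Dendrogram


def _dm(ids, dense):
    return DistanceMatrix(ids, np.asarray(dense, dtype=float))


@pytest.fixture
def three_point_dm():
    # two close points and one far point
    return _dm(["a", "b", "c"], [[0, 1, 10], [1, 0, 10], [10, 10, 0]])


@pytest.fixture
def quartet_trees():
    """((a,b),(c,d)) and ((a,c),(b,d)) built from forced distances."""
    t1 = hclust(
        _dm(["a", "b", "c", "d"],
            [[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]]),
        "average",
    )
    t2 = hclust(
        _dm(["a", "b", "c", "d"],
            [[0, 9, 1, 9], [9, 0, 9, 1], [1, 9, 0, 9], [9, 1, 9, 0]]),
        "average",
    )
    return t1, t2


class TestHclust:
    @pytest.mark.parametrize("linkage", ["ward", "average"])
    def test_forced_first_merge(self, three_point_dm, linkage):
        tree = hclust(three_point_dm, linkage)
        first = set(tree.Z[0, :2].astype(int))
        assert first == {0, 1}  # the close pair

    def test_average_linkage_matches_brute_force_on_quartet(self):
        d = np.array(
            [[0, 2, 6, 10], [2, 0, 5, 9], [6, 5, 0, 4], [10, 9, 4, 0]], dtype=float
        )
        tree = hclust(_dm(list("abcd"), d), "average")

        # exhaustive UPGMA oracle
        clusters = [{0}, {1}, {2}, {3}]
        merges = []
        while len(clusters) > 1:
            best = None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    dist = np.mean([d[p, q] for p in clusters[i] for q in clusters[j]])
                    if best is None or dist < best[0]:
                        best = (dist, i, j)
            dist, i, j = best
            merges.append((frozenset(clusters[i] | clusters[j]), dist))
            clusters = (
                [c for k, c in enumerate(clusters) if k not in (i, j)]
                + [clusters[i] | clusters[j]]
            )
        got_sets = []
        sets = [frozenset([k]) for k in range(4)]
        for a, b, height, _ in tree.Z:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            got_sets.append((merged, height))
        for (exp_set, exp_h), (got_set, got_h) in zip(merges, got_sets):
            assert exp_set == got_set
            assert got_h == pytest.approx(exp_h)

    def test_ward_heights_match_lance_williams_on_triple(self, three_point_dm):
        tree = hclust(three_point_dm, "ward")
        # first merge at d(a,b) = 1; then the Ward.D2 update:
        # d(ab, c) = sqrt[ (2*d(a,c)^2 + 2*d(b,c)^2 - d(a,b)^2) / 3 ]
        expected = math.sqrt((2 * 100 + 2 * 100 - 1) / 3)
        assert tree.Z[0, 2] == pytest.approx(1.0)
        assert tree.Z[1, 2] == pytest.approx(expected)

    def test_nan_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(Exception):
            hclust(DistanceMatrix(["a", "b"], vals), "ward")


class TestCutToK:
    def test_extremes(self, three_point_dm):
        tree = hclust(three_point_dm, "average")
        assert len(set(tree.cut_to_k(1).values())) == 1
        assert len(set(tree.cut_to_k(3).values())) == 3

    def test_forced_two_cluster_cut(self, three_point_dm):
        tree = hclust(three_point_dm, "average")
        labels = tree.cut_to_k(2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_out_of_range_rejected(self, three_point_dm):
        tree = hclust(three_point_dm, "average")
        with pytest.raises(CompareError):
            tree.cut_to_k(0)
        with pytest.raises(CompareError):
            tree.cut_to_k(4)


class TestNMI:
    def test_identity_up_to_relabeling(self):
        a = {f"g{i}": lab for i, lab in enumerate([1, 1, 2, 2, 3, 3])}
        b = {f"g{i}": lab for i, lab in enumerate(["x", "x", "y", "y", "z", "z"])}
        assert nmi(a, b) == pytest.approx(1.0)

    def test_zero_entropy_convention(self):
        a = {f"g{i}": 0 for i in range(6)}
        b = {f"g{i}": i % 2 for i in range(6)}
        assert nmi(a, b) == 0.0

    def test_hand_computed_example(self):
        """6 points, a = {1,1,1,2,2,2}, b = {1,1,2,2,3,3}: direct evaluation
        of the entropy/MI formulas."""
        a = {f"g{i}": lab for i, lab in enumerate([1, 1, 1, 2, 2, 2])}
        b = {f"g{i}": lab for i, lab in enumerate([1, 1, 2, 2, 3, 3])}
        # joint counts: (1,1)=2 (1,2)=1 (2,2)=1 (2,3)=2
        h_a = -sum(p * math.log(p) for p in (0.5, 0.5))
        h_b = -sum(p * math.log(p) for p in (2 / 6, 2 / 6, 2 / 6))
        mi = (
            (2 / 6) * math.log((2 / 6) / (0.5 * (2 / 6)))
            + (1 / 6) * math.log((1 / 6) / (0.5 * (2 / 6)))
            + (1 / 6) * math.log((1 / 6) / (0.5 * (2 / 6)))
            + (2 / 6) * math.log((2 / 6) / (0.5 * (2 / 6)))
        )
        expected = mi / ((h_a + h_b) / 2)
        assert nmi(a, b) == pytest.approx(expected, rel=1e-10)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(CompareError):
            nmi({"a": 1}, {"b": 1})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        labels_a=st.lists(st.integers(0, 3), min_size=4, max_size=12),
        perm_seed=st.integers(0, 100),
    )
    def test_symmetric_and_label_invariant(self, labels_a, perm_seed):
        rng = np.random.default_rng(perm_seed)
        labels_b = rng.integers(0, 3, size=len(labels_a))
        a = {f"g{i}": v for i, v in enumerate(labels_a)}
        b = {f"g{i}": int(v) for i, v in enumerate(labels_b)}
        relabel = {v: f"L{v + 7}" for v in set(labels_a)}
        a_rel = {k: relabel[v] for k, v in a.items()}
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)
        assert nmi(a, b) == pytest.approx(nmi(a_rel, b), abs=1e-12)


class TestNMIBaseline:
    def test_single_cluster_all_zero(self):
        ref = {f"g{i}": i % 4 for i in range(20)}
        assert np.all(nmi_baseline(ref, k=1, n_sims=50, seed=0) == 0.0)

    def test_bias_grows_with_k(self):
        """Random assignments with more clusters score higher NMI: the bias
        the simulated baseline exists to correct."""
        ref = {f"g{i}": i % 48 for i in range(161)}
        lo = nmi_baseline(ref, k=5, n_sims=200, seed=1).mean()
        hi = nmi_baseline(ref, k=48, n_sims=200, seed=1).mean()
        assert hi > lo

    def test_deterministic_under_seed(self):
        ref = {f"g{i}": i % 3 for i in range(30)}
        s1 = nmi_baseline(ref, k=3, n_sims=40, seed=9)
        s2 = nmi_baseline(ref, k=3, n_sims=40, seed=9)
        np.testing.assert_array_equal(s1, s2)


class TestPurity:
    def test_perfect_clusters(self):
        clusters = {"a": 0, "b": 0, "c": 1, "d": 1}
        taxa = {"a": "A", "b": "A", "c": "B", "d": "B"}
        assert purity(clusters, taxa) == 1.0

    def test_enumerated_example(self):
        clusters = dict(zip("abcde", [0, 0, 0, 1, 1]))
        taxa = dict(zip("abcde", ["a", "a", "b", "b", "b"]))
        assert purity(clusters, taxa) == pytest.approx(0.8)

    def test_single_cluster(self):
        clusters = {f"g{i}": 0 for i in range(10)}
        taxa = {f"g{i}": ("A" if i < 7 else "B") for i in range(10)}
        assert purity(clusters, taxa) == pytest.approx(0.7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 2)),
                    min_size=3, max_size=20))
    def test_pigeonhole_lower_bound(self, pairs):
        clusters = {f"g{i}": c for i, (c, _) in enumerate(pairs)}
        taxa = {f"g{i}": t for i, (_, t) in enumerate(pairs)}
        n_taxa = len(set(taxa.values()))
        assert purity(clusters, taxa) >= 1.0 / n_taxa


class TestDendrogramCorrelations:
    def test_identical_trees(self, three_point_dm):
        t = hclust(three_point_dm, "average")
        assert cophenetic_corr(t, t) == pytest.approx(1.0)
        assert common_nodes_corr(t, t) == 1.0

    def test_common_nodes_quartet_enumeration(self, quartet_trees):
        t1, t2 = quartet_trees
        # internal nodes: {ab},{cd},{abcd} vs {ac},{bd},{abcd} -> share root only
        assert common_nodes_corr(t1, t2) == pytest.approx(2.0 / 6.0)

    def test_common_nodes_root_lower_bound(self, quartet_trees, three_point_dm):
        t1, t2 = quartet_trees
        assert common_nodes_corr(t1, t2) > 0

    def test_cophenetic_hand_computation(self, quartet_trees):
        t1, t2 = quartet_trees
        from scipy.stats import pearsonr

        c1 = t1.cophenetic()
        idx = [t2.ids.index(g) for g in t1.ids]
        from scipy.spatial.distance import squareform

        c2 = squareform(squareform(t2.cophenetic())[np.ix_(idx, idx)], checks=False)
        assert cophenetic_corr(t1, t2) == pytest.approx(pearsonr(c1, c2)[0])

    def test_leaf_order_invariance(self, quartet_trees):
        t1, t2 = quartet_trees
        assert cophenetic_corr(t1, t2) == pytest.approx(cophenetic_corr(t2, t1))

    def test_constant_cophenetic_undefined(self):
        # a perfectly balanced quartet merged at equal heights has constant
        # cophenetic distances after the root for n=2-leaf trees; force via n=3
        dm = _dm(list("abc"), [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        t = hclust(dm, "average")
        other = hclust(_dm(list("abc"), [[0, 1, 9], [1, 0, 9], [9, 9, 0]]), "average")
        val = cophenetic_corr(t, other)
        assert np.isnan(val) or -1.0 <= val <= 1.0

    def test_newick_export_parses(self, quartet_trees):
        from io import StringIO

        from Bio import Phylo

        t1, _ = quartet_trees
        tree = Phylo.read(StringIO(t1.to_newick()), "newick")
        assert sorted(leaf.name for leaf in tree.get_terminals()) == list("abcd")


class TestSingletonCutEntropy:
    def test_nmi_of_singletons_matches_formula(self, three_point_dm):
        """Cutting at k = n gives singletons; NMI vs any reference equals
        H(ref)/mean(H(ref), log n) under the arithmetic normalization."""
        tree = hclust(three_point_dm, "average")
        singletons = tree.cut_to_k(3)
        ref = {"a": "X", "b": "X", "c": "Y"}
        h_ref = -(2 / 3) * math.log(2 / 3) - (1 / 3) * math.log(1 / 3)
        h_single = math.log(3)
        expected = h_ref / ((h_ref + h_single) / 2)  # MI = H(ref)
        assert nmi(singletons, ref) == pytest.approx(expected, rel=1e-10)
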