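"""K2P distances, neighbor joining, rooting, bootstrap, parsimony, clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cladepan as cp
from cladepan.coresnp import CharacterMatrix
from cladepan.phylo import SaturationError, site_counts
from cladepan.records import CladepanError
from cladepan.tree import TreeNode, bipartitions
from conftest import enumerate_unrooted_topologies, random_tree, tree_path_distances


class TestK2P:
    def test_identical_rows_zero(self):
        assert cp.k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_ten_transitions_closed_form(self):
        row_a = "A" * 100
        row_b = "G" * 10 + "A" * 90  # A->G is a transition
        assert cp.k2p_distance(row_a, row_b) == pytest.approx(
            -0.5 * math.log(0.8), abs=1e-12
        )

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            cp.k2p_from_counts(cp.SiteCounts(n_sites=100, P=0.25, Q=0.5))

    def test_gaps_and_n_excluded_pairwise(self):
        counts = site_counts("ACG-N", "ACGTA")
        assert counts.n_sites == 3

    def test_zero_usable_sites_is_error(self):
        with pytest.raises(CladepanError):
            cp.k2p_distance("---", "AAA")

    @pytest.mark.parametrize("seed", range(10))
    def test_correction_inflates_raw_mismatch(self, seed):
        rng = np.random.default_rng(seed)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        other = cp.mutate_sequence(base, 0.1, 4.0, rng)
        raw = sum(1 for x, y in zip(base, other) if x != y) / len(base)
        assert cp.k2p_distance(base, other) >= raw

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        rows = [base] + [cp.mutate_sequence(base, rate, 4.0, rng)
                         for rate in (0.05, 0.1, 0.2)]
        chars = CharacterMatrix(
            genomes=["a", "b", "c", "d"],
            columns=np.array([list(r) for r in rows]),
            provenance=[("x", j) for j in range(300)],
        )
        matrix = cp.k2p_matrix(chars)
        for i, j in itertools.combinations(range(4), 2):
            expected = cp.k2p_distance(rows[i], rows[j])
            assert matrix.df.iat[i, j] == pytest.approx(expected, abs=1e-12)


def _dist(df):
    return cp.LabeledMatrix(df=df, symmetric=True)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        df = pd.DataFrame(
            [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = cp.nj_tree(_dist(df))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovery(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(4 + seed % 3)]
        true_tree = random_tree(labels, rng)
        paths = tree_path_distances(true_tree)
        n = len(labels)
        cells = np.zeros((n, n))
        for (a, b), d in paths.items():
            i, j = labels.index(a), labels.index(b)
            cells[i, j] = cells[j, i] = d
        inferred = cp.nj_tree(_dist(pd.DataFrame(cells, index=labels, columns=labels)))
        assert bipartitions(inferred) == bipartitions(true_tree)
        inferred_paths = tree_path_distances(inferred)
        for key, d in paths.items():
            assert inferred_paths[key] == pytest.approx(d, abs=1e-9)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(11)
        labels = ["t0", "t1", "t2", "t3", "t4"]
        true_tree = random_tree(labels, rng)
        paths = tree_path_distances(true_tree)
        perm = ["t3", "t0", "t4", "t2", "t1"]
        def matrix_for(order):
            n = len(order)
            cells = np.zeros((n, n))
            for (a, b), d in paths.items():
                i, j = order.index(a), order.index(b)
                cells[i, j] = cells[j, i] = d
            return _dist(pd.DataFrame(cells, index=order, columns=order))
        t1 = cp.nj_tree(matrix_for(labels))
        t2 = cp.nj_tree(matrix_for(perm))
        assert cp.to_newick(t1) == cp.to_newick(t2)

    def test_agrees_with_dendropy_on_random_matrix(self):
        """Independent NJ implementation recovers the same topology."""
        import dendropy

        rng = np.random.default_rng(21)
        labels = [f"t{i}" for i in range(6)]
        true_tree = random_tree(labels, rng)
        paths = tree_path_distances(true_tree)
        n = len(labels)
        cells = np.zeros((n, n))
        for (a, b), d in paths.items():
            i, j = labels.index(a), labels.index(b)
            cells[i, j] = cells[j, i] = d
        ours = cp.nj_tree(_dist(pd.DataFrame(cells, index=labels, columns=labels)))
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(cells[i, j]) for j in range(n))
            for i in range(n)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=",")
        dp_tree = pdm.nj_tree()
        dp_splits = set()
        taxa = frozenset(labels)
        anchor = min(labels)
        for edge in dp_tree.preorder_edge_iter():
            head = edge.head_node
            clade = frozenset(t.taxon.label for t in head.leaf_iter())
            if 1 < len(clade) < n - 1:
                side = clade if anchor not in clade else taxa - clade
                if 1 < len(side) < n - 1:
                    dp_splits.add(side)
        assert bipartitions(ours) == dp_splits

    def test_missing_cell_is_error(self):
        df = pd.DataFrame(
            [[0.0, np.nan, 0.5], [np.nan, 0.0, 0.6], [0.5, 0.6, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        with pytest.raises(CladepanError):
            cp.nj_tree(_dist(df))


class TestRooting:
    def _tree(self):
        df = pd.DataFrame(
            [[0.0, 0.2, 0.7, 0.8],
             [0.2, 0.0, 0.7, 0.8],
             [0.7, 0.7, 0.0, 0.3],
             [0.8, 0.8, 0.3, 0.0]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        return cp.nj_tree(_dist(df))

    def test_outgroup_is_child_of_root(self):
        rooted = cp.root_tree(self._tree(), "D")
        assert len(rooted.children) == 2
        names = [c.name for c in rooted.children]
        assert "D" in names

    def test_rerooting_idempotent(self):
        rooted = cp.root_tree(self._tree(), "D")
        again = cp.root_tree(rooted, "D")
        assert cp.to_newick(rooted) == cp.to_newick(again)

    def test_unrooted_reduction_conserved(self):
        unrooted = self._tree()
        rooted = cp.root_tree(unrooted, "D")
        assert bipartitions(rooted) == bipartitions(unrooted)

    def test_absent_label_is_error(self):
        with pytest.raises(CladepanError):
            cp.root_tree(self._tree(), "Z")


class TestBootstrap:
    def _chars(self, columns, genomes=None):
        genomes = genomes or ["a", "b", "c", "d"]
        arr = np.array([list(c) for c in columns]).T
        return CharacterMatrix(
            genomes=genomes, columns=arr,
            provenance=[("x", j) for j in range(arr.shape[1])],
        )

    @staticmethod
    def _tree_like_columns(seed, n=120):
        """Columns drawn from 4 rows related by a tree at modest divergence."""
        rng = np.random.default_rng(seed)
        a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        b = cp.mutate_sequence(a, 0.05, 4.0, rng)
        c = cp.mutate_sequence(a, 0.2, 4.0, rng)
        d = cp.mutate_sequence(c, 0.05, 4.0, rng)
        return ["".join(col) for col in zip(a, b, c, d)]

    def test_unanimous_split_full_support(self):
        # every variant column separates {a,b} from {c,d}
        chars = self._chars(["AAGG"] * 20 + ["AAAA"] * 80)
        tree = cp.bootstrap_support(chars, n_reps=50, rng=np.random.default_rng(0))
        supports = [n.support for n in tree.walk()
                    if not n.is_leaf and n.support is not None]
        assert supports and all(s == 100 for s in supports)

    def test_fixed_seed_reproducible(self):
        chars = self._chars(self._tree_like_columns(5))
        t1 = cp.bootstrap_support(chars, n_reps=20, rng=np.random.default_rng(9))
        t2 = cp.bootstrap_support(chars, n_reps=20, rng=np.random.default_rng(9))
        assert cp.to_newick(t1) == cp.to_newick(t2)

    def test_column_order_invariance(self):
        cols = self._tree_like_columns(6)
        chars1 = self._chars(cols)
        chars2 = self._chars(cols[::-1])
        t1 = cp.bootstrap_support(chars1, n_reps=30, rng=np.random.default_rng(2))
        t2 = cp.bootstrap_support(chars2, n_reps=30, rng=np.random.default_rng(2))
        assert cp.to_newick(t1) == cp.to_newick(t2)


class TestFitch:
    def _tree(self, newick):
        return cp.from_newick(newick)

    def test_constant_columns_score_zero(self):
        chars = CharacterMatrix(
            genomes=["A1", "A2", "G1", "G2"],
            columns=np.array([["A"], ["A"], ["A"], ["A"]]),
            provenance=[("x", 0)],
        )
        tree = self._tree("((A1:1,A2:1):1,(G1:1,G2:1):1);")
        assert cp.fitch_score(tree, chars) == 0

    def test_single_change_column(self):
        chars = CharacterMatrix(
            genomes=["A1", "A2", "G1", "G2"],
            columns=np.array([["A"], ["A"], ["G"], ["G"]]),
            provenance=[("x", 0)],
        )
        tree = self._tree("((A1:1,A2:1):1,(G1:1,G2:1):1);")
        assert cp.fitch_score(tree, chars) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimization(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(6)]
        tree = random_tree(labels, rng)
        symbols = np.array(list("ACGT-"))
        column = symbols[rng.integers(0, 5, 6)]
        chars = CharacterMatrix(
            genomes=labels, columns=column.reshape(-1, 1), provenance=[("x", 0)],
        )
        observed = cp.fitch_score(tree, chars)
        # brute force: assign every internal node every symbol
        internal = [n for n in tree.walk() if not n.is_leaf]
        leaf_state = dict(zip(labels, column))
        best = math.inf
        for assignment in itertools.product("ACGT-", repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assignment)}
            changes = 0
            for node in tree.walk():
                s_node = state[id(node)] if not node.is_leaf else leaf_state[node.name]
                for child in node.children:
                    s_child = (state[id(child)] if not child.is_leaf
                               else leaf_state[child.name])
                    if s_node != s_child:
                        changes += 1
            best = min(best, changes)
        assert observed == best

    def test_leaf_mismatch_is_error(self):
        chars = CharacterMatrix(
            genomes=["A1", "A2"], columns=np.array([["A"], ["G"]]),
            provenance=[("x", 0)],
        )
        tree = self._tree("((A1:1,A2:1):1,(G1:1,G2:1):1);")
        with pytest.raises(CladepanError):
            cp.fitch_score(tree, chars)


class TestCompleteLinkage:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                          index=["r1", "r2", "r3"])
        dendro = cp.complete_linkage_dendrogram(df)
        assert dendro.linkage[0, 2] == 0.0
        assert {int(dendro.linkage[0, 0]), int(dendro.linkage[0, 1])} == {0, 1}

    def test_three_point_hand_example(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0]],
                          index=["p", "q", "r"])
        dendro = cp.complete_linkage_dendrogram(df)
        heights = dendro.merge_heights()
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(math.sqrt(200.0))

    def test_clade_agreement_with_nj(self, family_analysis, ingroup):
        """Complete-linkage on the ternary matrix groups the same clades as
        the trees do."""
        _, ann, truth = ingroup
        table, matrix = family_analysis
        dendro = cp.complete_linkage_dendrogram(matrix.df)
        order = dendro.leaf_order
        clade_of = truth.clade_of
        # every clade occupies one contiguous stretch of the leaf ordering
        positions = {}
        for idx, genome in enumerate(order):
            positions.setdefault(clade_of[genome], []).append(idx)
        for clade, pos in positions.items():
            assert max(pos) - min(pos) + 1 == len(pos), clade
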