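import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from mmpkit import phylo_nj as pn


# ---------------------------------------------------------------------------
# helpers: random additive trees and an exhaustive minimum-evolution oracle
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n):
    """Random unrooted binary tree with uniform branch lengths in [0.1, 1]."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def tip_distances(tree, labels):
    dm = tree.tip_tip_distances()
    return dm.filter(labels).data


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies as edge lists over labelled leaves.

    Nodes are labels (leaves) or ints (internal).  Built by sequential leaf
    insertion: 3 leaves give the single star; each further leaf subdivides
    any existing edge.  Yields (edges, n_nodes) with edges as frozensets.
    """
    a, b, c, *rest = labels
    start = ([(a, 0), (b, 0), (c, 0)], 1)
    stack = [(start, rest)]
    while stack:
        (edges, nint), todo = stack.pop()
        if not todo:
            yield edges
            continue
        leaf, *remaining = todo
        for k, (u, v) in enumerate(edges):
            new = nint
            others = edges[:k] + edges[k + 1:]
            grown = others + [(u, new), (v, new), (leaf, new)]
            stack.append(((grown, nint + 1), remaining))


def least_squares_tree_length(edges, labels, D):
    """Fit branch lengths by least squares on path distances; return total."""
    import networkx as nx

    g = nx.Graph()
    for idx, (u, v) in enumerate(edges):
        g.add_edge(u, v, idx=idx)
    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    index = {l: i for i, l in enumerate(labels)}
    for row, (u, v) in enumerate(pairs):
        path = nx.shortest_path(g, u, v)
        for s, t in zip(path, path[1:]):
            A[row, g.edges[s, t]["idx"]] = 1.0
        y[row] = D[index[u], index[v]]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.clip(lengths, 0, None).sum())


# ---------------------------------------------------------------------------
# trait distance
# ---------------------------------------------------------------------------

class TestTraitDistance:
    def make_table(self, tc, tsn):
        return pd.DataFrame(
            {"group": [f"g{i}" for i in range(len(tc))], "TC": tc, "TSN": tsn}
        )

    def test_single_term_example(self):
        # sigma_TC computed over the table itself; build a 3-group table
        # where two groups differ by exactly one population sd in TC
        df = self.make_table([10.0, 12.0, 11.0], [5.0, 5.0, 5.0 + 1e-9])
        D, labels = pn.trait_distance(df)
        sigma_tc = np.std([10.0, 12.0, 11.0])
        expected = (10.0 - 12.0) ** 2 / sigma_tc**2
        assert D[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_diagonal_zero_and_symmetry(self, rng):
        df = self.make_table(rng.uniform(1, 5, 6), rng.uniform(1800, 2200, 6))
        D, _ = pn.trait_distance(df)
        assert np.all(np.diagonal(D) == 0)
        np.testing.assert_allclose(D, D.T, atol=1e-12)

    def test_matches_bruteforce_double_loop(self, rng):
        tc = rng.uniform(1, 5, 6)
        tsn = rng.uniform(1800, 2200, 6)
        D, _ = pn.trait_distance(self.make_table(tc, tsn))
        s_tc, s_tsn = np.std(tc), np.std(tsn)
        for i in range(6):
            for j in range(6):
                expected = (tc[i] - tc[j]) ** 2 / s_tc**2 + (
                    tsn[i] - tsn[j]
                ) ** 2 / s_tsn**2
                assert D[i, j] == pytest.approx(expected, rel=1e-9)

    def test_zero_sigma_rejected(self):
        df = self.make_table([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="TC"):
            pn.trait_distance(df)

    def test_sample_sigma_option(self, rng):
        tc = rng.uniform(1, 5, 5)
        tsn = rng.uniform(1800, 2200, 5)
        df = self.make_table(tc, tsn)
        D_pop, _ = pn.trait_distance(df)
        D_samp, _ = pn.trait_distance(
            df, pn.TraitDistanceSpec(population_sigma=False)
        )
        ratio = np.std(tc, ddof=0) ** 2 / np.std(tc, ddof=1) ** 2
        assert D_samp[0, 1] < D_pop[0, 1]  # sample sd larger -> smaller D
        assert ratio < 1


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tt = pn.neighbor_joining(D, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tt.tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (3 + 4 - 5))
        assert lengths["b"] == pytest.approx(0.5 * (3 + 5 - 4))
        assert lengths["c"] == pytest.approx(0.5 * (4 + 5 - 3))

    def test_four_taxon_additive_roundtrip(self):
        D = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
        )
        labels = ["a", "b", "c", "d"]
        tt = pn.neighbor_joining(D, labels)
        np.testing.assert_allclose(tip_distances(tt.tree, labels), D, atol=1e-9)

    def test_additive_matrices_recovered(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            truth = random_additive_tree(rng, n)
            labels = [f"t{i}" for i in range(n)]
            D = tip_distances(truth, labels)
            tt = pn.neighbor_joining(D, labels)
            assert tt.tree.compare_rfd(truth) == 0
            np.testing.assert_allclose(tip_distances(tt.tree, labels), D, atol=1e-9)

    def test_agrees_with_skbio_on_noisy_matrices(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 8))
            labels = [f"t{i}" for i in range(n)]
            base = tip_distances(random_additive_tree(rng, n), labels)
            D = base + rng.uniform(0, 0.05, size=base.shape)
            D = 0.5 * (D + D.T)  # bitwise-symmetric by commutativity
            np.fill_diagonal(D, 0.0)
            tt = pn.neighbor_joining(D, labels)
            reference = skbio_nj(DistanceMatrix(D, labels))
            assert tt.tree.compare_rfd(reference) == 0

    def test_leaf_permutation_invariance(self, rng):
        n = 7
        labels = [f"t{i}" for i in range(n)]
        D = tip_distances(random_additive_tree(rng, n), labels)
        perm = rng.permutation(n)
        tt1 = pn.neighbor_joining(D, labels)
        tt2 = pn.neighbor_joining(
            D[np.ix_(perm, perm)], [labels[i] for i in perm]
        )
        assert tt1.tree.compare_rfd(tt2.tree) == 0

    def test_ultrametric_agrees_with_exhaustive_minimum_evolution(self, rng):
        labels = list("abcde")
        for _ in range(5):
            # random ultrametric: comb of coalescence heights
            heights = np.sort(rng.uniform(0.5, 5.0, size=4))
            # build by successive joins at increasing heights
            clusters = [({l}, 0.0) for l in labels]
            D = np.zeros((5, 5))
            idx = {l: i for i, l in enumerate(labels)}
            order = rng.permutation(len(clusters))
            merged = [clusters[i] for i in order]
            for h in heights:
                (s1, _), (s2, _) = merged[0], merged[1]
                for u in s1:
                    for v in s2:
                        D[idx[u], idx[v]] = D[idx[v], idx[u]] = 2 * h
                merged = [(s1 | s2, h)] + merged[2:]
            tt = pn.neighbor_joining(D, labels)
            best_len, best_edges = min(
                (least_squares_tree_length(e, labels, D), e)
                for e in enumerate_unrooted_topologies(labels)
            )
            # render the ME-optimal topology as a TreeNode for RF comparison
            me_tree = edges_to_tree(best_edges)
            assert tt.tree.compare_rfd(me_tree) == 0

    def test_negative_branches_clamped_with_warning(self):
        # non-additive matrix whose NJ solution has a negative branch
        D = np.array(
            [
                [0.0, 2.578, 1.894, 1.034],
                [2.578, 0.0, 1.742, 0.606],
                [1.894, 1.742, 0.0, 0.307],
                [1.034, 0.606, 0.307, 0.0],
            ]
        )
        with pytest.warns(UserWarning, match="clamped"):
            tt = pn.neighbor_joining(D, list("abcd"))
        assert all(t.length >= 0 for t in tt.tree.traverse() if t.length is not None)

    @pytest.mark.parametrize(
        "matrix",
        [
            np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]]),
            np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0]]),
            np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]]),
        ],
    )
    def test_invalid_matrices_rejected(self, matrix):
        with pytest.raises(ValueError):
            pn.neighbor_joining(matrix, list("abc"))

    def test_internal_node_count(self, rng):
        for n in (3, 5, 8):
            labels = [f"t{i}" for i in range(n)]
            D = tip_distances(random_additive_tree(rng, n), labels)
            tt = pn.neighbor_joining(D, labels)
            internal = sum(1 for node in tt.tree.non_tips()) + 1  # + root
            assert internal == n - 2


def edges_to_tree(edges):
    """Convert an edge list over labels/ints to a skbio TreeNode."""
    from collections import defaultdict

    adj = defaultdict(list)
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    root_key = next(k for k in adj if isinstance(k, int))

    def build(node, parent):
        children = [n for n in adj[node] if n != parent]
        tn = TreeNode(name=node if isinstance(node, str) else None, length=1.0)
        tn.extend([build(c, node) for c in children])
        return tn

    return build(root_key, None)


class TestBuildTraitTree:
    def test_outgroup_rooting_keeps_tips(self, rng):
        df = pd.DataFrame(
            {
                "group": [f"g{i}" for i in range(6)],
                "TC": rng.uniform(1, 5, 6),
                "TSN": rng.uniform(1800, 2200, 6),
            }
        )
        tt = pn.build_trait_tree(df, outgroup="g0")
        assert {t.name for t in tt.tree.tips()} == set(df["group"])
        assert tt.newick().endswith(";")
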