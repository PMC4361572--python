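import dendropy
import numpy as np
import pytest

from lineagevar.distances import distance_matrix
from lineagevar.errors import InputError
from lineagevar.njtree import (
    PhyloTree,
    bootstrap_support,
    count_bifurcations,
    nj_build,
    read_newick,
    write_newick,
)

from conftest import make_alignment, make_matrix, random_alignment


def random_binary_tree(rng, n):
    """Random unrooted binary tree with positive branch lengths (dendropy)."""
    taxa = dendropy.TaxonNamespace([f"T{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaves = []
    for i in range(3):
        node = dendropy.Node(taxon=taxa.get_taxon(f"T{i}"))
        tree.seed_node.add_child(node)
        node.edge.length = rng.uniform(0.1, 1.0)
        leaves.append(node)
    edges = [lf.edge for lf in leaves]
    for i in range(3, n):
        edge = edges[rng.integers(0, len(edges))]
        child = edge.head_node
        parent = edge.tail_node
        old_len = edge.length
        split = rng.uniform(0.2, 0.8) * old_len
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = old_len - split
        mid.add_child(child)
        child.edge.length = split
        leaf = dendropy.Node(taxon=taxa.get_taxon(f"T{i}"))
        mid.add_child(leaf)
        leaf.edge.length = rng.uniform(0.1, 1.0)
        edges = [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node]
    return tree


def tree_distance_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(t.label for t in tree.taxon_namespace))
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(tx[labels[i]], tx[labels[j]])
    return make_matrix(labels, d)


def path_distances(ptree):
    return tree_distance_matrix(ptree.tree)


class TestNjBuild:
    def test_two_taxa_split_edge(self):
        t = nj_build(make_matrix(("A", "B"), [[0, 0.4], [0.4, 0]]))
        lengths = {lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()}
        assert lengths == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_three_taxa_closed_form(self):
        d = [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]
        t = nj_build(make_matrix(("A", "B", "C"), d))
        lengths = {lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_worked_example(self):
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = nj_build(make_matrix("ABCD", d))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        lengths = {lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()}
        assert lengths == {
            "A": pytest.approx(1.0),
            "B": pytest.approx(2.0),
            "C": pytest.approx(3.0),
            "D": pytest.approx(4.0),
        }
        internal = [
            nd.edge.length
            for nd in t.tree.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
        ]
        assert internal == [pytest.approx(1.0)]

    @pytest.mark.parametrize("seed", range(12))
    def test_additive_consistency(self, seed):
        """NJ recovers the generating tree exactly from additive distances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        gen = random_binary_tree(rng, n)
        dm = tree_distance_matrix(gen)
        t = nj_build(dm)
        recovered = path_distances(t)
        assert recovered.labels == dm.labels
        assert np.max(np.abs(recovered.d - dm.d)) < 1e-9

    def test_matches_skbio_topology(self, rng):
        """Independent NJ implementation agrees on bipartitions."""
        skbio = pytest.importorskip("skbio")
        gen = random_binary_tree(rng, 9)
        dm = tree_distance_matrix(gen)
        ours = nj_build(dm)
        theirs = skbio.tree.nj(
            skbio.DistanceMatrix(dm.d, ids=list(dm.labels))
        )
        ref = min(dm.labels)
        allset = set(dm.labels)
        their_bps = set()
        for node in theirs.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            side = below if ref not in below else frozenset(allset - below)
            if 2 <= len(side) <= len(allset) - 2:
                their_bps.add(side)
        assert ours.bipartitions() == their_bps

    def test_leaf_order_permutation_invariant_bipartitions(self, rng):
        gen = random_binary_tree(rng, 8)
        dm = tree_distance_matrix(gen)
        perm = list(rng.permutation(len(dm)))
        labels = [dm.labels[i] for i in perm]
        assert nj_build(dm).bipartitions() == nj_build(dm.submatrix(labels)).bipartitions()

    def test_negative_branch_policy(self):
        # strongly non-additive matrix producing a negative NJ branch
        d = [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.05],
             [0.5, 0.5, 0.05, 0]]
        kept = nj_build(make_matrix("ABCD", d), negative_branch_policy="keep")
        clamped = nj_build(make_matrix("ABCD", d))
        kept_lengths = [nd.edge.length for nd in kept.tree.preorder_node_iter()
                        if nd.parent_node]
        clamped_lengths = [nd.edge.length for nd in clamped.tree.preorder_node_iter()
                           if nd.parent_node]
        assert all(x >= 0 for x in clamped_lengths)
        for raw, cl in zip(kept_lengths, clamped_lengths):
            assert cl == (raw if raw >= 0 else pytest.approx(0.0))
        assert kept.bipartitions() == clamped.bipartitions()

    def test_single_taxon_rejected(self):
        with pytest.raises(InputError):
            nj_build(make_matrix(("A",), [[0.0]]))


class TestBootstrap:
    def _block_alignment(self):
        a = "A" * 100 + "C" * 100
        b = "A" * 100 + "D" * 100
        return make_alignment([a] * 5 + [b] * 5,
                              [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)])

    def test_unambiguous_split_full_support(self):
        t = bootstrap_support(self._block_alignment(), n_reps=100, seed=3)
        block = frozenset({"b0", "b1", "b2", "b3", "b4"})
        assert t.supports[block] == 100.0

    def test_seeded_reproducibility(self):
        aln = self._block_alignment()
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        assert t1.supports == t2.supports

    def test_column_permutation_keeps_point_tree(self, rng):
        aln = random_alignment(rng, 6, 80)
        perm = rng.permutation(80)
        shuffled = make_alignment(
            ["".join(r.residues[c] for c in perm) for r in aln.records],
            list(aln.accessions),
        )
        assert (
            nj_build(distance_matrix(aln)).bipartitions()
            == nj_build(distance_matrix(shuffled)).bipartitions()
        )

    def test_support_convergence_on_doubling(self, rng):
        """Doubling replicates moves no support beyond a 3-sigma binomial bound."""
        aln = random_alignment(rng, 8, 120)
        t1 = bootstrap_support(aln, n_reps=100, seed=5)
        t2 = bootstrap_support(aln, n_reps=200, seed=1005)
        for bp, s1 in t1.supports.items():
            s2 = t2.supports[bp]
            pool = (s1 + 2 * s2) / 300.0  # pooled proportion (s in percent)
            bound = 300 * np.sqrt(max(pool * (1 - pool), 1e-4) * (1 / 100 + 1 / 200))
            assert abs(s1 - s2) <= bound

    def test_zero_reps_rejected(self):
        with pytest.raises(InputError):
            bootstrap_support(self._block_alignment(), n_reps=0, seed=0)


class TestNewickIO:
    def test_two_leaf_format(self, tmp_path):
        t = nj_build(make_matrix(("A", "B"), [[0, 0.4], [0.4, 0]]))
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        assert p.read_text().strip() == "(A:0.200000,B:0.200000);"

    def test_round_trip_random_tree(self, rng, tmp_path):
        gen = random_binary_tree(rng, 10)
        t = nj_build(tree_distance_matrix(gen))
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        back = read_newick(p)
        assert back.bipartitions() == t.bipartitions()
        assert np.allclose(
            path_distances(back).d, path_distances(t).d, atol=1e-5
        )

    def test_supports_round_trip(self, tmp_path):
        a = "A" * 60 + "C" * 60
        b = "A" * 60 + "D" * 60
        aln = make_alignment([a] * 4 + [b] * 4,
                             [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
        t = bootstrap_support(aln, n_reps=20, seed=1)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        assert read_newick(p).supports == t.supports

    def test_malformed_newick_rejected(self, tmp_path):
        from lineagevar.errors import NewickParseError

        p = tmp_path / "bad.nwk"
        p.write_text("((A:0.1,B:0.2;")
        with pytest.raises(NewickParseError):
            read_newick(p)


class TestCountBifurcations:
    def test_three_leaf_star(self):
        d = [[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]]
        t = nj_build(make_matrix("ABC", d))
        for leaf in "ABC":
            assert count_bifurcations(t, leaf, "midpoint") == 1

    def test_balanced_eight_leaf_depth(self):
        nwk = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        gen = dendropy.Tree.get(data=nwk, schema="newick")
        t = nj_build(tree_distance_matrix(gen))
        for leaf in "ABCDEFGH":
            assert count_bifurcations(t, leaf, "midpoint") == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_walk_oracle(self, seed):
        """Counts equal an independent graph-walk (BFS) on the rooted clone."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        gen = random_binary_tree(rng, 20)
        t = nj_build(tree_distance_matrix(gen))
        from lineagevar.njtree import _midpoint_rooted

        rooted = _midpoint_rooted(t)
        G = nx.Graph()
        names = {}
        for i, node in enumerate(rooted.preorder_node_iter()):
            names[id(node)] = (
                node.taxon.label if node.is_leaf() else f"int{i}"
            )
            if node.parent_node is not None:
                G.add_edge(names[id(node.parent_node)], names[id(node)])
        root_name = names[id(rooted.seed_node)]
        leaf_names = [lf.taxon.label for lf in rooted.leaf_node_iter()]
        for leaf in leaf_names:
            path = nx.shortest_path(G, root_name, leaf)
            expected = sum(1 for nd in path if nd.startswith("int"))
            assert count_bifurcations(t, leaf, "midpoint") == expected

    def test_unknown_leaf_rejected(self):
        d = [[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]]
        t = nj_build(make_matrix("ABC", d))
        with pytest.raises(InputError):
            count_bifurcations(t, "Z")
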