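"""Similarity networks, neighbor joining, clade placement."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rnrclassify import synth
from rnrclassify.graphs import (
    SSN, PhyloTree, build_ssn, clade_query, components,
    distance_matrix_from_identity, nj_tree,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_additive(rng, n):
    """Random binary tree metric on n leaves, built independently of
    PhyloTree: plain adjacency dicts + path lengths."""
    ids = [f"t{i}" for i in range(n)]
    adj = {i: {} for i in ids}
    active = list(ids)
    counter = itertools.count()
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[int(i)], active[int(j)]
        new = f"x{next(counter)}"
        adj[new] = {}
        for leaf, node in ((a, new), (b, new)):
            w = float(rng.uniform(0.1, 1.0))
            adj[leaf][node] = w
            adj[node][leaf] = w
        active = [c for c in active if c not in (a, b)] + [new]
    w = float(rng.uniform(0.1, 1.0))
    adj[active[0]][active[1]] = w
    adj[active[1]][active[0]] = w

    def path(u, v):
        stack = [(u, None, 0.0)]
        while stack:
            node, prev, d = stack.pop()
            if node == v:
                return d
            for nbr, w in adj[node].items():
                if nbr != prev:
                    stack.append((nbr, node, d + w))
        raise AssertionError

    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = path(ids[i], ids[j])
    return dm, ids


def ls_quartet_oracle(dm):
    """Least-squares fit of all three quartet topologies; returns the best
    split as a frozenset pair-of-pairs."""
    pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    idx = {(i, j): k for k, (i, j) in enumerate(
        (i, j) for i in range(4) for j in range(i + 1, 4))}

    def dist(i, j):
        return dm[min(i, j), max(i, j)]

    best = None
    for (a, b), (c, d) in pairs:
        # edges: 4 pendant + 1 internal
        A = np.zeros((6, 5))
        y = np.zeros(6)
        pend = {a: 0, b: 1, c: 2, d: 3}
        for (i, j), row in idx.items():
            A[row, pend[i]] = 1
            A[row, pend[j]] = 1
            same = {i, j} in ({a, b}, {c, d})
            if not same:
                A[row, 4] = 1
            y[row] = dist(i, j)
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((A @ coef - y) ** 2))
        key = frozenset((frozenset((a, b)), frozenset((c, d))))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, key)
    return best[1]


def nj_quartet_split(tree):
    """The non-trivial split of a 4-leaf NJ tree as index pairs."""
    leaves = sorted(tree.leaves)
    for a, b, _ in tree.edges():
        side = tree.split(a, b)
        if len(side) == 2:
            other = frozenset(tree.leaves) - side
            return frozenset((
                frozenset(leaves.index(x) for x in side),
                frozenset(leaves.index(x) for x in other),
            ))
    raise AssertionError("no internal edge")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        """With three taxa the branch lengths follow the three-point
        formulas l_a = (d_ab + d_ac - d_bc)/2 etc."""
        dab, dac, dbc = 0.6, 1.0, 0.8
        dm = np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]])
        tree = nj_tree(dm, ["a", "b", "c"])
        lengths = {}
        for u, v, l in tree.edges():
            leaf = u if u in tree.leaves else v
            lengths[leaf] = l
        assert lengths["a"] == pytest.approx((dab + dac - dbc) / 2)
        assert lengths["b"] == pytest.approx((dab + dbc - dac) / 2)
        assert lengths["c"] == pytest.approx((dac + dbc - dab) / 2)

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            dm, ids = random_additive(rng, n)
            tree = nj_tree(dm, ids)
            got = tree.leaf_distances()
            for i, a in enumerate(ids):
                for j, b in enumerate(ids):
                    if i < j:
                        assert abs(got[(a, b)] - dm[i, j]) < 1e-9

    def test_quartet_topology_matches_least_squares_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            dm, ids = random_additive(rng, 4)
            tree = nj_tree(dm, ids)
            assert nj_quartet_split(tree) == ls_quartet_oracle(dm)

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check topology and metric against scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        dm, ids = random_additive(rng, 7)
        ours = nj_tree(dm, ids)
        theirs = skbio_nj(DistanceMatrix(dm, ids))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    d_theirs = theirs.find(a).distance(theirs.find(b))
                    assert ours.leaf_distances()[(a, b)] == pytest.approx(d_theirs, abs=1e-6)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0]]), ["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, -1], [-1, 0]]), ["a", "b"])

    def test_newick_round_trips_through_skbio(self):
        skbio = pytest.importorskip("skbio")
        import io
        from skbio import TreeNode

        rng = np.random.default_rng(29)
        dm, ids = random_additive(rng, 6)
        tree = nj_tree(dm, ids)
        parsed = TreeNode.read(io.StringIO(tree.to_newick()))
        assert sorted(t.name for t in parsed.tips()) == sorted(ids)


class TestSSN:
    def test_identical_sequences_collapse_to_single_node(self):
        seqs = {f"s{i}": "MKLVNNPQRSTWMKLVNNPQRSTW" for i in range(5)}
        ssn = build_ssn(seqs)
        assert len(ssn.members) == 1
        assert ssn.graph.number_of_edges() == 0
        comps, singles = components(ssn)
        assert len(comps) == 1 and singles == 1

    def test_unrelated_sequences_stay_singletons(self):
        rng = np.random.default_rng(31)
        seqs = {f"s{i}": "".join(rng.choice(list(AA), 80)) for i in range(2)}
        ssn = build_ssn(seqs, min_score=90.0)
        comps, singles = components(ssn)
        assert len(comps) == 2 and singles == 2

    def test_planted_families_form_components(self):
        """Three families at ~80% within / ~40% between identity: member
        nodes connect within families only."""
        seqs, labels = synth.make_family_set(synth.SynthSpec(
            seed=33, n_families=3, members_per_family=3, family_length=250,
            within_identity=0.80, between_identity=0.40))
        ssn = build_ssn(seqs, min_score=90.0, rep_identity=0.90)
        comps, _ = components(ssn)
        assert len(comps) == 3
        for comp in comps:
            fams = {labels[m] for node in comp for m in ssn.members[node]}
            assert len(fams) == 1

    def test_edge_scores_symmetric(self):
        from rnrclassify.graphs import alignment_score
        rng = np.random.default_rng(37)
        a = "".join(rng.choice(list(AA), 60))
        b = "".join(rng.choice(list(AA), 70))
        assert alignment_score(a, b) == pytest.approx(alignment_score(b, a), abs=1e-9)

    def test_components_partition_nodes(self):
        seqs, _ = synth.make_family_set(synth.SynthSpec(
            seed=39, n_families=2, members_per_family=3, family_length=150))
        ssn = build_ssn(seqs)
        comps, _ = components(ssn)
        all_nodes = sorted(n for c in comps for n in c)
        assert all_nodes == sorted(ssn.graph.nodes)

    def test_empty_graph_components(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        ssn = SSN(graph=g, members={n: [n] for n in g}, min_score=90, rep_identity=0.9)
        comps, singles = components(ssn)
        assert len(comps) == 3 and singles == 3
        g.add_edge("a", "b", score=95.0)
        g.add_edge("b", "c", score=95.0)
        comps, singles = components(ssn)
        assert len(comps) == 1 and singles == 0


def brute_force_monophyly(tree, focal):
    """Enumerate all edge splits and test focal-set monophyly directly."""
    focal = frozenset(focal)
    leaves = frozenset(tree.leaves)
    for a, b, _ in tree.edges():
        side = tree.split(a, b)
        if side == focal or leaves - side == focal:
            return True
    return False


class TestCladeQuery:
    def _tree(self):
        # ((a,b),(c,d),(e,f)) star of cherries with distinct lengths
        t = PhyloTree(leaves=["a", "b", "c", "d", "e", "f"])
        t.add_edge("a", "_u", 0.1); t.add_edge("b", "_u", 0.2)
        t.add_edge("c", "_v", 0.1); t.add_edge("d", "_v", 0.2)
        t.add_edge("e", "_w", 0.1); t.add_edge("f", "_w", 0.2)
        t.add_edge("_u", "_x", 0.3); t.add_edge("_v", "_x", 0.3)
        t.add_edge("_w", "_x", 0.3)
        return t

    def test_cherry_is_monophyletic(self):
        res = clade_query(self._tree(), {"a", "b"})
        assert res["monophyletic"]

    def test_scattered_set_is_not(self):
        res = clade_query(self._tree(), {"a", "c"})
        assert not res["monophyletic"]

    def test_sister_group_labels_reported(self):
        labels = {"a": "F1", "b": "F1", "c": "F2", "d": "F2", "e": "F3", "f": "F3"}
        res = clade_query(self._tree(), {"a", "b"}, labels)
        assert res["monophyletic"]
        assert sorted(tuple(s) for s in res["sister_groups"]) == [("F2",), ("F3",)]

    def test_agrees_with_brute_force_on_random_trees(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            dm, ids = random_additive(rng, n)
            tree = nj_tree(dm, ids)
            k = int(rng.integers(1, n))
            focal = set(rng.choice(ids, size=k, replace=False))
            res = clade_query(tree, focal)
            assert res["monophyletic"] == brute_force_monophyly(tree, focal)

    def test_planted_outgroup_relation_recovered(self):
        """NJ on families with one divergent family: the divergent family is
        monophyletic and its sisters are the remaining families."""
        seqs, labels = synth.make_family_set(synth.SynthSpec(
            seed=43, n_families=3, members_per_family=3, family_length=200,
            within_identity=0.92, between_identity=0.45))
        dm, ids = distance_matrix_from_identity(seqs)
        tree = nj_tree(dm, ids)
        focal = {i for i in ids if labels[i] == "fam0"}
        res = clade_query(tree, focal, labels)
        assert res["monophyletic"]
        sisters = {l for group in res["sister_groups"] for l in group}
        assert sisters <= {"fam1", "fam2"}
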