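"""Sequence similarity networks and neighbor-joining phylogenies.

SSN
---
Nodes are 90%-identity greedy clusters (so each node is a set of
near-identical sequences); for every node pair the representatives are
locally aligned (Smith-Waterman, BLOSUM62) and the raw score is converted
to an "alignment score" in the EFI-EST sense: -log10 of a Karlin-Altschul
E-value, E = K * m * n * exp(-lambda * S), with the standard gapped BLOSUM62
constants lambda = 0.267, K = 0.041.  An edge joins two nodes when the
alignment score meets the threshold (default 90).  Connected components and
singleton counts come from the resulting undirected graph.

Phylogeny
---------
Neighbor joining over a distance matrix, with a fixed tie-break (lowest
(i, j) index pair on equal Q values) for determinism.  On an additive
matrix NJ provably recovers the generating tree, metric included; that is
the correctness oracle used in the tests.  Clade queries answer unrooted
monophyly — does some edge split the leaf set into exactly the focal set
and the rest — and report the label composition of the adjacent subtrees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .align import ScoringConfig, local_align_score
from .curate import greedy_cluster

KA_LAMBDA = 0.267   # gapped BLOSUM62 (open 10 / extend 1) Karlin-Altschul params
KA_K = 0.041


def alignment_score(a: str, b: str, config: ScoringConfig | None = None) -> float:
    """EFI-EST-style score: -log10 E-value of the optimal local alignment."""
    s = local_align_score(a, b, config)
    log10_e = math.log10(KA_K * len(a) * len(b)) - KA_LAMBDA * s / math.log(10)
    return -log10_e


@dataclass
class SSN:
    graph: nx.Graph                      # nodes = representative ids
    members: dict[str, list[str]]        # node -> member sequence ids
    min_score: float
    rep_identity: float

    def node_of(self, seq_id: str) -> str:
        for rep, mem in self.members.items():
            if seq_id in mem:
                return rep
        raise KeyError(seq_id)


def build_ssn(seqs: dict[str, str], min_score: float = 90.0,
              rep_identity: float = 0.90,
              config: ScoringConfig | None = None) -> SSN:
    """Build the representative-node similarity network."""
    if not seqs:
        raise ValueError("need at least one sequence")
    clusters = greedy_cluster(seqs, threshold=rep_identity, coverage=0.0, config=config)
    members = {cl.representative: sorted(cl.members) for cl in clusters}
    g = nx.Graph()
    g.add_nodes_from(members)
    reps = sorted(members)
    for a, b in itertools.combinations(reps, 2):
        score = alignment_score(seqs[a], seqs[b], config)
        if score >= min_score:
            g.add_edge(a, b, score=score)
    return SSN(graph=g, members=members, min_score=min_score, rep_identity=rep_identity)


def components(ssn: SSN) -> tuple[list[set[str]], int]:
    """Connected components ordered by smallest member id; plus the number
    of singleton components."""
    comps = sorted(nx.connected_components(ssn.graph), key=lambda c: min(c))
    singletons = sum(1 for c in comps if len(c) == 1)
    return [set(c) for c in comps], singletons


def write_ssn(ssn: SSN, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for a, b, d in sorted(ssn.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['score']:.2f}\n")
    with open(out / "nodes.tsv", "w") as fh:
        fh.write("node\tmember\n")
        for rep in sorted(ssn.members):
            for m in ssn.members[rep]:
                fh.write(f"{rep}\t{m}\n")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map with branch lengths."""

    adjacency: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    leaves: list[str] = field(default_factory=list)

    def add_edge(self, a: str, b: str, length: float) -> None:
        self.adjacency.setdefault(a, []).append((b, length))
        self.adjacency.setdefault(b, []).append((a, length))

    def edges(self) -> list[tuple[str, str, float]]:
        seen = set()
        out = []
        for a, nbrs in self.adjacency.items():
            for b, l in nbrs:
                if (b, a) not in seen:
                    seen.add((a, b))
                    out.append((a, b, l))
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path-length metric between all leaf pairs."""
        dist: dict[tuple[str, str], float] = {}
        for leaf in self.leaves:
            stack = [(leaf, None, 0.0)]
            while stack:
                node, prev, d = stack.pop()
                if node in self.leaves and node != leaf:
                    dist[(leaf, node)] = d
                for nbr, l in self.adjacency[node]:
                    if nbr != prev:
                        stack.append((nbr, node, d + l))
        return dist

    def split(self, a: str, b: str) -> frozenset[str]:
        """Leaves on the `a` side of edge (a, b)."""
        seen = {b}
        stack = [a]
        side = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in self.leaves:
                side.add(node)
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    stack.append(nbr)
        return frozenset(side)

    def to_newick(self) -> str:
        # root at an arbitrary internal node (or the first leaf for tiny trees)
        internal = [n for n in self.adjacency if n not in self.leaves]
        root = internal[0] if internal else self.leaves[0]

        def sub(node: str, prev: str | None) -> str:
            children = [(n, l) for n, l in self.adjacency[node] if n != prev]
            if not children:
                return node
            parts = [f"{sub(n, node)}:{l:.6f}" for n, l in children]
            return "(" + ",".join(parts) + ")" + ("" if node.startswith("_") else node)

        return sub(root, None) + ";"


def nj_tree(dm: np.ndarray, ids: list[str]) -> PhyloTree:
    """Neighbor joining (Saitou-Nei with the standard Q criterion).

    ``dm`` must be symmetric with zero diagonal.  Ties in the Q matrix are
    broken toward the lowest (i, j) index pair, so the output is
    deterministic.  Negative branch-length estimates are clamped to zero
    (they arise only on non-additive inputs).
    """
    dm = np.asarray(dm, dtype=float)
    n = len(ids)
    if dm.shape != (n, n):
        raise ValueError("matrix/ids shape mismatch")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if np.any(dm < 0):
        raise ValueError("distances must be non-negative")

    tree = PhyloTree(leaves=list(ids))
    if n == 1:
        tree.adjacency[ids[0]] = []
        return tree
    if n == 2:
        tree.add_edge(ids[0], ids[1], dm[0, 1])
        return tree

    active = list(ids)
    d = {(a, b): dm[i, j] for i, a in enumerate(ids) for j, b in enumerate(ids)}
    counter = itertools.count()

    while len(active) > 2:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        a, b = active[i], active[j]
        new = f"_nj{next(counter)}"
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[(a, b)] - la
        tree.add_edge(a, new, max(la, 0.0))
        tree.add_edge(b, new, max(lb, 0.0))
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new, c)] = d[(c, new)] = max(dn, 0.0)
        d[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    a, b = active
    tree.add_edge(a, b, max(d[(a, b)], 0.0))
    return tree


def clade_query(tree: PhyloTree, focal_ids: set[str],
                group_labels: dict[str, str] | None = None) -> dict:
    """Unrooted monophyly of the focal leaves, plus neighboring composition.

    Monophyletic iff some edge splits the leaf set into exactly the focal
    set and its complement.  When it does, ``sister_groups`` lists the label
    composition of each subtree adjacent to the focal clade's attachment
    point (for a leaf-edge attachment, the rest of the tree as one group).
    """
    focal = frozenset(focal_ids)
    if not focal or not focal <= set(tree.leaves):
        raise ValueError("focal_ids must be a non-empty subset of the leaves")
    group_labels = group_labels or {l: l for l in tree.leaves}

    for a, b, _ in tree.edges():
        side = tree.split(a, b)
        if side == focal or (frozenset(tree.leaves) - side) == focal:
            attach = b if side == focal else a   # node on the non-focal side
            other = a if side == focal else b
            sisters = []
            for nbr, _l in tree.adjacency[attach]:
                if nbr == other:
                    continue
                sub = tree.split(nbr, attach)
                labels = sorted({group_labels[x] for x in sub if x in group_labels})
                if labels:
                    sisters.append(labels)
            return {"monophyletic": True, "sister_groups": sisters}
    return {"monophyletic": False, "sister_groups": []}


def distance_matrix_from_identity(seqs: dict[str, str],
                                  config: ScoringConfig | None = None
                                  ) -> tuple[np.ndarray, list[str]]:
    """Normalized alignment dissimilarity (1 - pairwise identity) for NJ."""
    from .align import percent_identity

    ids = sorted(seqs)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - percent_identity(seqs[ids[i]], seqs[ids[j]], config=config)
            dm[i, j] = dm[j, i] = d
    return dm, ids
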