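"""Distance-tree construction: neighbor joining and BioNJ.

Both methods agglomerate a distance matrix with the Q-criterion

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

joining the minimizing pair (ties broken lexicographically by cluster label,
where a cluster is labelled by its smallest leaf name).  They differ only in
the matrix reduction: classic NJ averages the two distances, while BioNJ
uses the variance-weighted update of Gascuel's method, with pair variances
modelled proportional to distances (the proportionality constant cancels in
the weight), which minimizes the variance of the reduced matrix.  On an
additive (tree-like) matrix the two are identical and both are consistent.

Trees are returned as unrooted :class:`dendropy.Tree` objects with a
degree-3 seed node; negative branch-length estimates are kept by default so
the algorithm's raw output is testable, with ``clamp_negative`` to floor
them at zero.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .popgen import DistanceMatrix

__all__ = [
    "nj_tree",
    "bionj_tree",
    "rf_distance",
    "is_clan",
    "random_binary_tree",
    "distance_matrix_from_tree",
]


def _check_matrix(d: DistanceMatrix) -> np.ndarray:
    m = np.asarray(d.values, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("distance matrix contains non-finite values")
    if not np.allclose(m, m.T):
        raise ValueError("distance matrix is not symmetric")
    return m.copy()


def _agglomerate(d: DistanceMatrix, bionj: bool, clamp_negative: bool) -> dendropy.Tree:
    m = _check_matrix(d)
    names = list(d.names)
    n = len(names)
    tns = dendropy.TaxonNamespace(names)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes = []
    for name in names:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        nodes.append(node)
    labels = list(names)  # cluster label = smallest leaf name inside

    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        # a single edge of total length d; dendropy needs a degree-2 seed,
        # so the length is split across the two leaf edges
        root = dendropy.Node()
        half = m[0, 1] / 2.0
        for node in nodes:
            node.edge.length = half
            root.add_child(node)
        tree.seed_node = root
        tree.is_rooted = False
        return tree

    variance = m.copy() if bionj else None

    def set_len(node, length):
        node.edge.length = max(0.0, length) if clamp_negative else length

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = m.sum(axis=1)
        q = (r - 2) * m - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break: lexicographically smallest label pair
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(cand, key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))))
        dij = m[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        new = dendropy.Node()
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        new.add_child(nodes[i])
        new.add_child(nodes[j])

        others = [k for k in range(r) if k not in (i, j)]
        if bionj:
            vij = variance[i, j]
            if vij > 0:
                lam = 0.5 + (
                    sum(variance[j, k] - variance[i, k] for k in others)
                    / (2.0 * (r - 2) * vij)
                )
                lam = min(1.0, max(0.0, lam))
            else:
                lam = 0.5
            new_d = lam * (m[i, others] - li) + (1 - lam) * (m[j, others] - lj)
            new_v = (
                lam * variance[i, others]
                + (1 - lam) * variance[j, others]
                - lam * (1 - lam) * vij
            )
        else:
            new_d = 0.5 * (m[i, others] + m[j, others] - dij)
            new_v = None

        keep = np.array(others)
        m = m[np.ix_(keep, keep)]
        m = np.pad(m, ((0, 1), (0, 1)))
        m[-1, :-1] = new_d
        m[:-1, -1] = new_d
        if bionj:
            variance = variance[np.ix_(keep, keep)]
            variance = np.pad(variance, ((0, 1), (0, 1)))
            variance[-1, :-1] = new_v
            variance[:-1, -1] = new_v
        nodes = [nodes[k] for k in others] + [new]
        labels = [labels[k] for k in others] + [min(labels[i], labels[j])]

    # final 3-node star: solve the three leaf edges exactly
    root = dendropy.Node()
    (a, b, c) = (m[0, 1], m[0, 2], m[1, 2])
    lens = ((a + b - c) / 2.0, (a + c - b) / 2.0, (b + c - a) / 2.0)
    for node, length in zip(nodes, lens):
        set_len(node, length)
        root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def nj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> dendropy.Tree:
    """Classic Saitou–Nei neighbor joining."""
    return _agglomerate(d, bionj=False, clamp_negative=clamp_negative)


def bionj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> dendropy.Tree:
    """BioNJ: neighbor joining with variance-weighted matrix reduction."""
    return _agglomerate(d, bionj=True, clamp_negative=clamp_negative)


def _common_namespace(t1: dendropy.Tree, t2: dendropy.Tree):
    tns = dendropy.TaxonNamespace()
    c1 = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    c2 = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick",
        taxon_namespace=tns, preserve_underscores=True,
    )
    c1.is_rooted = False
    c2.is_rooted = False
    labels1 = {leaf.taxon.label for leaf in c1.leaf_node_iter()}
    labels2 = {leaf.taxon.label for leaf in c2.leaf_node_iter()}
    if labels1 != labels2:
        raise ValueError(
            f"leaf sets differ: {sorted(labels1 ^ labels2)} not shared"
        )
    return c1, c2


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric difference of non-trivial bipartitions."""
    c1, c2 = _common_namespace(t1, t2)
    c1.encode_bipartitions()
    c2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(c1, c2))


def is_clan(tree: dendropy.Tree, names) -> bool:
    """True if the named leaves can be split from the rest by one edge cut.

    On an unrooted tree this asks whether {names | rest} is a bipartition of
    the tree (degenerate subsets — empty, single leaf, all leaves, or all but
    one — are clans trivially).
    """
    clone = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        preserve_underscores=True,
    )
    clone.is_rooted = False
    all_leaves = {leaf.taxon.label for leaf in clone.leaf_node_iter()}
    target = set(names)
    if not target <= all_leaves:
        raise ValueError(f"unknown leaves: {sorted(target - all_leaves)}")
    if len(target) <= 1 or len(all_leaves - target) <= 1:
        return True
    clone.encode_bipartitions()
    for bipartition in clone.bipartition_encoding:
        split = {
            t.label
            for t in clone.taxon_namespace.bitmask_taxa_list(
                bipartition.split_bitmask
            )
        }
        if split == target or split == (all_leaves - target):
            return True
    return False


def random_binary_tree(
    taxa: list[str], rng: np.random.Generator,
    min_blen: float = 0.05, max_blen: float = 1.0,
) -> dendropy.Tree:
    """Random unrooted binary tree with uniform branch lengths.

    Built by random sequential agglomeration; every topology has positive
    probability.  Used to generate additive matrices for consistency tests.
    """
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    tns = dendropy.TaxonNamespace(list(taxa))
    active = []
    for name in taxa:
        node = dendropy.Node(taxon=tns.get_taxon(name))
        node.edge.length = float(rng.uniform(min_blen, max_blen))
        active.append(node)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        new = dendropy.Node()
        new.add_child(active[i])
        new.add_child(active[j])
        new.edge.length = float(rng.uniform(min_blen, max_blen))
        active = [a for k, a in enumerate(active) if k not in (i, j)] + [new]
    root = dendropy.Node()
    for node in active:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def distance_matrix_from_tree(tree: dendropy.Tree) -> DistanceMatrix:
    """Additive (path-length) distance matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    names = [t.label for t in taxa]
    n = len(names)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(names, values)
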