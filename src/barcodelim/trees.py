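"""Distance-based trees: neighbor-joining, UPGMA, branching times.

NJ follows the Saitou-Nei agglomeration with two determinism policies pinned
down: ties in the Q criterion break on the lowest current (i, j) index pair,
and a negative branch length is clamped to zero with the clamped amount
absorbed by its sister edge (so the joined pair's distance is preserved).
UPGMA supplies the ultrametric trees the single-threshold GMYC stage needs
when no externally dated tree is given.
"""

from __future__ import annotations

import numpy as np
import dendropy
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core_io import PhyloTree, ValidationError
from .distances import DistanceMatrix


def _require_defined(dm: DistanceMatrix) -> np.ndarray:
    d = dm.d.copy()
    if np.isnan(d).any():
        i, j = np.argwhere(np.isnan(d))[0]
        raise ValidationError(
            f"undefined (saturated) distance between {dm.ids[i]!r} and "
            f"{dm.ids[j]!r}; tree building requires defined distances"
        )
    return d


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Returns the unrooted NJ tree represented with an arbitrary root (the last
    agglomerated node); ``is_ultrametric`` will generally be False.
    """
    n = len(dm)
    if n < 3:
        raise ValidationError("neighbor joining needs >=3 taxa")
    d = _require_defined(dm)

    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    for sid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(node)

    active = list(range(n))
    d = d.astype(float)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) index pair on ties: argmin of flattened row-major
        # scan is exactly lexicographic order
        flat = np.argmin(q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = sub[ai, aj]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        # reduced distances can themselves dip below 0 on noisy matrices
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)

        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = np.full(d.shape[0] + 1, 0.0)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    # graft the remaining node onto the other with the full leftover distance
    u, v = active
    if not nodes[u].is_leaf():
        root, child = nodes[u], nodes[v]
    else:
        root, child = nodes[v], nodes[u]
    root.add_child(child)
    child.edge.length = float(max(d[u, v], 0.0))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    return PhyloTree(tree)


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage (UPGMA) tree; node heights are half the merge distance.

    The result is ultrametric by construction and asserted to be so.
    """
    n = len(dm)
    if n < 2:
        raise ValidationError("UPGMA needs >=2 taxa")
    d = _require_defined(dm)
    taxa = dendropy.TaxonNamespace(dm.ids)

    if n == 2:
        root = dendropy.Node()
        for sid in dm.ids:
            leaf = dendropy.Node(taxon=taxa.get_taxon(sid))
            leaf.edge.length = d[0, 1] / 2.0
            root.add_child(leaf)
        ptree = PhyloTree(dendropy.Tree(taxon_namespace=taxa, seed_node=root))
        assert ptree.is_ultrametric
        return ptree

    Z = linkage(squareform(d, checks=False), method="average")
    nodes: list[dendropy.Node] = []
    heights: list[float] = []
    for sid in dm.ids:
        nodes.append(dendropy.Node(taxon=taxa.get_taxon(sid)))
        heights.append(0.0)
    for a, b, dist, _ in Z:
        a, b = int(a), int(b)
        h = dist / 2.0
        parent = dendropy.Node()
        for child_idx in (a, b):
            child = nodes[child_idx]
            child.edge.length = max(h - heights[child_idx], 0.0)
            parent.add_child(child)
        nodes.append(parent)
        heights.append(h)
    ptree = PhyloTree(dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[-1]))
    assert ptree.is_ultrametric, "UPGMA output must be ultrametric"
    return ptree


def node_ages(ptree: PhyloTree) -> dict[dendropy.Node, float]:
    """Age (time before present, tips at 0) of every node of an ultrametric tree."""
    if not ptree.is_ultrametric:
        raise ValidationError("branching times require an ultrametric tree")
    depths = {}
    for node in ptree.tree.preorder_node_iter():
        parent_depth = depths.get(node.parent_node, 0.0)
        depths[node] = parent_depth + (node.edge.length or 0.0)
    tip_depth = max(depths[lf] for lf in ptree.tree.leaf_node_iter())
    return {
        node: max(tip_depth - depth, 0.0)
        for node, depth in depths.items()
        if not node.is_leaf()
    }


def branching_times(ptree: PhyloTree) -> list[float]:
    """Internal-node times before present, most ancient first (n_leaves - 1)."""
    ages = sorted(node_ages(ptree).values(), reverse=True)
    return [float(a) for a in ages]


def patristic_matrix(ptree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = ptree.tree.phylogenetic_distance_matrix()
    labels = sorted(ptree.leaf_labels)
    taxa = {t.label: t for t in ptree.tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[a], taxa[labels[j]])
    return DistanceMatrix(ids=labels, d=d,
                          comparable_sites=np.full((n, n), -1, dtype=int))


def cut_ultrametric(ptree: PhyloTree, age: float) -> list[frozenset[str]]:
    """Groups of leaves below each lineage crossing the given age."""
    ages = node_ages(ptree)
    root = ptree.tree.seed_node
    if age >= ages[root]:
        return [frozenset(ptree.leaf_labels)]
    groups: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        node_age = 0.0 if node.is_leaf() else ages[node]
        if node_age <= age:
            groups.append(frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            ))
        else:
            for child in node.child_nodes():
                walk(child)

    walk(root)
    return groups
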