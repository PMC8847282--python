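"""Rooted-tree utilities: Newick I/O, geometry, monophyly, and a UPGMA builder.

Trees are DendroPy :class:`~dendropy.Tree` objects throughout. Node *heights*
are measured from the tips (height 0) upward — the natural axis for
time-threshold delimitation, where thresholds are times before present.
External chronograms carry rounding, so ultrametricity checks use a relative
tolerance (default 1e-3 of tree height).
"""

from __future__ import annotations


import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

DEFAULT_REL_TOL = 1e-3


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths; validate tip uniqueness."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True, rooting="force-rooted")
    except Exception as exc:
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return _validate(tree)


def tree_from_string(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True, rooting="force-rooted")
    except Exception as exc:
        raise ValueError(f"could not parse Newick string: {exc}") from exc
    return _validate(tree)


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is not None and (not np.isfinite(edge.length) or edge.length < 0):
            raise ValueError("branch lengths must be finite and non-negative")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip()


def write_newick_file(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    """Distance of every node from the root (branch-length sum)."""
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_height(tree: dendropy.Tree) -> float:
    depths = _node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = DEFAULT_REL_TOL) -> bool:
    """True iff all root-to-tip path lengths agree within rel_tol x max path."""
    depths = _node_depths(tree)
    tip_depths = [depths[leaf] for leaf in tree.leaf_node_iter()]
    if len(tip_depths) < 2:
        return True
    height = max(tip_depths)
    if height == 0:
        return True
    return (height - min(tip_depths)) <= rel_tol * height


def node_heights(tree: dendropy.Tree, rel_tol: float = DEFAULT_REL_TOL) -> dict:
    """Height (time before present) of every node of an ultrametric tree.

    A node's height is the mean path length to its descendant tips; within
    the ultrametricity tolerance this equals any single path.
    """
    if not is_ultrametric(tree, rel_tol):
        raise ValueError("tree is not ultrametric within tolerance")
    heights = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            heights[node] = float(np.mean(
                [heights[c] + (c.edge.length or 0.0) for c in node.child_nodes()]))
    return heights


def branching_times(tree: dendropy.Tree, rel_tol: float = DEFAULT_REL_TOL) -> list[float]:
    """Internal-node heights, sorted descending (root first)."""
    heights = node_heights(tree, rel_tol)
    times = [h for node, h in heights.items() if not node.is_leaf()]
    return sorted(times, reverse=True)


def is_monophyletic(tree: dendropy.Tree, tip_set) -> bool:
    """True iff some clade's tip set equals ``tip_set`` exactly."""
    tip_set = set(tip_set)
    if not tip_set:
        raise ValueError("tip_set must be non-empty")
    known = set(tip_labels(tree))
    unknown = tip_set - known
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(tip_set) == 1:
        return True
    # direct postorder scan; avoids bipartition/rooting machinery
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if below[node] == tip_set:
            return True
    return False


def upgma(dmat: DistanceMatrix) -> dendropy.Tree:
    """UPGMA tree from a distance matrix; merge heights are half the average
    inter-cluster distance, so the result is ultrametric by construction."""
    ids = list(dmat.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("UPGMA requires at least two taxa")
    Z = linkage(squareform(dmat.data, checks=False), method="average")
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    heights = []
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        heights.append(0.0)
    for a, b, dist, _count in Z:
        left, right = nodes[int(a)], nodes[int(b)]
        h = dist / 2.0
        parent = dendropy.Node()
        left.edge.length = h - heights[int(a)]
        right.edge.length = h - heights[int(b)]
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
        heights.append(h)
    tree.seed_node = nodes[-1]
    tree.is_rooted = True
    return tree
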