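"""Phylogenetic tree helpers built on dendropy.

Trees are kept as :class:`dendropy.Tree` objects throughout the package,
rooted as written, with tip labels matching the community table's taxon
IDs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .errors import ValidationError


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (``None`` lengths count as zero)."""
    return float(
        sum(e.length for e in tree.preorder_edge_iter() if e.length is not None)
    )


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (cophenetic) distance matrix between all tips.

    Distances are sums of branch lengths along the path joining two tips.
    Computed by a single postorder sweep: each internal node combines the
    root-ward distances of the tip sets descending from each pair of its
    children.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    dist = np.zeros((n, n), dtype=float)
    # node -> {tip index: distance from node to that tip}
    below: dict[int, dict[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {index[id(node)]: 0.0}
            continue
        children = node.child_nodes()
        merged: dict[int, float] = {}
        child_maps = []
        for child in children:
            edge = child.edge.length
            if edge is None:
                edge = 0.0
            cmap = {tip: d + edge for tip, d in below.pop(id(child)).items()}
            child_maps.append(cmap)
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for ti, di in child_maps[a].items():
                    for tj, dj in child_maps[b].items():
                        dist[ti, tj] = dist[tj, ti] = di + dj
        for cmap in child_maps:
            merged.update(cmap)
        below[id(node)] = merged
    return pd.DataFrame(dist, index=labels, columns=labels)


def faith_pd(tree: dendropy.Tree, present: set[str], include_root_path: bool = True) -> float:
    """Faith's phylogenetic diversity of the taxa in ``present``.

    Sum of branch lengths of the minimal subtree spanning the present tips.
    With ``include_root_path`` (default) the subtree is anchored at the
    tree's root, so the stem lineage(s) joining the present tips to the
    root contribute — the common default of phylogenetic-diversity tools.
    With it off, only branches on paths *between* present tips count.
    """
    labels = set(tip_labels(tree))
    missing = present - labels
    if missing:
        raise ValidationError(f"taxa absent from tree: {sorted(missing)}")
    if not present:
        return 0.0
    # number of present tips below each edge
    counts: dict[int, int] = {}
    pd_sum = 0.0
    n_present = len(present)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in present else 0
        else:
            c = sum(counts.pop(id(ch)) for ch in node.child_nodes())
        counts[id(node)] = c
        length = node.edge.length or 0.0
        if c == 0:
            continue
        if include_root_path:
            pd_sum += length
        elif 0 < c < n_present:
            pd_sum += length
    return float(pd_sum)


def prune_to_taxa(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    """Return a deep copy of ``tree`` pruned to the tips in ``keep``."""
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    return pruned
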