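"""Mitotype clustering from binary marker bands.

Each PCR marker band is a unit character scored 1/0 per line; lines are
clustered by neighbour joining on a binary distance matrix.  The default
metric is simple matching (fraction of markers that differ — shared
absence counts, appropriate for dominant agarose-band markers); Jaccard is
available for presence-weighted analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

__all__ = [
    "binary_distance_matrix",
    "nj_tree",
    "to_newick",
    "is_monophyletic",
]


def binary_distance_matrix(
    matrix: pd.DataFrame, metric: str = "simple_matching"
) -> DistanceMatrix:
    """Pairwise binary distances between lines (rows of ``matrix``).

    simple_matching: (# mismatching markers) / (# markers)
    jaccard:         1 − |intersection| / |union| of present markers
    """
    if matrix.shape[1] == 0:
        raise ValueError("zero markers")
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 lines")
    values = matrix.to_numpy(dtype=int)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("marker matrix entries must be 0/1")
    if len(set(matrix.index)) != len(matrix.index):
        raise ValueError("duplicate line labels")
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = values[i], values[j]
            if metric == "simple_matching":
                dist = float((a != b).sum()) / values.shape[1]
            elif metric == "jaccard":
                union = ((a == 1) | (b == 1)).sum()
                inter = ((a == 1) & (b == 1)).sum()
                dist = 1.0 - inter / union if union else 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=list(matrix.index))


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Unrooted neighbour-joining tree with canonicalised child order.

    Negative branch lengths (an NJ artefact on noisy matrices) are clamped
    to zero; children are sorted by their smallest tip label so the same
    matrix always yields the same Newick string.
    """
    if distances.shape[0] < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    tree = nj(distances)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    # NJ roots arbitrarily at its final join; reroot at the neighbour of the
    # alphabetically first tip so equal matrices give equal Newick strings
    first = tree.find(min(t.name for t in tree.tips()))
    if first.parent is not None and first.parent.parent is not None:
        tree = first.parent.unrooted_copy()
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    _canonicalize(tree)
    return tree


def _canonicalize(tree: TreeNode) -> None:
    def min_tip(node: TreeNode) -> str:
        return min(t.name for t in node.tips()) if node.children else node.name

    for node in tree.postorder():
        if node.children:
            node.children.sort(key=min_tip)


def to_newick(tree: TreeNode) -> str:
    from io import StringIO

    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def is_monophyletic(tree: TreeNode, labels: set[str]) -> bool:
    """Whether ``labels`` form one side of some edge of the unrooted tree."""
    all_tips = {t.name for t in tree.tips()}
    labels = set(labels)
    if not labels <= all_tips:
        raise ValueError("labels not all present in tree")
    if labels in (set(), all_tips):
        return True
    for node in tree.traverse():
        if node.is_tip():
            clade = {node.name}
        else:
            clade = {t.name for t in node.tips()}
        if clade == labels or clade == all_tips - labels:
            return True
    return False
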