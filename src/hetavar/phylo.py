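"""Distance trees with bootstrap support.

Trees are neighbor-joining trees on gap-excluded distances — exact on
additive matrices and topologically adequate for the questions asked of
them here (do subfamilies separate; does a distant ortholog fall outside
the ingroup).  Bootstrap support resamples MSA columns with replacement,
rebuilds the p-distance matrix and the NJ tree per replicate, and reports
the percentage of replicates containing each internal bipartition of the
full-data tree.  Newick export carries supports as internal-node labels,
compatible with external ML tools.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj

from .align import DistanceMatrix, MultipleAlignment, matrix_p_distances
from .errors import AnalysisError

DEFAULT_REPLICATES = 1000


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch-length estimates clamp to 0."""
    if len(dm.ids) < 3:
        raise AnalysisError("neighbor joining needs at least 3 taxa")
    tree = nj(dm.to_skbio())  # skbio disallows negative branch lengths
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not
    containing the lexicographically smallest leaf."""
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def has_split(tree: TreeNode, group) -> bool:
    """True when the tree contains the bipartition separating ``group``."""
    leaves = {t.name for t in tree.tips()}
    group = frozenset(group)
    anchor = min(leaves)
    if anchor in group:
        group = frozenset(leaves - group)
    return group in bipartitions(tree)


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | None = None,
) -> TreeNode:
    """NJ tree from the MSA with bootstrap supports on internal nodes.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate rebuilds the pairwise-deletion p-distance matrix and its NJ
    tree.  Internal nodes of the full-data tree are labelled with the
    percentage of replicates containing their bipartition.  Degenerate
    inputs (all-identical sequences, star-like trees) are flagged on the
    returned tree as ``tree.degenerate``.
    """
    if n_replicates < 1:
        raise AnalysisError("need at least 1 bootstrap replicate")
    if len(msa.ids) < 4:
        raise AnalysisError("bootstrap needs an MSA with at least 4 rows")
    rng = np.random.default_rng(seed)
    mat = msa.matrix()
    L = mat.shape[1]

    full = _tree_from_matrix(mat, msa.ids)
    target = bipartitions(full)
    hits = {s: 0 for s in target}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = _tree_from_matrix(mat[:, cols], msa.ids)
        if rep is None:
            continue
        found = bipartitions(rep)
        for s in target:
            if s in found:
                hits[s] += 1

    leaves = {t.name for t in full.tips()}
    anchor = min(leaves)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(leaves - side)
        if side in hits:
            node.name = f"{100.0 * hits[side] / n_replicates:g}"
    full.degenerate = bool(not target or np.allclose(matrix_p_distances(mat), 0.0))
    return full


def _tree_from_matrix(mat: np.ndarray, ids) -> TreeNode | None:
    data = matrix_p_distances(mat)
    if np.isnan(data).any():
        return None
    return nj(SkbioDM(data, ids=list(ids)))
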