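"""Independent reference implementations used only by the tests.

These deliberately share no code with the package: alignment scores come
from exhaustive enumeration of alignment paths, clustering from scipy's
hierarchical machinery, and additive trees from explicit path-length
construction.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> float:
    """Maximum global alignment score by enumerating every alignment path.

    An alignment is a sequence of moves (diag, up, left) consuming both
    inputs; each maximal run of L same-direction gap moves costs
    ``gap_open + (L-1) * gap_extend``.  Exponential — use only for short
    sequences.
    """
    best = -np.inf
    stack = [(0, 0, 0.0, " ")]  # i, j, score so far, previous move
    while stack:
        i, j, score, prev = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            if a[i] == "N" or b[j] == "N":
                s = 0.0
            stack.append((i + 1, j + 1, score + s, "M"))
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open
            stack.append((i + 1, j, score + cost, "U"))
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open
            stack.append((i, j + 1, score + cost, "L"))
    return float(best)


def scipy_complete_linkage(ids, dist_matrix: np.ndarray, threshold: float):
    """Partition via scipy complete linkage cut at the threshold; returns a
    set of frozensets of ids."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    condensed = squareform(dist_matrix, checks=False)
    Z = linkage(condensed, method="complete")
    flat = fcluster(Z, t=threshold, criterion="distance")
    groups: dict[int, set] = {}
    for rid, c in zip(ids, flat):
        groups.setdefault(c, set()).add(rid)
    return {frozenset(g) for g in groups.values()}


def random_additive_tree(rng, n_leaves: int):
    """Random binary tree with positive branch lengths; returns (children,
    lengths, root, leaf names).  Nodes are ints; leaves are 0..n-1."""
    nodes = list(range(n_leaves))
    lengths = {}
    children = {}
    next_id = n_leaves
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = next_id
        next_id += 1
        children[parent] = (a, b)
        lengths[a] = float(rng.uniform(0.05, 1.0))
        lengths[b] = float(rng.uniform(0.05, 1.0))
        nodes = [x for x in nodes if x not in (a, b)] + [parent]
    root = nodes[0]
    return children, lengths, root


def additive_distance_matrix(children, lengths, root, n_leaves: int) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of the tree."""
    paths = {}

    def walk(node, depth, path):
        if node < n_leaves:
            paths[node] = dict(path)
            return
        for child in children[node]:
            path[child] = depth + lengths[child]
            walk(child, depth + lengths[child], path)
            del path[child]

    # record, for each leaf, the cumulative depth of every edge on its path
    def collect(node, acc):
        if node < n_leaves:
            paths[node] = list(acc)
            return
        for child in children[node]:
            collect(child, acc + [child])

    collect(root, [])
    D = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        pi, pj = paths[i], paths[j]
        shared = 0
        for a, b in zip(pi, pj):
            if a == b:
                shared += 1
            else:
                break
        d = sum(lengths[e] for e in pi[shared:]) + sum(lengths[e] for e in pj[shared:])
        D[i, j] = D[j, i] = d
    return D


def tree_bipartitions(children, root, n_leaves: int) -> set[frozenset[int]]:
    """Non-trivial bipartitions of the generating tree (smaller-side-free
    canonical form anchored at leaf 0's complement)."""
    all_leaves = frozenset(range(n_leaves))

    def leaves_under(node):
        if node < n_leaves:
            return {node}
        a, b = children[node]
        return leaves_under(a) | leaves_under(b)

    splits = set()
    for node in children:
        if node == root:
            continue
        side = frozenset(leaves_under(node))
        if 0 in side:
            side = all_leaves - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(side)
    return splits
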