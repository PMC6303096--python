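"""Neighbor-joining construction, nonparametric bootstrap, midpoint rooting.

Determinism conventions:

* among pairs minimizing the Q-criterion, the lexicographically smallest
  label pair is joined (a cluster is keyed by its smallest leaf name);
* negative intermediate branch lengths are clamped to 0 (no redistribution);
* bootstrap resampling draws alignment columns with replacement from a
  single ``numpy`` RNG stream seeded with one integer.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .distance import DistanceMatrix, _matrix_from_encoded, encode_library
from .errors import BootstrapError, UndefinedDistanceError
from .library_io import ReferenceLibrary
from .tree import Tree, TreeNode

logger = logging.getLogger(__name__)

DEFAULT_REPLICATES = 100


def nj_build(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei agglomeration on a complete distance matrix.

    Returns an unrooted tree (trifurcating root for n >= 3). For n == 2 a
    single-edge tree is returned with a warning.
    """
    if dm.undefined_pairs:
        raise UndefinedDistanceError(
            f"{len(dm.undefined_pairs)} undefined pair(s) in distance matrix",
            pairs=sorted(tuple(sorted(p)) for p in dm.undefined_pairs),
        )
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        logger.warning("NJ on 2 taxa: returning single-edge tree")
        d = float(dm.values[0, 1])
        root = TreeNode()
        root.add_child(TreeNode(dm.labels[0], d / 2.0))
        root.add_child(TreeNode(dm.labels[1], d / 2.0))
        return Tree(root, rooted=False)

    D = dm.values.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(lbl) for lbl in dm.labels]
    keys: List[str] = list(dm.labels)  # smallest leaf name per cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = None
        for ai, aj in cand:
            if ai >= aj:
                continue
            i, j = active[ai], active[aj]
            key = tuple(sorted((keys[i], keys[j])))
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        # distances from new cluster to the remaining ones
        new_idx = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (sub[ai, ak] + sub[aj, ak] - dij)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final three-point join
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = lk
        root.add_child(nodes[k])
    return Tree(root, rooted=False)


def bootstrap_support(
    lib: ReferenceLibrary,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    min_overlap: int = 100,
) -> Tree:
    """NJ tree with percent bootstrap support on its internal edges.

    Alignment columns are resampled with replacement (same length), the K2P
    matrix and NJ tree are recomputed per replicate, and each original-tree
    internal bipartition's recovery frequency is recorded. Replicates that
    produce undefined distances are discarded; if more than half are
    discarded a :class:`BootstrapError` is raised.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    enc = encode_library(lib)
    labels = [r.specimen_id for r in lib.records]
    dm = _matrix_from_encoded(enc, labels, min_overlap)
    tree = nj_build(dm)
    target = tree.bipartition_nodes()
    counts: Dict[FrozenSet[str], int] = {bip: 0 for bip in target.values()}

    rng = np.random.default_rng(seed)
    L = enc.shape[1]
    kept = 0
    for rep in range(replicates):
        cols = rng.integers(0, L, size=L)
        dm_rep = _matrix_from_encoded(enc[:, cols], labels, min_overlap)
        if dm_rep.undefined_pairs:
            logger.warning(
                "bootstrap replicate %d discarded (%d undefined pairs)",
                rep, len(dm_rep.undefined_pairs),
            )
            continue
        kept += 1
        rep_bips = nj_build(dm_rep).bipartitions()
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    if kept < replicates / 2.0:
        raise BootstrapError(
            f"only {kept}/{replicates} bootstrap replicates usable"
        )
    for node, bip in target.items():
        node.support = 100.0 * counts[bip] / kept
    return tree


# ----------------------------------------------------------------------
# midpoint rooting
# ----------------------------------------------------------------------

def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties are broken by the lexicographically smallest (sorted) leaf-name
    pair. If every branch length is zero, the tree is rooted on the edge
    incident to the lexicographically first leaf and a warning is logged.
    """
    work = tree.copy()
    leaves = work.leaves()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting requires at least 2 leaves")
    adj = work.adjacency()

    paths = work.leaf_path_lengths()
    diameter = max(paths.values())
    if diameter <= 0.0:
        logger.warning("all-zero branch lengths: rooting at first leaf's edge")
        first = min(leaves, key=lambda lf: lf.name)
        nbr, length, support = adj[first][0]
        return _reroot_on_edge(work, adj, first, nbr, 0.0, length, support)

    pair = min(k for k, v in paths.items() if v >= diameter - 1e-15)
    name_a, name_b = pair  # sorted names; walk from name_a
    by_name = {lf.name: lf for lf in leaves}
    src, dst = by_name[name_a], by_name[name_b]

    # recover the src -> dst path
    parent: Dict[TreeNode, Optional[Tuple[TreeNode, float, Optional[float]]]] = {src: None}
    stack = [src]
    while stack:
        node = stack.pop()
        if node is dst:
            break
        for nbr, length, support in adj[node]:
            if nbr not in parent:
                parent[nbr] = (node, length, support)
                stack.append(nbr)
    path: List[Tuple[TreeNode, TreeNode, float, Optional[float]]] = []
    cur = dst
    while parent[cur] is not None:
        prev, length, support = parent[cur]
        path.append((prev, cur, length, support))
        cur = prev
    path.reverse()  # edges from src to dst

    half = diameter / 2.0
    walked = 0.0
    for u, v, length, support in path:
        if walked + length >= half - 1e-15:
            offset = min(max(half - walked, 0.0), length)
            return _reroot_on_edge(work, adj, u, v, offset, length, support)
        walked += length
    u, v, length, support = path[-1]  # numeric fallback
    return _reroot_on_edge(work, adj, u, v, length, length, support)


def _reroot_on_edge(
    tree: Tree,
    adj,
    u: TreeNode,
    v: TreeNode,
    dist_from_u: float,
    edge_length: float,
    support: Optional[float],
) -> Tree:
    """Build a rooted tree whose root splits edge (u, v) at ``dist_from_u``."""

    def build(node: TreeNode, avoid: TreeNode) -> TreeNode:
        new = TreeNode(node.name if node.is_leaf else None)
        if not node.is_leaf:
            new.support = None
        for nbr, length, sup in adj[node]:
            if nbr is avoid:
                continue
            child = build(nbr, node)
            child.length = length
            child.support = sup if not nbr.is_leaf else None
            new.add_child(child)
        return new

    root = TreeNode()
    left = build(u, v)
    left.length = dist_from_u
    left.support = support if not u.is_leaf else None
    right = build(v, u)
    right.length = edge_length - dist_from_u
    right.support = support if not v.is_leaf else None
    root.add_child(left)
    root.add_child(right)
    return Tree(root, rooted=True)
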