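"""Lightweight phylogenetic tree structure shared by the I/O and NJ layers.

A :class:`Tree` is stored as a rooted node structure even when it represents
an unrooted tree (``rooted=False``); in that case the root is simply an
arbitrary internal vertex (typically of degree 3) and all topology queries
(bipartitions, path lengths) are root-agnostic.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterator, List, Optional, Set, Tuple


class TreeNode:
    """A node; ``length`` and ``support`` describe the edge to its parent."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = length
        self.support = support
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name!r} {kind} len={self.length}>"


class Tree:
    """Rooted node structure with an explicit ``rooted`` flag."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # ------------------------------------------------------------------
    # topology
    # ------------------------------------------------------------------
    def leaf_sets(self) -> Dict[TreeNode, FrozenSet[str]]:
        """Leaf-name set below every node."""
        sets: Dict[TreeNode, FrozenSet[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.name])
            else:
                acc: Set[str] = set()
                for c in node.children:
                    acc |= sets[c]
                sets[node] = frozenset(acc)
        return sets

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Non-trivial bipartitions, canonicalized as the side NOT containing
        the lexicographically smallest leaf name.

        Trivial splits (a single leaf on either side) are excluded; the two
        root edges of a rooted binary tree induce the same bipartition and
        are deduplicated by the canonical form.
        """
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) < 4:
            return set()
        ref = min(all_leaves)
        sets = self.leaf_sets()
        out: Set[FrozenSet[str]] = set()
        for node, below in sets.items():
            if node is self.root:
                continue
            side = below if ref not in below else all_leaves - below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def bipartition_nodes(self) -> Dict[TreeNode, FrozenSet[str]]:
        """Map each non-root node to the canonical bipartition of its parent
        edge (only non-trivial ones)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves) if all_leaves else None
        sets = self.leaf_sets()
        out: Dict[TreeNode, FrozenSet[str]] = {}
        for node, below in sets.items():
            if node is self.root:
                continue
            side = below if ref not in below else all_leaves - below
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[node] = side
        return out

    # ------------------------------------------------------------------
    # unrooted view
    # ------------------------------------------------------------------
    def adjacency(self) -> Dict[TreeNode, List[Tuple[TreeNode, float, Optional[float]]]]:
        """Undirected adjacency: node -> [(neighbor, edge length, support)]."""
        adj: Dict[TreeNode, List[Tuple[TreeNode, float, Optional[float]]]] = {}
        for node in self.preorder():
            adj.setdefault(node, [])
            for c in node.children:
                adj.setdefault(c, [])
                adj[node].append((c, c.length, c.support))
                adj[c].append((node, c.length, c.support))
        return adj

    def leaf_path_lengths(self) -> Dict[Tuple[str, str], float]:
        """Path-length metric over all unordered leaf pairs (sorted-name keys)."""
        adj = self.adjacency()
        leaves = self.leaves()
        out: Dict[Tuple[str, str], float] = {}
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, length, _ in adj[node]:
                    if nbr not in dist:
                        dist[nbr] = dist[node] + length
                        stack.append(nbr)
            for other in leaves:
                if other is src:
                    continue
                key = tuple(sorted((src.name, other.name)))
                out[key] = dist[other]
        return out

    # ------------------------------------------------------------------
    # serialization / copy
    # ------------------------------------------------------------------
    def to_newick(self, include_support: bool = True) -> str:
        def fmt_support(s: float) -> str:
            if float(s).is_integer():
                return str(int(s))
            return repr(round(float(s), 6))

        def walk(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(walk(c, False) for c in node.children)
                label = ""
                if include_support and node.support is not None and not top:
                    label = fmt_support(node.support)
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.6f}"

        return walk(self.root, True) + ";"

    def copy(self) -> "Tree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.support)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), rooted=self.rooted)
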