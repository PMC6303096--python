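"""Independent brute-force oracles used by the test suite.

Deliberately written without reusing any package internals: plain Python
loops and textbook formulas only, so that agreement with the package is a
real two-route check.
"""

from __future__ import annotations

import math
import random
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"


def k2p_oracle(a: str, b: str) -> Tuple[int, int, int, Optional[float]]:
    """(comparable, transitions, transversions, d) by per-character loop."""
    comparable = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in BASES or y not in BASES:
            continue
        comparable += 1
        if x == y:
            continue
        if (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES):
            ts += 1
        else:
            tv += 1
    if comparable == 0:
        return 0, 0, 0, None
    P = ts / comparable
    Q = tv / comparable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return comparable, ts, tv, None
    return comparable, ts, tv, -0.5 * math.log(w1 * math.sqrt(w2))


# ----------------------------------------------------------------------
# random additive trees (for NJ consistency checks)
# ----------------------------------------------------------------------

class _ONode:
    def __init__(self, name=None, length=0.0):
        self.name = name
        self.length = length
        self.children: List["_ONode"] = []


def random_additive_tree(
    rng: random.Random, n_taxa: int
) -> Tuple[List[str], Dict[Tuple[str, str], float], Set[FrozenSet[str]]]:
    """Random unrooted binary tree with strictly positive branch lengths.

    Returns (labels, path-length metric keyed by sorted label pairs, set of
    non-trivial bipartitions canonicalized as the side without the smallest
    label).
    """
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    nodes = [_ONode(name=lbl) for lbl in labels]
    for node in nodes:
        node.length = rng.uniform(0.1, 2.0)
    pool = nodes[:]
    while len(pool) > 3:
        i = rng.randrange(len(pool))
        a = pool.pop(i)
        j = rng.randrange(len(pool))
        b = pool.pop(j)
        parent = _ONode(length=rng.uniform(0.1, 2.0))
        parent.children = [a, b]
        pool.append(parent)
    root = _ONode()
    root.children = pool

    # leaf sets and pairwise path lengths by recursion
    leafsets: Dict[int, Set[str]] = {}
    depths: Dict[str, Dict[str, float]] = {}

    def walk(node: _ONode) -> Dict[str, float]:
        """leaf name -> distance from this node."""
        if not node.children:
            leafsets[id(node)] = {node.name}
            return {node.name: 0.0}
        merged: Dict[str, float] = {}
        child_maps = []
        for c in node.children:
            cm = {k: v + c.length for k, v in walk(c).items()}
            child_maps.append(cm)
            merged.update(cm)
        leafsets[id(node)] = set(merged)
        for ci in range(len(child_maps) - 1):
            for cj in range(ci + 1, len(child_maps)):
                for la, da in child_maps[ci].items():
                    for lb, db in child_maps[cj].items():
                        key = tuple(sorted((la, lb)))
                        dists[key] = da + db
        return merged

    dists: Dict[Tuple[str, str], float] = {}
    walk(root)

    all_set = frozenset(labels)
    ref = min(labels)
    bips: Set[FrozenSet[str]] = set()

    def collect(node: _ONode):
        for c in node.children:
            below = frozenset(leafsets[id(c)])
            side = below if ref not in below else all_set - below
            if 2 <= len(side) <= len(all_set) - 2:
                bips.add(side)
            collect(c)

    collect(root)
    return labels, dists, bips


def conspecific_stats_oracle(
    pair_dist: Dict[Tuple[str, str], float], ids: List[str]
) -> Tuple[Optional[float], Optional[float]]:
    """(max, mean) over all unordered conspecific pairs; None for <2 ids."""
    vals = []
    for i in range(len(ids) - 1):
        for j in range(i + 1, len(ids)):
            vals.append(pair_dist[tuple(sorted((ids[i], ids[j])))])
    if not vals:
        return None, None
    return max(vals), sum(vals) / len(vals)


def nearest_neighbor_oracle(
    pair_dist: Dict[Tuple[str, str], float],
    species_of: Dict[str, str],
) -> Dict[str, Tuple[str, float]]:
    """Per species: (lexicographically first nearest species, min distance)
    by exhaustive double loop over heterospecific record pairs."""
    species = sorted(set(species_of.values()))
    out = {}
    for sp in species:
        best = math.inf
        best_sp = None
        for a, sa in species_of.items():
            if sa != sp:
                continue
            for b, sb in species_of.items():
                if sb == sp:
                    continue
                d = pair_dist[tuple(sorted((a, b)))]
                if d < best or (d == best and sb < best_sp):
                    best = d
                    best_sp = sb
        out[sp] = (best_sp, best)
    return out
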