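"""Independent oracle implementations used by the test suite only.

These deliberately avoid the package's code paths: a hand-written
newick parser drives the brute-force weighted-UniFrac/Faith-PD branch
sums, a depth-first simple-path search drives the least-cost oracle,
and direct union-model arithmetic drives the variation-partitioning
oracle.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# minimal newick parser (independent of scikit-bio)
# ---------------------------------------------------------------------------

class NwkNode:
    def __init__(self, name=None, length=None):
        self.name = name
        self.length = length
        self.children: list[NwkNode] = []

    def leaves(self):
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def branches(self):
        """All (length, descendant-leaf-set) pairs below this node."""
        out = []
        for c in self.children:
            if c.length is not None:
                out.append((c.length, frozenset(c.leaves())))
            out.extend(c.branches())
        return out


def parse_newick(s: str) -> NwkNode:
    s = s.strip().rstrip(";")
    pos = 0

    def parse_node() -> NwkNode:
        nonlocal pos
        node = NwkNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                assert s[pos] == ")"
                pos += 1
                break
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        if pos > start:
            node.name = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    return parse_node()


def brute_force_weighted_unifrac(newick: str, abund_a: dict, abund_b: dict,
                                 normalized: bool = False) -> float:
    """Sum over every branch of l * |pA - pB| from the newick string."""
    root = parse_newick(newick)
    total_a = sum(abund_a.values()) or 1.0
    total_b = sum(abund_b.values()) or 1.0
    num = den = 0.0
    for length, leafset in root.branches():
        pa = sum(abund_a.get(x, 0) for x in leafset) / total_a
        pb = sum(abund_b.get(x, 0) for x in leafset) / total_b
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    if normalized:
        return num / den if den > 0 else 0.0
    return num


def brute_force_faith_pd(newick: str, present: set) -> float:
    root = parse_newick(newick)
    return sum(length for length, leafset in root.branches()
               if leafset & present)


# ---------------------------------------------------------------------------
# exhaustive simple-path shortest distance
# ---------------------------------------------------------------------------

def exhaustive_shortest_path(nodes, edges, start, goal) -> float:
    """DFS over all simple paths with length pruning.

    ``edges`` maps node -> list of (neighbour, weight).
    """
    best = [np.inf]

    def dfs(node, dist, visited):
        if dist >= best[0]:
            return
        if node == goal:
            best[0] = dist
            return
        for nb, w in edges.get(node, []):
            if nb not in visited:
                dfs(nb, dist + w, visited | {nb})

    dfs(start, 0.0, {start})
    return best[0]


# ---------------------------------------------------------------------------
# direct variation-partitioning arithmetic (2 and 3 sets)
# ---------------------------------------------------------------------------

def varpart3_fractions(r2):
    """Textbook three-set fractions from the 7 union adjusted R2 values.

    ``r2`` keys: 'a','b','c','ab','ac','bc','abc'. Returns the 7 Venn
    fractions keyed by the sets involved.
    """
    out = {}
    out[frozenset("a")] = r2["abc"] - r2["bc"]
    out[frozenset("b")] = r2["abc"] - r2["ac"]
    out[frozenset("c")] = r2["abc"] - r2["ab"]
    out[frozenset("ab")] = r2["ac"] + r2["bc"] - r2["abc"] - r2["c"]
    out[frozenset("ac")] = r2["ab"] + r2["bc"] - r2["abc"] - r2["b"]
    out[frozenset("bc")] = r2["ab"] + r2["ac"] - r2["abc"] - r2["a"]
    out[frozenset("abc")] = (
        r2["abc"] - r2["ab"] - r2["ac"] - r2["bc"]
        + r2["a"] + r2["b"] + r2["c"]
    )
    return out


# ---------------------------------------------------------------------------
# misc small oracles
# ---------------------------------------------------------------------------

def manual_upgma_first_merge(dist: np.ndarray):
    """Index pair of the first UPGMA merge (global minimum)."""
    n = dist.shape[0]
    best, pair = np.inf, None
    for i, j in itertools.combinations(range(n), 2):
        if dist[i, j] < best:
            best, pair = dist[i, j], (i, j)
    return pair


def flood_fill_components(mask: np.ndarray) -> int:
    """4/8-neighbour connected components of a boolean grid (8-neighbour)."""
    seen = np.zeros_like(mask, dtype=bool)
    rows, cols = mask.shape
    n = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                n += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < rows and 0 <= xx < cols
                                    and mask[yy, xx] and not seen[yy, xx]):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
    return n
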