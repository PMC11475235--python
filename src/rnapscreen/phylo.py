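"""Neighbor-joining cladogram over identity-derived distances.

The screen's diversity claim is visual — the selected representatives span
the library's sequence space — so the tree is built on the simple distance
``d = 100 - percent identity`` rather than an evolutionary-model correction:
branch lengths are diversity units, not substitutions per site or time.
Standard NJ agglomeration on the Q-criterion, with deterministic
lexicographic tie-breaking and the usual clamping of negative branch-length
estimates (deficit moved to the sibling branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cluster import IdentityMatrix


@dataclass
class Node:
    name: Optional[str] = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree serialized with a trifurcating (or 2-leaf) root."""

    root: Node

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def total_length(self) -> float:
        def walk(node: Node) -> float:
            return sum(bl + walk(child) for child, bl in node.children)

        return walk(self.root)

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path length between every leaf pair (useful as a test oracle)."""
        dists: dict[tuple[str, str], float] = {}

        def below(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name or "": 0.0}
            sub = []
            for child, bl in node.children:
                m = below(child)
                sub.append({k: v + bl for k, v in m.items()})
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a, da in sub[i].items():
                        for b, db in sub[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for m in sub:
                merged.update(m)
            return merged

        below(self.root)
        return dists


def nj_tree(matrix: IdentityMatrix) -> Tree:
    """Neighbor-joining tree on distances 100 - identity.

    On additive distance matrices the generating tree is recovered exactly.
    Pair choice ties are broken lexicographically by each node's smallest
    descendant label, so the result is invariant to input leaf order.
    """
    ids = list(matrix.ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    D = 100.0 - np.asarray(matrix.values, dtype=float)
    np.fill_diagonal(D, 0.0)

    nodes: list[Node] = [Node(name=i) for i in ids]
    labels: list[str] = list(ids)  # smallest descendant label per active node
    active = list(range(len(ids)))
    dist = {(i, j): D[i, j] for i in range(len(ids)) for j in range(len(ids))}

    def d(i: int, j: int) -> float:
        return dist[(i, j)] if i <= j else dist[(j, i)]

    next_idx = len(ids)
    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        dij = d(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_idx), max(k, next_idx))] = (
                d(i, k) + d(j, k) - dij
            ) / 2
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    if len(active) == 2:
        i, j = active
        half = d(i, j) / 2
        root = Node(children=[(nodes[i], half), (nodes[j], half)])
    else:
        i, j, k = active
        li = (d(i, j) + d(i, k) - d(j, k)) / 2
        lj = (d(i, j) + d(j, k) - d(i, k)) / 2
        lk = (d(i, k) + d(j, k) - d(i, j)) / 2
        root = Node(
            children=[
                (nodes[i], max(li, 0.0)),
                (nodes[j], max(lj, 0.0)),
                (nodes[k], max(lk, 0.0)),
            ]
        )
    return Tree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += -li
        li = 0.0
    if lj < 0:
        li += -lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def write_newick(tree: Tree, path=None) -> str:
    """Newick text with branch lengths; whitespace in labels -> underscores."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            return (node.name or "").replace(" ", "_")
        inner = ",".join(f"{fmt(child)}:{bl:.10g}" for child, bl in node.children)
        return f"({inner})"

    text = fmt(tree.root) + ";"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text + "\n")
    return text
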