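"""Neighbour-joining phylogenetics on amino-acid p-distances.

Saitou–Nei agglomeration with deterministic tie-breaking (smallest (i, j)
index pair on equal Q), negative branch lengths clamped to zero, and
nonparametric bootstrap support by resampling alignment columns.  Distances
default to uncorrected p-distances, adequate for the highly similar
families this package targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class Tree:
    """An unrooted tree stored with an arbitrary trifurcating root."""

    root: Node

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each encoded as the side not containing
        the lexicographically smallest leaf (canonical for unrooted trees)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                side = all_leaves - below if ref in below else below
                out.add(side)
            return below

        walk(self.root)
        return out

    def internal_nodes(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = m


def aa_p_distance(ids: list[str], rows: list[str]) -> DistanceMatrix:
    """Pairwise proportion of differing residues, gap columns deleted pairwise."""
    enc = [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in rows]
    k = len(ids)
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        a, b = enc[i], enc[j]
        both = (a != ord("-")) & (b != ord("-"))
        n = int(both.sum())
        if n == 0:
            raise ValueError(f"no shared columns between {ids[i]} and {ids[j]}")
        d[i, j] = d[j, i] = float((a[both] != b[both]).sum() / n)
    return DistanceMatrix(ids, d)


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining; deterministic and exact on additive inputs.

    Q-matrix ties are broken by the smallest (i, j) index pair; negative
    branch lengths are clamped to zero with a logged warning.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[Node] = [Node(name=i) for i in dist.ids]
    D = dist.matrix.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {a: sum(D[a, b] for b in active if b != a) for a in active}
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                a, b = active[ai], active[bi]
                q = (r - 2) * D[a, b] - sums[a] - sums[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * D[a, b] + (sums[a] - sums[b]) / (2 * (r - 2))
        lb = D[a, b] - la
        new = Node(children=[nodes[a], nodes[b]])
        nodes[a].length = clamp(la)
        nodes[b].length = clamp(lb)
        u = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (a, b):
                continue
            D[u, c] = D[c, u] = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        nodes.append(new)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for x, lx in zip((a, b, c), (la, lb, lc)):
        nodes[x].length = clamp(lx)
    return Tree(root=Node(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_support(ids: list[str], rows: list[str], *, B: int = 100,
                      seed: int | None = None) -> Tree:
    """NJ tree with bootstrap supports (percent) on internal edges.

    Alignment columns are resampled with replacement B times; the support
    of each internal edge of the point-estimate tree is the percentage of
    replicate trees containing the same bipartition.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    tree = neighbor_joining(aa_p_distance(ids, rows))
    arr = np.vstack([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in rows])
    L = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    used = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        sub = arr[:, cols]
        sub_rows = ["".join(map(chr, row)) for row in sub]
        try:
            rep = neighbor_joining(aa_p_distance(ids, sub_rows))
        except ValueError:
            logger.warning("bootstrap replicate degenerate; skipped")
            continue
        used += 1
        for s in rep.splits():
            counts[s] = counts.get(s, 0) + 1

    all_leaves = frozenset(ids)
    ref = min(all_leaves)

    def annotate(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
            side = all_leaves - below if ref in below else below
            node.support = 100.0 * counts.get(side, 0) / max(used, 1)
        return below

    annotate(tree.root)
    return tree


# -- Newick ------------------------------------------------------------------

def _newick(node: Node, *, with_length: bool = True) -> str:
    if node.is_leaf:
        s = node.name or ""
    else:
        s = "(" + ",".join(_newick(c, with_length=with_length) for c in node.children) + ")"
        if node.support is not None:
            s += f"{node.support:g}"
        elif node.name:
            s += node.name
    if with_length and node.length is not None:
        s += f":{node.length:.10g}"
    return s


def to_newick(tree: Tree) -> str:
    return "(" + ",".join(_newick(c) for c in tree.root.children) + ");"


def write_newick(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def _convert(dn: dendropy.Node) -> Node:
    node = Node()
    if dn.taxon is not None:
        node.name = dn.taxon.label
    elif dn.label:
        try:
            node.support = float(dn.label)
        except ValueError:
            node.name = dn.label
    node.length = float(dn.edge.length) if dn.edge.length is not None else 0.0
    node.children = [_convert(c) for c in dn.child_nodes()]
    return node


def read_newick(path_or_string: str | Path) -> Tree:
    """Parse a Newick tree (internal-node labels read as bootstrap supports)."""
    text = str(path_or_string)
    if "(" not in text:
        text = Path(path_or_string).read_text()
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    root = _convert(dt.seed_node)
    return Tree(root=root)
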