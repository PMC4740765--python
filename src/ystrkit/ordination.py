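"""Classical metric MDS and neighbor-joining trees for population
distance matrices, with Newick serialization.

MDS is Torgerson scaling: negative dissimilarities are clamped to zero,
squared, double-centered (B = -1/2 J D2 J) and eigendecomposed; negative
eigenvalues contribute no coordinates but are reported.  Neighbor
joining follows the Saitou-Nei agglomeration with Q-matrix selection and
deterministic tie-breaking (lexicographically lowest label pair), so
repeated runs on tied inputs give identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import NewickParseError, ValidationError
from .structure import DistanceMatrix

__all__ = [
    "MdsSolution",
    "TreeNode",
    "PhyloTree",
    "classical_mds",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]


# ----------------------------------------------------------------------
# Classical (Torgerson) multidimensional scaling
# ----------------------------------------------------------------------

@dataclass
class MdsSolution:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # populations x k, columns by descending eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues, per kept axis


def classical_mds(D: DistanceMatrix, k: int = 2) -> MdsSolution:
    """Embed a dissimilarity matrix into k dimensions.

    Negative entries (possible for R_ST) are clamped to 0 before
    squaring.  Axes with non-positive eigenvalues yield all-zero
    coordinates.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    d = np.maximum(D.values, 0.0)
    n = d.shape[0]
    d2 = d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = min(k, n)
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    positive = np.clip(eigval, 0.0, None)
    total = positive.sum()
    prop = positive[:k] / total if total > 0 else np.zeros(k)
    coords = coords - coords.mean(axis=0)  # numerically re-center
    return MdsSolution(D.labels, coords, eigval, prop)


# ----------------------------------------------------------------------
# Trees
# ----------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an (effectively unrooted) phylogeny.

    ``children`` holds (child, branch_length) pairs; leaves carry a name.
    """

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child, _ in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.walk() if n.is_leaf]

    def _edges(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {}
        for node in self.root.walk():
            for child, length in node.children:
                adj.setdefault(id(node), []).append((id(child), length))
                adj.setdefault(id(child), []).append((id(node), length))
        return adj

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique path between two leaves."""
        by_name = {n.name: id(n) for n in self.root.walk() if n.is_leaf}
        for name in (a, b):
            if name not in by_name:
                raise KeyError(f"no leaf named {name!r}")
        if a == b:
            return 0.0
        adj = self._edges()
        start, goal = by_name[a], by_name[b]
        stack = [(start, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == goal:
                return dist
            for nxt, length in adj.get(node, ()):
                if nxt != prev:
                    stack.append((nxt, dist + length, node))
        raise KeyError("leaves are not connected")  # pragma: no cover


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    ``clamp_negative`` replaces negative branch lengths by zero and
    transfers the deficit to the sibling branch (standard workaround);
    by default negatives are kept as computed.
    """
    n = len(D.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 labels")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=l) for i, l in enumerate(D.labels)}
    keys: dict[int, str] = {i: l for i, l in enumerate(D.labels)}  # tie-break keys
    d: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = float(D.values[i, j])
    active = list(range(n))
    next_id = n

    def dist(i: int, j: int) -> float:
        return d[frozenset((i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        bi = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        if clamp_negative:
            bi, bj = _clamp_pair(bi, bj)
        parent = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        u = next_id
        next_id += 1
        nodes[u] = parent
        keys[u] = min(keys[i], keys[j])
        for k_ in active:
            if k_ not in (i, j):
                d[frozenset((u, k_))] = (dist(i, k_) + dist(j, k_) - dij) / 2
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda i: keys[i])
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root)


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    if bi < 0:
        bj += bi
        bi = 0.0
    if bj < 0:
        bi += bj
        bj = 0.0
    return bi, max(bj, 0.0)


# ----------------------------------------------------------------------
# Newick
# ----------------------------------------------------------------------

def _needs_quoting(name: str) -> bool:
    return any(c in name for c in "(),:;'\" \t\n[]")


def _format_name(name: str) -> str:
    if _needs_quoting(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _format_name(node.name or "")
        inner = ",".join(
            f"{render(child)}:{length!r}" for child, length in node.children
        )
        return f"({inner})" + (_format_name(node.name) if node.name else "")

    return render(tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string; raises :class:`NewickParseError` with the
    offending position on malformed input."""
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError("missing terminating semicolon", len(text))
    pos = 0

    def error(msg: str):
        raise NewickParseError(msg, pos)

    def parse_name() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if pos >= len(s):
                    error("unterminated quoted name")
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
        return 0.0

    def parse_clade() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child, length = parse_clade()
                node.children.append((child, length))
                if pos >= len(s):
                    error("unbalanced parenthesis")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected character {s[pos]!r}")
            name = parse_name()
            node.name = name or None
        else:
            name = parse_name()
            if not name:
                error("expected a label")
            node.name = name
        return node, parse_length()

    root, _ = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        error("trailing content before semicolon")
    return PhyloTree(root)
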