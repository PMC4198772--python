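"""Distance-based phylogenetics: p/Poisson/JC distances, neighbor-joining,
nonparametric bootstrap, and monophyly checks.

This is the placement machinery for asking where a newly recovered element
falls among reference retroviruses: distances are computed from a protein or
nucleotide alignment with pairwise deletion of gap columns, trees are built
with Saitou–Nei neighbor-joining (deterministic tie-breaks; exact on
additive matrices), and clade confidence comes from column-resampled
bootstrap replicates.  Per-gene trees for recombination checks are just
sub-alignments fed through the same functions.  Newick interchange goes
through dendropy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix", "Node", "Tree", "distance_matrix", "nj_tree",
           "bootstrap_support", "check_monophyly", "sub_alignment",
           "read_newick"]

Alignment = dict[str, str]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class Node:
    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored rooted at an arbitrary internal node."""

    root: Node

    def leaves(self) -> list[str]:
        out = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial splits as frozensets of the leaf names below each edge."""
        all_leaves = frozenset(self.leaves())
        out: dict[frozenset, Node] = {}

        def collect(n: Node) -> frozenset:
            if n.is_leaf:
                return frozenset([n.name])
            below = frozenset().union(*(collect(c) for c, _ in n.children))
            if n is not self.root and 1 < len(below) < len(all_leaves) - 1:
                out[below] = n
            return below

        collect(self.root)
        return out

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf patristic distances (additivity checks)."""
        leaves = self.leaves()
        idx = {n: i for i, n in enumerate(leaves)}
        d = np.zeros((len(leaves), len(leaves)))

        def walk(n: Node, dist_to_here: dict[str, float]) -> dict[str, float]:
            if n.is_leaf:
                return {n.name: 0.0}
            below: dict[str, float] = {}
            groups = []
            for c, bl in n.children:
                sub = walk(c, dist_to_here)
                sub = {k: v + bl for k, v in sub.items()}
                groups.append(sub)
                below.update(sub)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a, da in groups[i].items():
                        for b, db in groups[j].items():
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
            return below

        walk(self.root, {})
        return DistanceMatrix(taxa=leaves, values=d)

    def newick(self, with_support: bool = True) -> str:
        def fmt(n: Node, bl: float | None) -> str:
            if n.is_leaf:
                core = n.name
            else:
                inner = ",".join(fmt(c, l) for c, l in n.children)
                label = ""
                if with_support and n.support is not None:
                    label = f"{n.support:g}"
                core = f"({inner}){label}"
            return core if bl is None else f"{core}:{bl:.6g}"

        return fmt(self.root, None) + ";"


def distance_matrix(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap columns.

    Models: ``p`` (mismatch fraction), ``poisson`` (protein,
    d = −ln(1−p)) and ``jc`` (nucleotide, d = −(3/4)·ln(1−4p/3)).
    Raises when a pair is beyond the model's saturation bound.
    """
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    rows = [np.frombuffer(alignment[t].upper().encode(), dtype="S1") for t in taxa]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("alignment rows differ in length")
    gap = np.bytes_(b"-")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (rows[i] != gap) & (rows[j] != gap)
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(f"no shared columns for {taxa[i]}/{taxa[j]}")
            p = float((rows[i][shared] != rows[j][shared]).mean())
            if model == "p":
                dist = p
            elif model == "poisson":
                if p >= 1.0:
                    raise ValueError(f"saturated pair {taxa[i]}/{taxa[j]} (p={p})")
                dist = -math.log(1.0 - p)
            elif model == "jc":
                if p >= 0.75:
                    raise ValueError(f"saturated pair {taxa[i]}/{taxa[j]} (p={p})")
                dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown model: {model}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, values=d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor-joining.

    Deterministic: on equal Q the smallest (i, j) index pair joins first.
    Negative branch lengths are clamped to zero.  Recovers additive trees
    exactly; an all-zero matrix yields a star tree with a warning.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [Node(name=t) for t in dm.taxa]
    if n == 2:
        d = float(dm.values[0, 1])
        return Tree(root=Node(children=[(nodes[0], d / 2), (nodes[1], d / 2)]))
    if np.all(dm.values == 0):
        warnings.warn("degenerate all-zero distance matrix: star tree",
                      stacklevel=2)
        return Tree(root=Node(children=[(x, 0.0) for x in nodes]))
    d = dm.values.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the matrix with the new node's distances
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node(children=[(nodes[i], max(li, 0.0)),
                          (nodes[j], max(lj, 0.0)),
                          (nodes[k], max(lk, 0.0))])
    return Tree(root=root)


def _split_key(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def bootstrap_support(alignment: Alignment, model: str = "p",
                      n_reps: int = 1000, seed: int = 0) -> Tree:
    """NJ tree with bootstrap supports (percent of replicates containing
    each original bipartition; columns resampled with replacement)."""
    ncol = len(next(iter(alignment.values())))
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = nj_tree(distance_matrix(alignment, model))
    all_leaves = frozenset(tree.leaves())
    splits = tree.bipartitions()
    keys = {_split_key(s, all_leaves): node for s, node in splits.items()}
    counts = {k: 0 for k in keys}
    rng = np.random.default_rng(seed)
    mat = np.array([list(alignment[t]) for t in alignment])
    taxa = list(alignment)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = {t: "".join(mat[r, cols]) for r, t in enumerate(taxa)}
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:
            continue  # saturated replicate contributes no support
        rep_keys = {_split_key(s, all_leaves) for s in rep_tree.bipartitions()}
        for k in counts:
            if k in rep_keys:
                counts[k] += 1
    for k, node in keys.items():
        node.support = 100.0 * counts[k] / n_reps
    return tree


def check_monophyly(tree: Tree, taxa_subset) -> tuple[bool, frozenset | None]:
    """True iff some edge bipartition isolates exactly ``taxa_subset``."""
    subset = frozenset(taxa_subset)
    leaves = frozenset(tree.leaves())
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(subset) in (1, len(leaves) - 1, len(leaves)):
        return True, subset  # trivial splits always hold on an unrooted tree
    for side in tree.bipartitions():
        if side == subset or leaves - side == subset:
            return True, side
    return False, None


def sub_alignment(alignment: Alignment, start: int, end: int) -> Alignment:
    """Columns [start, end] (1-based inclusive) — per-gene partitions."""
    return {t: s[start - 1:end] for t, s in alignment.items()}


def read_newick(source: str) -> Tree:
    """Parse a newick string or file path (via dendropy) into a Tree."""
    import os

    import dendropy

    if os.path.exists(source):
        dt = dendropy.Tree.get(path=source, schema="newick")
    else:
        dt = dendropy.Tree.get(data=source, schema="newick")

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(name=dnode.taxon.label if dnode.taxon else None)
        n = Node(name=None)
        if dnode.label is not None:
            try:
                n.support = float(dnode.label)
            except ValueError:
                pass
        for ch in dnode.child_nodes():
            n.children.append((convert(ch), ch.edge.length or 0.0))
        return n

    return Tree(root=convert(dt.seed_node))
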