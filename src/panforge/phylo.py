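"""Distance matrices, neighbour-joining trees with bootstrap, and PCoA.

NJ follows the Saitou-Nei Q-criterion with deterministic tie-breaking
(lexicographically lowest label pair).  Negative branch lengths are clamped
to zero and flagged.  Bootstrap supports come from resampling characters
(PAV genes or SNP sites) with replacement, rebuilding the tree per
replicate, and scoring each original bipartition by the percentage of
replicates containing it.  PCoA is classical metric scaling: eigendecompose
the double-centred squared-distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# PAV distances


def pav_distance(matrix, metric: str = "simple_matching") -> DistanceMatrix:
    """Pairwise accession distance over the binary PAV matrix.

    simple_matching: mismatch fraction over all genes.  jaccard: 1 - |A&B| /
    |A|B| over present-gene sets.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    labels = list(data.columns)
    if len(labels) < 3:
        raise ValueError("need >= 3 accessions")
    X = data.to_numpy(dtype=bool).T  # accessions x genes
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "simple_matching":
                d = float(np.mean(X[i] != X[j]))
            elif metric == "jaccard":
                union = np.logical_or(X[i], X[j]).sum()
                if union == 0:
                    raise ValueError(f"empty present-gene union for {labels[i]}, {labels[j]}")
                inter = np.logical_and(X[i], X[j]).sum()
                d = 1.0 - inter / union
            else:
                raise ValueError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=labels, values=D)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted binary tree stored with an arbitrary trifurcating root."""

    root: TreeNode
    negative_clamped: bool = False

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length metric between all leaf pairs."""
        labels = self.leaf_names
        idx = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))

        def below(node: TreeNode) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            sets = []
            for child, bl in node.children:
                d = {i: dist + bl for i, dist in below(child).items()}
                sets.append(d)
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i, di in sets[a].items():
                        for j, dj in sets[b].items():
                            D[i, j] = D[j, i] = di + dj
            merged = {}
            for d in sets:
                merged.update(d)
            return merged

        below(self.root)
        return DistanceMatrix(labels=labels, values=D)

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial splits, each canonicalised to the side not containing
        the lexicographically first leaf, mapped to the child node whose
        edge induces it."""
        all_leaves = set(self.leaf_names)
        anchor = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            mine = set()
            for child, _ in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = frozenset(side if anchor not in side else all_leaves - side)
                    out[canon] = child
                mine |= side
            return mine

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(f"{fmt(c)}:{bl:.6g}" for c, bl in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining from the Q-matrix definition.

    For an additive input the path-length metric of the result reproduces D
    exactly.  Ties in the Q minimisation are broken on the lexicographically
    lowest label pair; negative branch lengths are clamped to 0 and flagged.
    """
    labels = list(D.labels)
    if len(labels) < 3:
        raise ValueError("NJ requires >= 3 taxa")
    d = D.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=x) for x in labels]
    tags: list[str] = list(labels)  # tie-break keys
    clamped = False

    while len(nodes) > 3:
        n = len(nodes)
        R = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - R[i] - R[j]
                key = (q, *sorted((tags[i], tags[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        new_tag = min(tags[i], tags[j])
        nodes = [nodes[x] for x in keep] + [parent]
        tags = [tags[x] for x in keep] + [new_tag]

    # final three-point join
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    root = TreeNode(children=[(a, la), (b, lb), (c, lc)])
    return Tree(root=root, negative_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap


def character_distance(chars: pd.DataFrame, metric: str = "simple_matching") -> DistanceMatrix:
    """Distance over a samples x characters matrix, ignoring (-1) missing
    codes pairwise."""
    labels = list(chars.index)
    X = chars.to_numpy()
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (X[i] >= 0) & (X[j] >= 0)
            D[i, j] = D[j, i] = float(np.mean(X[i][ok] != X[j][ok])) if ok.any() else 0.0
    return DistanceMatrix(labels=labels, values=D)


def bootstrap_support(
    chars: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    metric: str = "simple_matching",
) -> Tree:
    """NJ tree with bipartition bootstrap supports (percent of replicates).

    ``chars`` is samples x characters (e.g. accessions x PAV genes, or
    accessions x SNP genotype codes with -1 for missing).  B=0 returns the
    plain tree with no supports.
    """
    if chars.shape[0] < 3 or chars.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 characters")
    tree = nj_tree(character_distance(chars, metric))
    if B == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {split: 0 for split in tree.bipartitions()}
    m = chars.shape[1]
    for _ in range(B):
        cols = rng.integers(0, m, size=m)
        rep = chars.iloc[:, cols]
        rep_tree = nj_tree(character_distance(rep, metric))
        rep_splits = set(rep_tree.bipartitions())
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in tree.bipartitions().items():
        node.support = 100.0 * counts[split] / B
    return tree


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray
    labels: list[str]


def pcoa(D: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Negative eigenvalues are reported but their axes are never returned as
    coordinates; if fewer than k positive eigenvalues exist the coordinate
    matrix is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = D.values**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals[0])) if vals.size else 0.0
    pos = vals > tol
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating coordinates to {n_pos} axes")
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    pos_sum = vals[pos].sum()
    prop = np.where(pos, vals / pos_sum, 0.0) if pos_sum > 0 else np.zeros_like(vals)
    return PcoaResult(coordinates=coords, eigenvalues=vals, proportion_explained=prop, labels=list(D.labels))
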