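"""Cell-type hierarchy construction by recursive partitioning of mean profiles.

The tree is built HOPACH-style: at each node, the cell types are
partitioned with PAM (k-medoids) on correlation distance for every
candidate number of children, and the partition minimizing the median
split silhouette is kept. Medoid seeding is deterministic
(farthest-point from the global medoid), so the tree is a pure function
of the profile matrix. The collapsing step of full HOPACH is omitted;
see the methods note for the conventions adopted for tiny clusters.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellAnnotation, ExpressionMatrix, ValidationError
from .similarity import pairwise_similarity


@dataclass
class TreeNode:
    node_id: str
    cell_type_set: frozenset[str]
    children: list["TreeNode"] = field(default_factory=list)
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return len(self.children) == 0

    def __iter__(self):
        yield self
        for c in self.children:
            yield from c


@dataclass
class CellTypeTree:
    root: TreeNode

    def __post_init__(self) -> None:
        self.validate()

    def nodes(self) -> list[TreeNode]:
        return list(self.root)

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root if not n.is_leaf]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root if n.is_leaf]

    def labels(self) -> list[str]:
        return sorted(self.root.cell_type_set)

    def node(self, node_id: str) -> TreeNode:
        for n in self.root:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def validate(self) -> None:
        """Check the partition/leaf invariants of the hierarchy."""
        for n in self.root:
            if n.is_leaf:
                if len(n.cell_type_set) != 1:
                    raise ValidationError(
                        f"leaf {n.node_id} has {len(n.cell_type_set)} labels"
                    )
            else:
                union: set[str] = set()
                total = 0
                for c in n.children:
                    union |= c.cell_type_set
                    total += len(c.cell_type_set)
                    if c.depth != n.depth + 1:
                        raise ValidationError(f"bad depth at {c.node_id}")
                if union != set(n.cell_type_set) or total != len(n.cell_type_set):
                    raise ValidationError(
                        f"children of {n.node_id} do not partition its label set"
                    )

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        def enc(n: TreeNode) -> dict:
            return {
                "id": n.node_id,
                "types": sorted(n.cell_type_set),
                "children": [enc(c) for c in n.children],
            }

        return json.dumps(enc(self.root))

    @classmethod
    def from_json(cls, s: str) -> "CellTypeTree":
        def dec(d: dict, depth: int) -> TreeNode:
            node = TreeNode(d["id"], frozenset(d["types"]), depth=depth)
            node.children = [dec(c, depth + 1) for c in d["children"]]
            return node

        return cls(dec(json.loads(s), 0))

    def to_newick(self) -> str:
        def enc(n: TreeNode) -> str:
            if n.is_leaf:
                return next(iter(n.cell_type_set)).replace(" ", "_")
            return "(" + ",".join(enc(c) for c in n.children) + ")"

        return enc(self.root) + ";"


def tree_from_blueprint(blueprint: dict) -> CellTypeTree:
    """Build a tree from a nested ``{label: subtree-or-None}`` mapping.

    The top level may either be a single-root mapping or a mapping of
    several children, in which case an implicit root is added.
    """

    def build(name: str, sub, path: str, depth: int) -> TreeNode:
        if not sub:
            return TreeNode(path, frozenset([name]), depth=depth)
        children = [
            build(k, v, f"{path}.{i}", depth + 1)
            for i, (k, v) in enumerate(sorted(sub.items()))
        ]
        node = TreeNode(path, frozenset().union(*(c.cell_type_set for c in children)), depth=depth)
        node.children = children
        return node

    if len(blueprint) == 1:
        name, sub = next(iter(blueprint.items()))
        if not sub:
            raise ValidationError("blueprint must contain at least 2 leaf types")
        return CellTypeTree(build(name, sub, "root", 0))
    return CellTypeTree(build("root", blueprint, "root", 0))


def mean_profiles(
    expr: ExpressionMatrix, ann: CellAnnotation, genes: list[str] | None = None
) -> pd.DataFrame:
    """Average log expression of each cell type over the selected genes."""
    labels = ann.label_array(expr.cell_ids)
    sub = expr if genes is None else expr.subset_genes(list(genes))
    out = {}
    for t in sorted(set(labels)):
        out[t] = sub.values[:, labels == t].mean(axis=1)
    return pd.DataFrame(out, index=sub.gene_ids).T


def correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between profile rows, zeroed diagonal."""
    D = 1.0 - pairwise_similarity(profiles, profiles, "pearson")
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


# -- PAM (k-medoids) with deterministic seeding --------------------------


def _assign(D: np.ndarray, medoids: list[int]) -> np.ndarray:
    # nearest medoid; ties go to the earliest medoid in the list
    sub = D[:, medoids]
    return np.argmin(sub, axis=1)


def _cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam(D: np.ndarray, k: int) -> np.ndarray:
    """k-medoids with build (farthest-point) seeding and greedy swaps.

    Returns integer cluster labels in 0..k-1, renumbered by first
    occurrence so the labelling is deterministic.
    """
    m = D.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"k={k} out of range for {m} items")
    medoids = [int(np.argmin(D.sum(axis=1)))]  # global medoid
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        d_near[medoids] = -np.inf
        medoids.append(int(np.argmax(d_near)))
    improved = True
    while improved:
        improved = False
        best = (_cost(D, medoids), None)
        for mi in range(k):
            for o in range(m):
                if o in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = o
                c = _cost(D, trial)
                if c < best[0] - 1e-12:
                    best = (c, trial)
        if best[1] is not None:
            medoids = best[1]
            improved = True
    labels = _assign(D, sorted(medoids))
    # renumber by first occurrence
    remap: dict[int, int] = {}
    out = np.empty(m, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def silhouette_widths(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette widths under a precomputed distance matrix.

    Members of singleton clusters get width 0 (the usual convention),
    as do points with no positive distances.
    """
    n = len(labels)
    sil = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():
            continue  # singleton cluster
        a = D[i, own].mean()
        bs = [
            D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        ]
        b = min(bs) if bs else 0.0
        denom = max(a, b)
        sil[i] = (b - a) / denom if denom > 0 else 0.0
    return sil


def split_silhouette(D: np.ndarray, members: np.ndarray) -> float:
    """Median silhouette of a cluster's members after re-splitting it in two.

    Clusters of size <= 2 cannot be meaningfully split and score 0
    (treated as homogeneous).
    """
    if len(members) <= 2:
        return 0.0
    sub = D[np.ix_(members, members)]
    labels = pam(sub, 2)
    return float(np.median(silhouette_widths(sub, labels)))


def median_split_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    vals = [
        split_silhouette(D, np.flatnonzero(labels == c)) for c in np.unique(labels)
    ]
    return float(np.median(vals))


def choose_partition(D: np.ndarray, kmax: int) -> np.ndarray:
    """Pick the PAM partition (k = 2..kmax) minimizing the median split
    silhouette.

    With few items many candidate partitions tie at a median split
    silhouette of 0 (clusters of size <= 2 are unsplittable); ties are
    broken by the largest average silhouette width of the partition
    itself, and remaining ties by the smallest k.
    """
    m = D.shape[0]
    candidates: list[tuple[float, float, int, np.ndarray]] = []
    for k in range(2, min(kmax, m) + 1):
        labels = pam(D, k)
        if len(np.unique(labels)) < k:
            continue
        mss = median_split_silhouette(D, labels)
        avg_sil = float(silhouette_widths(D, labels).mean())
        candidates.append((mss, -avg_sil, k, labels))
    assert candidates
    candidates.sort(key=lambda c: (round(c[0], 12), round(c[1], 12), c[2]))
    return candidates[0][3]


def build_tree(profiles: pd.DataFrame, kmax: int = 5) -> CellTypeTree:
    """Recursive divisive partitioning of cell-type mean profiles.

    ``profiles`` is types x genes with the type labels as index. Child
    ordering is canonicalized lexicographically by the smallest member
    label, so the tree is invariant to row permutation.
    """
    labels = [str(t) for t in profiles.index]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate type labels in profile matrix")
    values = np.asarray(profiles, dtype=float)
    if len(labels) < 2:
        root = TreeNode("root", frozenset(labels), depth=0)
        return CellTypeTree(root)
    D = correlation_distance(values)

    def recurse(idx: list[int], node_id: str, depth: int) -> TreeNode:
        names = [labels[i] for i in idx]
        node = TreeNode(node_id, frozenset(names), depth=depth)
        if len(idx) == 1:
            return node
        if len(idx) == 2:
            parts = [[idx[0]], [idx[1]]]
        else:
            sub = D[np.ix_(idx, idx)]
            part_labels = choose_partition(sub, kmax)
            parts = [
                [idx[j] for j in np.flatnonzero(part_labels == c)]
                for c in np.unique(part_labels)
            ]
        parts.sort(key=lambda p: min(labels[i] for i in p))
        node.children = [
            recurse(p, f"{node_id}.{i}", depth + 1) for i, p in enumerate(parts)
        ]
        return node

    order = sorted(range(len(labels)), key=lambda i: labels[i])
    return CellTypeTree(recurse(order, "root", 0))
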