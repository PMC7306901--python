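"""Training and top-down multiscale prediction over the cell-type tree.

A :class:`TrainedClassifier` couples the cell-type hierarchy with one
:class:`~hiertype.ensemble.NodeModel` per branch node. Query cells are
classified from the root downward; a cell stops at the first node where
the ensemble abstains and is reported as "unassigned" (stopped at the
root), an intermediate type (stopped part-way; its label is the set of
leaf types under the last accepted node) or a leaf label.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import CellAnnotation, ExpressionMatrix, ValidationError
from .ensemble import UNASSIGNED, NodeModel, node_predict, train_node
from .genestats import de_stat, select_top
from .tree import CellTypeTree, TreeNode, build_tree, mean_profiles


@dataclass
class PredictionRecord:
    """Classification outcome for one query cell."""

    cell_id: str
    path: list[str]  # root-anchored node ids that accepted the cell
    final_label: str | frozenset
    outcome: str  # "leaf" | "intermediate" | "unassigned"
    #: winning-label ensemble weight share at the deepest accepted node
    score: float = 0.0
    levels: list[dict] = field(default_factory=list)

    def label_string(self) -> str:
        if isinstance(self.final_label, frozenset):
            return "|".join(sorted(self.final_label))
        return str(self.final_label)


def tree_gene_union(
    expr: ExpressionMatrix, ann: CellAnnotation, config: RunConfig
) -> list[str]:
    """Union of one-vs-all DE genes over all labels, for tree building."""
    labels = ann.label_array(expr.cell_ids)
    union: set[str] = set()
    for t in sorted(set(labels)):
        mask = labels == t
        table = de_stat(expr.values, mask, ~mask, expr.gene_ids, config.expr_threshold)
        union.update(
            select_top(
                table,
                max_genes=config.max_genes,
                adjp_cut=config.adjp_cut,
                propdiff_cut=config.propdiff_cut,
                fc_cut=config.fc_cut,
            )
        )
    if len(union) < 2:
        warnings.warn("no usable DE genes found for tree building; using all genes")
        return list(expr.gene_ids)
    return sorted(union)


@dataclass
class TrainedClassifier:
    """Cell-type tree plus one trained ensemble per branch node."""

    tree: CellTypeTree
    node_models: dict[str, NodeModel]
    ref_values: np.ndarray  # genes x cells, log expression
    gene_ids: list[str]
    cell_ids: list[str]
    leaf_labels: np.ndarray  # per reference cell
    config: RunConfig
    overall_eps: float = 0.5  # reference-level training error

    def gene_universe(self) -> list[str]:
        union: set[str] = set()
        for m in self.node_models.values():
            for b in m.base:
                union.update(b.gene_ids)
        return sorted(union)

    # -- serialization ---------------------------------------------------
    def to_archive(self) -> tuple[dict, dict]:
        meta = {
            "tree": self.tree.to_json(),
            "config": _jsonable(self.config.to_dict()),
            "gene_ids": self.gene_ids,
            "cell_ids": self.cell_ids,
            "leaf_labels": [str(x) for x in self.leaf_labels],
            "overall_eps": self.overall_eps,
            "nodes": [m.to_archive()[0] for m in self.node_models.values()],
        }
        return meta, {"ref_values": self.ref_values}

    @classmethod
    def from_archive(cls, meta: dict, arrays: dict) -> "TrainedClassifier":
        models = {
            d["node_id"]: NodeModel.from_archive(d, {}) for d in meta["nodes"]
        }
        return cls(
            tree=CellTypeTree.from_json(meta["tree"]),
            node_models=models,
            ref_values=np.asarray(arrays["ref_values"], dtype=float),
            gene_ids=list(meta["gene_ids"]),
            cell_ids=list(meta["cell_ids"]),
            leaf_labels=np.array(meta["leaf_labels"], dtype=object),
            config=RunConfig.from_dict(_unjsonable(meta["config"])),
            overall_eps=meta["overall_eps"],
        )


def _jsonable(d: dict) -> dict:
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def _unjsonable(d: dict) -> dict:
    out = dict(d)
    for k in ("selections", "metrics"):
        if k in out:
            out[k] = tuple(out[k])
    return out


def train_classifier(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    config: RunConfig | None = None,
    tree: CellTypeTree | None = None,
) -> TrainedClassifier:
    """Build the cell-type tree and train every branch-node ensemble.

    When ``tree`` is given it is used as-is; otherwise the hierarchy is
    built from the per-type mean profiles over the one-vs-all DE gene
    union.
    """
    config = config or RunConfig()
    if not expr.normalized:
        warnings.warn("expression matrix is not flagged as normalized")
    ann.validate_against(expr)
    labels = ann.label_array(expr.cell_ids)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValidationError("training requires at least 2 cell types")
    if tree is None:
        genes = tree_gene_union(expr, ann, config)
        profiles = mean_profiles(expr, ann, genes)
        tree = build_tree(profiles, kmax=config.kmax)
    if set(tree.labels()) != set(types):
        raise ValidationError("tree labels do not match annotation labels")

    models: dict[str, NodeModel] = {}
    for node in tree.internal_nodes():
        member = np.isin(labels, sorted(node.cell_type_set))
        idx = np.flatnonzero(member)
        model = train_node(
            expr.values[:, idx],
            expr.gene_ids,
            labels[idx],
            node,
            config,
            cell_indices=idx,
        )
        if model is not None:
            models[node.node_id] = model

    if models:
        weights = np.array([len(m.cell_indices) for m in models.values()], float)
        eps_nodes = np.array([m.eps_ensemble for m in models.values()])
        overall_eps = float(np.clip((weights * eps_nodes).sum() / weights.sum(), 0.01, 0.99))
    else:
        overall_eps = 0.5
    return TrainedClassifier(
        tree=tree,
        node_models=models,
        ref_values=expr.values.copy(),
        gene_ids=list(expr.gene_ids),
        cell_ids=list(expr.cell_ids),
        leaf_labels=labels,
        config=config,
        overall_eps=overall_eps,
    )


def _check_overlap(model: TrainedClassifier, query: ExpressionMatrix, floor: float):
    universe = model.gene_universe()
    qset = set(query.gene_ids)
    present = [g for g in universe if g in qset]
    if len(universe) and len(present) / len(universe) < floor:
        missing = [g for g in universe if g not in qset]
        raise ValidationError(
            f"query covers only {len(present)}/{len(universe)} model genes "
            f"(floor {floor:.0%}); missing e.g. {missing[:10]}"
        )


def predict(
    model: TrainedClassifier,
    query: ExpressionMatrix,
    config: RunConfig | None = None,
) -> list[PredictionRecord]:
    """Top-down multiscale classification of a query matrix.

    Genes absent from the query are dropped from each node's gene sets
    at prediction time (cross-platform queries rarely share the full
    gene universe), subject to the configured overlap floor.
    """
    config = config or model.config
    _check_overlap(model, query, config.gene_overlap_floor)
    ref_gene_row = {g: i for i, g in enumerate(model.gene_ids)}
    q_gene_row = query.gene_index()

    n = query.n_cells
    records = [
        PredictionRecord(cid, [], UNASSIGNED, "unassigned") for cid in query.cell_ids
    ]
    node_by_id = {nd.node_id: nd for nd in model.tree.nodes()}

    # BFS over (node, query-cell indices routed to it)
    frontier: list[tuple[TreeNode, np.ndarray]] = [
        (model.tree.root, np.arange(n))
    ]
    while frontier:
        node, idx = frontier.pop(0)
        if len(idx) == 0:
            continue
        if node.is_leaf:
            label = next(iter(node.cell_type_set))
            for i in idx:
                records[i].final_label = label
                records[i].outcome = "leaf"
            continue
        nm = model.node_models.get(node.node_id)
        if nm is None:
            # untrainable branch node: the traversal ends here
            for i in idx:
                _finish_intermediate(records[i], node)
            continue
        ref_cols = nm.cell_indices
        labels_out, shares = node_predict(
            nm,
            model.ref_values[:, ref_cols],
            ref_gene_row,
            model.leaf_labels[ref_cols],
            query.values[:, idx],
            q_gene_row,
            config,
        )
        routed: dict[str, list[int]] = {c: [] for c in nm.children}
        for j, i in enumerate(idx):
            rec = records[i]
            assigned = labels_out[j]
            if assigned == UNASSIGNED:
                _finish_intermediate(rec, node)
            else:
                rec.path.append(assigned)
                rec.score = float(shares[j])
                rec.levels.append(
                    {
                        "node": node.node_id,
                        "assigned": assigned,
                        "share": float(shares[j]),
                    }
                )
                routed[assigned].append(i)
        for child in node.children:
            if child.node_id in routed and routed[child.node_id]:
                frontier.append((child, np.array(routed[child.node_id])))
    return records


def _finish_intermediate(rec: PredictionRecord, node: TreeNode) -> None:
    if rec.path:
        rec.final_label = frozenset(node.cell_type_set)
        rec.outcome = "intermediate"
    else:
        rec.final_label = UNASSIGNED
        rec.outcome = "unassigned"
        rec.score = 0.0


def reference_weight(eps_r: float) -> float:
    """Non-negative reference weight ln((1 - eps) / eps), floored at 0."""
    return max(float(np.log((1.0 - eps_r) / eps_r)), 0.0)


def joint_predict(
    models: list[TrainedClassifier],
    query: ExpressionMatrix,
    config: RunConfig | None = None,
    label_map: dict[str, str] | None = None,
) -> list[PredictionRecord]:
    """Joint classification over several reference classifiers.

    Each reference's prediction contributes its ensemble weight share,
    scaled by the reference weight ln((1 - eps_r) / eps_r) derived
    from that reference's overall training error; the label with the
    largest weighted average score wins. A cell is unassigned only
    when every reference leaves it unassigned. ``label_map``
    translates reference-specific labels into a shared vocabulary.
    """
    if not models:
        raise ValueError("joint_predict needs at least one trained classifier")
    per_ref = [predict(m, query, config) for m in models]
    weights = [reference_weight(m.overall_eps) for m in models]
    total_w = sum(weights)
    if total_w == 0:
        weights = [1.0] * len(models)
        total_w = float(len(models))
    weights = [w / total_w for w in weights]  # normalized reference weights

    def translate(label):
        if label_map is None:
            return label
        if isinstance(label, frozenset):
            return frozenset(label_map.get(t, t) for t in label)
        return label_map.get(label, label)

    out: list[PredictionRecord] = []
    for i, cid in enumerate(query.cell_ids):
        scores: dict = {}
        best_rec: dict = {}
        for recs, w in zip(per_ref, weights):
            rec = recs[i]
            if rec.outcome == "unassigned":
                continue
            key = translate(rec.final_label)
            scores[key] = scores.get(key, 0.0) + w * rec.score
            if key not in best_rec:
                best_rec[key] = rec
        if not scores:
            out.append(PredictionRecord(cid, [], UNASSIGNED, "unassigned"))
            continue
        winner = max(
            sorted(scores, key=_label_sort_key), key=lambda k: scores[k]
        )
        src = best_rec[winner]
        out.append(
            PredictionRecord(
                cell_id=cid,
                path=list(src.path),
                final_label=winner,
                outcome="leaf" if isinstance(winner, str) else "intermediate",
                score=scores[winner],
                levels=list(src.levels),
            )
        )
    return out


def _label_sort_key(label) -> str:
    if isinstance(label, frozenset):
        return "|".join(sorted(label))
    return str(label)


def posthoc_cluster(
    expr: ExpressionMatrix,
    k: int | str = "auto",
    n_top_genes: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cluster unassigned cells and report per-cluster marker genes.

    The default clusterer is k-means on the top-variance genes with k
    chosen by a silhouette scan over 2..10; any clustering can be
    substituted upstream, this is a deliberately simple default.
    Returns integer cluster labels and a one-vs-rest DE marker table
    with a ``cluster`` column.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    n = expr.n_cells
    if n < 10:
        warnings.warn("fewer than 10 cells; returning a single cluster")
        return np.zeros(n, dtype=int), pd.DataFrame()
    variances = expr.values.var(axis=1)
    rows = np.argsort(-variances, kind="stable")[: min(n_top_genes, expr.n_genes)]
    X = expr.values[rows, :].T
    if k == "auto":
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(10, n - 1) + 1):
            lab = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit_predict(X)
            if len(set(lab)) < 2:
                continue
            s = silhouette_score(X, lab)
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    labels = KMeans(n_clusters=int(k), n_init=10, random_state=seed).fit_predict(X)

    tables = []
    for c in sorted(set(labels)):
        mask = labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        tab = de_stat(expr.values, mask, ~mask, expr.gene_ids)
        tab = tab.sort_values("adj_p", kind="stable").head(50)
        tab.insert(0, "cluster", c)
        tables.append(tab)
    markers = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return labels, markers


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Flatten prediction records for CSV export."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "final_label": [r.label_string() for r in records],
            "outcome": [r.outcome for r in records],
            "path": ["/".join(r.path) for r in records],
            "score": [r.score for r in records],
            "levels": [json.dumps(r.levels) for r in records],
        }
    )
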