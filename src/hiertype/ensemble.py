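"""Per-branch-node ensembles of distance-weighted kNN base classifiers.

Each branch node trains one base classifier per (gene-selection,
similarity-metric) combination — 30 with all five selections and six
metrics enabled. A base classifier's training error ``eps_t`` is
estimated by leave-one-out self-classification on (a stratified
subsample of) the node's reference cells, and its ensemble weight is
the AdaBoost-style log-odds ``alpha_t = ln((1 - eps_t) / eps_t)``.

At prediction time every base classifier votes for a child of the node
or abstains ("unassigned") when its nearest neighbours are not similar
enough (mixture-model threshold) or the winning label's weight share
is below the weight threshold; the ensemble label is the argmax of
summed alphas over agreeing classifiers.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .genestats import STAT_FUNCS, select_top
from .similarity import knn_weights, nearest_indices, pairwise_similarity

UNASSIGNED = "unassigned"
EPS_CLIP = (0.01, 0.99)


def ensemble_weight(eps_t: float) -> float:
    """AdaBoost-style classifier weight: ln((1 - eps) / eps)."""
    if not 0 < eps_t < 1:
        raise ValueError("eps_t must be strictly inside (0, 1)")
    return float(np.log((1.0 - eps_t) / eps_t))


@dataclass
class BaseClassifier:
    selection: str
    metric: str
    gene_ids: list[str]
    eps_t: float
    alpha_t: float


@dataclass
class NodeModel:
    """Trained ensemble for one branch node of the cell-type tree."""

    node_id: str
    children: list[str]  # child node ids, reachable ones only
    child_types: dict[str, list[str]]  # child node id -> leaf labels
    base: list[BaseClassifier] = field(default_factory=list)
    cell_indices: np.ndarray | None = None  # columns into the reference matrix
    eps_ensemble: float = 0.5
    unreachable: list[str] = field(default_factory=list)

    @property
    def alpha_vector(self) -> np.ndarray:
        return np.array([b.alpha_t for b in self.base])

    # archive support (arrays are tiny; the reference matrix lives with
    # the enclosing classifier)
    def to_archive(self) -> tuple[dict, dict]:
        meta = {
            "node_id": self.node_id,
            "children": self.children,
            "child_types": self.child_types,
            "eps_ensemble": self.eps_ensemble,
            "unreachable": self.unreachable,
            "cell_indices": None
            if self.cell_indices is None
            else [int(i) for i in self.cell_indices],
            "base": [
                {
                    "selection": b.selection,
                    "metric": b.metric,
                    "gene_ids": b.gene_ids,
                    "eps_t": b.eps_t,
                    "alpha_t": b.alpha_t,
                }
                for b in self.base
            ],
        }
        return meta, {}

    @classmethod
    def from_archive(cls, meta: dict, arrays: dict) -> "NodeModel":
        return cls(
            node_id=meta["node_id"],
            children=list(meta["children"]),
            child_types={k: list(v) for k, v in meta["child_types"].items()},
            base=[BaseClassifier(**b) for b in meta["base"]],
            cell_indices=None
            if meta["cell_indices"] is None
            else np.asarray(meta["cell_indices"], dtype=int),
            eps_ensemble=meta["eps_ensemble"],
            unreachable=list(meta["unreachable"]),
        )


def _node_rng(seed: int, node_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(node_id.encode())])


def _stratified_subsample(
    labels: np.ndarray, max_cells: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(labels)
    if n <= max_cells:
        return np.arange(n)
    keep: list[np.ndarray] = []
    groups = sorted(set(labels))
    for g in groups:
        idx = np.flatnonzero(labels == g)
        share = max(2, int(round(max_cells * len(idx) / n)))
        keep.append(rng.choice(idx, size=min(share, len(idx)), replace=False))
    return np.sort(np.concatenate(keep))


def _batch_vote(
    sims: np.ndarray, ref_labels: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance-weighted vote per query row of a similarity matrix.

    Returns (winner, winner_weight_share, max_similarity); winner is
    None on an exact tie. ``-inf`` similarities mark excluded
    reference cells (self-matches during leave-one-out).
    """
    nq = sims.shape[0]
    winners = np.empty(nq, dtype=object)
    shares = np.empty(nq)
    finite = np.where(np.isfinite(sims), sims, -1.0)
    max_sim = finite.max(axis=1)
    d = 1.0 - sims  # -inf similarity -> +inf distance, sorted last
    for i in range(nq):
        usable = np.isfinite(d[i])
        k_eff = min(k, int(usable.sum()))
        idx = nearest_indices(d[i], k_eff)
        w = knn_weights(d[i][idx])
        totals: dict[str, float] = {}
        for lab, wt in zip(ref_labels[idx], w):
            totals[lab] = totals.get(lab, 0.0) + float(wt)
        total = sum(totals.values())
        best = max(totals.values())
        top = sorted(lab for lab, wt in totals.items() if wt == best)
        if len(top) > 1:
            winners[i] = None
        else:
            winners[i] = top[0]
        shares[i] = best / total if total > 0 else 1.0
    return winners, shares, max_sim


def node_gene_sets(
    values: np.ndarray,
    gene_ids: list[str],
    super_labels: np.ndarray,
    children: list[str],
    config: RunConfig,
) -> dict[str, list[str]]:
    """One-vs-rest gene sets per selection method over the node's children.

    Children act as super-labels (unions of their descendant leaves).
    The returned per-selection set is the union over children,
    ordered by gene id. A selection with an empty set falls back to
    the DE set; if DE itself is empty, the node falls back to the
    top-variance genes.
    """
    per_sel: dict[str, list[str]] = {}
    for sel in config.selections:
        union: set[str] = set()
        for child in children:
            in_mask = super_labels == child
            out_mask = ~in_mask
            table = STAT_FUNCS[sel](
                values, in_mask, out_mask, gene_ids, config.expr_threshold
            )
            union.update(
                select_top(
                    table,
                    max_genes=config.max_genes,
                    adjp_cut=config.adjp_cut,
                    propdiff_cut=config.propdiff_cut,
                    fc_cut=config.fc_cut,
                )
            )
        per_sel[sel] = sorted(union)
    # similarity metrics need at least 2 genes; degenerate sets fall back
    if len(per_sel.get("DE", [])) >= 2:
        fallback = per_sel["DE"]
    else:
        variances = values.var(axis=1)
        top = np.argsort(-variances, kind="stable")[: config.max_genes]
        fallback = sorted(gene_ids[i] for i in top)
    for sel, genes in per_sel.items():
        if len(genes) < 2:
            warnings.warn(
                f"empty or degenerate {sel} gene set; falling back to "
                f"{'the DE selection' if fallback is per_sel.get('DE') else 'top-variance genes'}"
            )
            per_sel[sel] = list(fallback)
    return per_sel


def train_node(
    values: np.ndarray,
    gene_ids: list[str],
    leaf_labels: np.ndarray,
    node,
    config: RunConfig,
    cell_indices: np.ndarray | None = None,
) -> NodeModel | None:
    """Train the base-classifier ensemble for one branch node.

    ``values`` is the genes x cells log-expression of the node's
    reference cells (cells whose leaf label belongs to the node), with
    ``leaf_labels`` per cell and ``cell_indices`` their columns in the
    full reference matrix. Children with fewer than
    ``config.min_cells_per_type`` cells are flagged unreachable;
    returns None when fewer than two children remain.
    """
    child_types = {c.node_id: sorted(c.cell_type_set) for c in node.children}
    super_labels = np.empty(len(leaf_labels), dtype=object)
    for cid, types in child_types.items():
        super_labels[np.isin(leaf_labels, types)] = cid

    counts = {c: int((super_labels == c).sum()) for c in child_types}
    reachable = [c for c in sorted(child_types) if counts[c] >= config.min_cells_per_type]
    unreachable = [c for c in sorted(child_types) if c not in reachable]
    if unreachable:
        warnings.warn(
            f"node {node.node_id}: children {unreachable} have fewer than "
            f"{config.min_cells_per_type} cells and are unreachable"
        )
    if len(reachable) < 2:
        return None
    keep = np.isin(super_labels, reachable)
    values = values[:, keep]
    super_labels = super_labels[keep]
    kept_indices = (
        np.flatnonzero(keep) if cell_indices is None else np.asarray(cell_indices)[keep]
    )

    gene_sets = node_gene_sets(values, gene_ids, super_labels, reachable, config)
    gene_row = {g: i for i, g in enumerate(gene_ids)}

    rng = _node_rng(config.seed, node.node_id)
    sub = _stratified_subsample(super_labels, config.eps_max_cells, rng)
    sub_labels = super_labels[sub]

    base: list[BaseClassifier] = []
    vote_matrix = []  # per base classifier: LOO votes on the subsample
    for sel in config.selections:
        genes = gene_sets[sel]
        rows = [gene_row[g] for g in genes]
        R = values[rows, :].T  # cells x genes
        Q = R[sub, :]
        for metric in config.metrics:
            sims = pairwise_similarity(Q, R, metric, config.jaccard_threshold)
            sims[np.arange(len(sub)), sub] = -np.inf  # leave self out
            winners, _, _ = _batch_vote(sims, super_labels, config.k)
            errors = np.array(
                [w is None or w != t for w, t in zip(winners, sub_labels)]
            )
            eps = float(np.clip(errors.mean(), *EPS_CLIP))
            base.append(
                BaseClassifier(sel, metric, list(genes), eps, ensemble_weight(eps))
            )
            vote_matrix.append(winners)

    # ensemble training error: weighted argmax over the LOO votes
    alphas = np.array([b.alpha_t for b in base])
    ens_errors = []
    for i, truth in enumerate(sub_labels):
        scores: dict[str, float] = {}
        for t, votes in enumerate(vote_matrix):
            v = votes[i]
            if v is not None:
                scores[v] = scores.get(v, 0.0) + alphas[t]
        pred = max(sorted(scores), key=lambda c: scores[c]) if scores else None
        ens_errors.append(pred != truth)
    eps_ensemble = float(np.clip(np.mean(ens_errors), *EPS_CLIP))

    return NodeModel(
        node_id=node.node_id,
        children=reachable,
        child_types={c: child_types[c] for c in reachable},
        base=base,
        cell_indices=kept_indices,
        eps_ensemble=eps_ensemble,
        unreachable=unreachable,
    )


# -- correlation rejection threshold (two-component Gaussian mixture) ----


def gaussian_mixture_em(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> dict:
    """Two-component 1-D Gaussian mixture fitted by EM.

    Deterministic k-means-style initialization: centres start at the
    10% and 90% quantiles and are refined by a few Lloyd steps, which
    finds well-separated modes even when one component holds a small
    minority of the values (a balanced half-split start converges to
    a poor local optimum in that case). Returns means, variances,
    weights and the log-likelihood trace (non-decreasing up to the
    tolerance).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 values to fit a mixture")
    mu = np.array([np.quantile(x, 0.1), np.quantile(x, 0.9)])
    for _ in range(10):  # Lloyd refinement of the two centres
        assign = np.abs(x[:, np.newaxis] - mu[np.newaxis, :]).argmin(axis=1)
        if 0 < assign.sum() < n:
            new = np.array([x[assign == 0].mean(), x[assign == 1].mean()])
            if np.allclose(new, mu):
                break
            mu = new
        else:
            break
    assign = np.abs(x[:, np.newaxis] - mu[np.newaxis, :]).argmin(axis=1)
    if 0 < assign.sum() < n:
        var = np.array(
            [max(x[assign == c].var(), 1e-8) for c in (0, 1)]
        )
        w = np.array([(assign == 0).mean(), (assign == 1).mean()])
        w = np.clip(w, 0.05, 0.95)
        w /= w.sum()
    else:
        var = np.full(2, max(x.var(), 1e-8))
        w = np.array([0.5, 0.5])
    trace: list[float] = []
    for _ in range(max_iter):
        # E step
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var)[np.newaxis, :]
            - 0.5 * (x[:, np.newaxis] - mu[np.newaxis, :]) ** 2 / var[np.newaxis, :]
            + np.log(w)[np.newaxis, :]
        )
        mx = log_pdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(log_pdf - mx).sum(axis=1))
        loglik = float(lse.sum())
        resp = np.exp(log_pdf - lse[:, np.newaxis])
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return {"means": mu, "vars": var, "weights": w, "loglik": trace,
                    "converged": False, "degenerate": True}
        w = nk / n
        mu = (resp * x[:, np.newaxis]).sum(axis=0) / nk
        var = (resp * (x[:, np.newaxis] - mu[np.newaxis, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-10)
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            break
    order = np.argsort(mu)
    return {
        "means": mu[order],
        "vars": var[order],
        "weights": w[order],
        "loglik": trace,
        "converged": len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol,
        "degenerate": bool(np.any(var < 1e-9) or np.any(w < 1e-3)),
    }


def fit_corr_threshold(
    similarities: np.ndarray,
    fallback: float = 0.0,
    min_n: int = 20,
    min_separation: float = 0.1,
) -> float:
    """Similarity rejection threshold from a two-component mixture.

    The threshold is the point between the two component means where
    the posterior responsibility of the higher-mean component crosses
    0.5. A threshold is only returned when the batch gives positive
    evidence of a genuinely bimodal similarity distribution — a
    foreign low-similarity population alongside the matching one.
    Otherwise the function falls back to ``fallback`` (0 disables
    correlation rejection): forcing a two-component fit onto a
    unimodal distribution would split it down the middle and reject
    half the confident cells. The evidence checks are (a) the
    two-component fit must beat a single Gaussian on BIC, (b) the
    component means must differ by at least ``min_separation``, and
    (c) the mixture density at the threshold must be a genuine valley
    (below half the density at either component mean).
    """
    x = np.asarray(similarities, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n or np.ptp(x) < 1e-12:
        return float(fallback)
    fit = gaussian_mixture_em(x)
    mu, var, w = fit["means"], fit["vars"], fit["weights"]
    if fit["degenerate"] or abs(mu[1] - mu[0]) < min_separation:
        return float(fallback)
    n = len(x)
    loglik2 = fit["loglik"][-1] if fit["loglik"] else -np.inf
    s2 = max(x.var(), 1e-12)
    loglik1 = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    bic1 = 2 * np.log(n) - 2 * loglik1
    bic2 = 5 * np.log(n) - 2 * loglik2
    if bic2 >= bic1:
        return float(fallback)

    def mix_pdf(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(t)
        comp = (
            w[np.newaxis, :]
            / np.sqrt(2 * np.pi * var)[np.newaxis, :]
            * np.exp(
                -0.5 * (t[:, np.newaxis] - mu[np.newaxis, :]) ** 2
                / var[np.newaxis, :]
            )
        )
        return comp.sum(axis=1)

    grid = np.linspace(mu[0], mu[1], 2001)
    log_pdf = (
        -0.5 * np.log(2 * np.pi * var)[np.newaxis, :]
        - 0.5 * (grid[:, np.newaxis] - mu[np.newaxis, :]) ** 2 / var[np.newaxis, :]
        + np.log(w)[np.newaxis, :]
    )
    post_high = 1.0 / (1.0 + np.exp(log_pdf[:, 0] - log_pdf[:, 1]))
    crossing = np.flatnonzero(post_high >= 0.5)
    if len(crossing) == 0:
        return float(fallback)
    thr = float(grid[crossing[0]])
    if mix_pdf(np.array([thr]))[0] > 0.5 * min(mix_pdf(mu[0:1])[0], mix_pdf(mu[1:2])[0]):
        return float(fallback)
    return thr


def node_predict(
    model: NodeModel,
    ref_values: np.ndarray,
    ref_gene_row: dict[str, int],
    ref_leaf_labels: np.ndarray,
    query_values: np.ndarray,
    query_gene_row: dict[str, int],
    config: RunConfig,
    return_diagnostics: bool = False,
):
    """Ensemble prediction at one branch node for a batch of query cells.

    ``ref_values``/``query_values`` are genes x cells with row lookups
    given by the gene-id -> row dictionaries; reference columns must
    already be restricted to the node's cells. Returns an object-dtype
    array of child node ids or "unassigned" together with the winning
    label's ensemble weight share (positive-alpha fraction of agreeing
    classifiers), plus a diagnostics list of per-base votes when
    requested.
    """
    nq = query_values.shape[1]
    super_labels = np.empty(ref_values.shape[1], dtype=object)
    for cid, types in model.child_types.items():
        super_labels[np.isin(ref_leaf_labels, types)] = cid

    per_base: list[tuple[np.ndarray, np.ndarray, np.ndarray] | None] = []
    for bc in model.base:
        genes = [g for g in bc.gene_ids if g in query_gene_row and g in ref_gene_row]
        if len(genes) < 2:
            per_base.append(None)
            continue
        R = ref_values[[ref_gene_row[g] for g in genes], :].T
        Q = query_values[[query_gene_row[g] for g in genes], :].T
        sims = pairwise_similarity(Q, R, bc.metric, config.jaccard_threshold)
        per_base.append(_batch_vote(sims, super_labels, config.k))

    # Rejection thresholds are fitted per base classifier and per
    # winning child: each (selection, metric) pair has its own
    # similarity scale, and different children can have different
    # intrinsic within-type similarity levels, so only bimodality
    # *within* the pool of cells voting for one child is evidence of a
    # foreign population.
    thresholds: list[dict[str, float]] = []
    for res in per_base:
        if res is None:
            thresholds.append({c: 0.0 for c in model.children})
        elif isinstance(config.corr_threshold, str):  # dynamic
            winners, _, max_sim = res
            per_child: dict[str, float] = {}
            for c in model.children:
                mask = winners == c
                per_child[c] = fit_corr_threshold(
                    max_sim[mask],
                    fallback=config.fallback_corr_threshold,
                    min_n=config.min_mixture_n,
                )
            thresholds.append(per_child)
        else:
            thresholds.append(
                {c: float(config.corr_threshold) for c in model.children}
            )

    candidates = sorted(model.children) + [UNASSIGNED]
    out = np.empty(nq, dtype=object)
    diagnostics: list[dict] = []
    votes_per_base: list[np.ndarray] = []
    for bc, res, thr in zip(model.base, per_base, thresholds):
        votes = np.full(nq, UNASSIGNED, dtype=object)
        if res is not None:
            winners, shares, max_sim = res
            for i in range(nq):
                if (
                    winners[i] is not None
                    and max_sim[i] >= thr[winners[i]]
                    and shares[i] >= config.weight_threshold
                ):
                    votes[i] = winners[i]
        votes_per_base.append(votes)

    alphas = model.alpha_vector
    pos = np.maximum(alphas, 0.0)
    pos_total = float(pos.sum())
    shares = np.zeros(nq)
    for i in range(nq):
        scores = {c: 0.0 for c in candidates}
        agree = {c: 0.0 for c in candidates}
        for t, votes in enumerate(votes_per_base):
            scores[votes[i]] += alphas[t]
            agree[votes[i]] += pos[t]
        out[i] = max(candidates, key=lambda c: scores[c])
        shares[i] = agree[out[i]] / pos_total if pos_total > 0 else 0.0
        if return_diagnostics:
            diagnostics.append(
                {
                    "scores": dict(scores),
                    "votes": [v[i] for v in votes_per_base],
                    "thresholds": list(thresholds),
                }
            )
    if return_diagnostics:
        return out, shares, diagnostics
    return out, shares
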