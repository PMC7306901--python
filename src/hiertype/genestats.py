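"""Per-gene discriminative statistics for one-vs-rest contrasts.

Five statistics, each picking up a different kind of cell-type signal:

* DE  - differential mean expression (moderated t on log expression,
        with an empirical-Bayes variance squeeze toward the
        mean-variance trend);
* DV  - differential variability (Bartlett's test);
* DD  - differential distribution (two-sample Kolmogorov-Smirnov);
* DP  - differential proportion expressed (chi-squared on the 2x2
        group-by-expressed table);
* BD  - bimodality index ranking.

Every statistic returns the same tabular layout (a ``GeneStatTable``
DataFrame) so the downstream top-gene filter is uniform.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

#: prior degrees of freedom of the variance squeeze in :func:`de_stat`
DE_PRIOR_DF = 4.0

COLUMNS = ["gene_id", "statistic", "p_value", "adj_p", "effect", "prop_diff"]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if len(p) == 0:
        return p.copy()
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _group_arrays(expr: np.ndarray, in_group, out_group):
    expr = np.asarray(expr, dtype=float)
    in_group = np.asarray(in_group)
    out_group = np.asarray(out_group)
    if in_group.dtype != bool:
        raise ValueError("group selectors must be boolean masks over cells")
    X1 = expr[:, in_group]
    X2 = expr[:, out_group]
    if X1.shape[1] < 2 or X2.shape[1] < 2:
        raise ValueError("each group needs at least 2 cells")
    return X1, X2


def _prop_diff(X1: np.ndarray, X2: np.ndarray, threshold: float) -> np.ndarray:
    return (X1 > threshold).mean(axis=1) - (X2 > threshold).mean(axis=1)


def _table(
    gene_ids, statistic, p_value, adj_p, effect, prop_diff, method: str
) -> pd.DataFrame:
    tab = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "statistic": statistic,
            "p_value": p_value,
            "adj_p": adj_p,
            "effect": effect,
            "prop_diff": prop_diff,
        }
    )
    tab.attrs["method"] = method
    return tab


def de_stat(
    expr: np.ndarray,
    in_group: np.ndarray,
    out_group: np.ndarray,
    gene_ids: list[str],
    expr_threshold: float = 1.0,
) -> pd.DataFrame:
    """Moderated two-sample t-test on log expression.

    Per-gene pooled variances are squeezed toward a lowess trend of
    log-variance against mean expression (a limma-trend style
    empirical-Bayes moderation with ``DE_PRIOR_DF`` prior degrees of
    freedom); the effect column is the log-fold-change (difference of
    group means on the log scale).
    """
    X1, X2 = _group_arrays(expr, in_group, out_group)
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    amean = (n1 * m1 + n2 * m2) / (n1 + n2)
    positive = sp2 > 0
    prior = np.full_like(sp2, np.nan)
    if positive.sum() >= 10:
        smooth = lowess(
            np.log(sp2[positive]), amean[positive], frac=0.5, return_sorted=False
        )
        prior[positive] = np.exp(smooth)
    else:
        prior[positive] = sp2[positive]
    d0 = DE_PRIOR_DF
    s2_mod = np.where(positive, (d0 * prior + df * sp2) / (d0 + df), 0.0)

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    effect = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df + d0), 1.0)
    return _table(
        gene_ids, t, p, bh_adjust(p), effect, _prop_diff(X1, X2, expr_threshold), "DE"
    )


def dv_stat(
    expr: np.ndarray,
    in_group: np.ndarray,
    out_group: np.ndarray,
    gene_ids: list[str],
    expr_threshold: float = 1.0,
) -> pd.DataFrame:
    """Bartlett's test of equal variances between the two groups."""
    X1, X2 = _group_arrays(expr, in_group, out_group)
    n1, n2 = X1.shape[1], X2.shape[1]
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    N, k = n1 + n2, 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (N - k)
    C = 1.0 + (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (N - k)) / (3.0 * (k - 1))
    ok = (v1 > 0) & (v2 > 0)
    stat = np.zeros(len(v1))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (
            (N - k) * np.log(sp2) - (n1 - 1) * np.log(v1) - (n2 - 1) * np.log(v2)
        ) / C
    stat[ok] = np.maximum(raw[ok], 0.0)
    p = np.where(ok, stats.chi2.sf(stat, k - 1), 1.0)
    return _table(
        gene_ids,
        stat,
        p,
        bh_adjust(p),
        np.full(len(stat), np.nan),
        _prop_diff(X1, X2, expr_threshold),
        "DV",
    )


def dd_stat(
    expr: np.ndarray,
    in_group: np.ndarray,
    out_group: np.ndarray,
    gene_ids: list[str],
    expr_threshold: float = 1.0,
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov test per gene (asymptotic p-values)."""
    X1, X2 = _group_arrays(expr, in_group, out_group)
    stat = np.empty(X1.shape[0])
    p = np.empty(X1.shape[0])
    for g in range(X1.shape[0]):
        res = stats.ks_2samp(X1[g], X2[g], method="asymp")
        stat[g], p[g] = res.statistic, res.pvalue
    return _table(
        gene_ids,
        stat,
        np.minimum(p, 1.0),
        bh_adjust(np.minimum(p, 1.0)),
        np.full(len(stat), np.nan),
        _prop_diff(X1, X2, expr_threshold),
        "DD",
    )


def dp_stat(
    expr: np.ndarray,
    in_group: np.ndarray,
    out_group: np.ndarray,
    gene_ids: list[str],
    expr_threshold: float = 1.0,
) -> pd.DataFrame:
    """Chi-squared test on the 2x2 group-by-expressed table.

    A cell "expresses" a gene when its log expression exceeds
    ``expr_threshold`` (default 1 for log-transformed data); no
    continuity correction is applied.
    """
    X1, X2 = _group_arrays(expr, in_group, out_group)
    n1, n2 = X1.shape[1], X2.shape[1]
    a = (X1 > expr_threshold).sum(axis=1).astype(float)  # expressed, in-group
    c = (X2 > expr_threshold).sum(axis=1).astype(float)
    b, d = n1 - a, n2 - c
    n = float(n1 + n2)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    p = np.where(denom > 0, stats.chi2.sf(stat, 1), 1.0)
    prop_diff = a / n1 - c / n2
    return _table(gene_ids, stat, p, bh_adjust(p), np.full(len(stat), np.nan), prop_diff, "DP")


def bd_stat(
    expr: np.ndarray,
    in_group: np.ndarray,
    out_group: np.ndarray,
    gene_ids: list[str],
    expr_threshold: float = 1.0,
) -> pd.DataFrame:
    """Bimodality index: BI = |m1 - m2| / s * sqrt(p (1 - p)).

    ``m1``/``m2`` are the group means, ``s`` the assumed common
    (pooled) standard deviation and ``p`` the in-group cell proportion.
    The index carries no p-value; genes are ranked by BI directly, so
    ``adj_p`` is set to 0 to make the adjusted-P filter a no-op.
    """
    X1, X2 = _group_arrays(expr, in_group, out_group)
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    s = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    p_mix = n1 / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        bi = np.where(s > 0, np.abs(m1 - m2) / s * np.sqrt(p_mix * (1 - p_mix)), 0.0)
    return _table(
        gene_ids,
        bi,
        np.full(len(bi), np.nan),
        np.zeros(len(bi)),
        m1 - m2,
        _prop_diff(X1, X2, expr_threshold),
        "BD",
    )


STAT_FUNCS = {
    "DE": de_stat,
    "DV": dv_stat,
    "DD": dd_stat,
    "DP": dp_stat,
    "BD": bd_stat,
}


def select_top(
    table: pd.DataFrame,
    max_genes: int = 50,
    adjp_cut: float = 0.01,
    propdiff_cut: float = 0.05,
    fc_cut: float = 1.0,
) -> list[str]:
    """Filter and rank a GeneStatTable into at most ``max_genes`` genes.

    Genes must pass ``adj_p < adjp_cut`` (skipped for BD, which has no
    p-value and ranks by the index itself) and move the expressed-cell
    proportion by more than ``propdiff_cut`` in either direction
    (variance- or shape-changing genes can lower it). DE additionally
    requires a fold-change above ``fc_cut`` (natural scale; the
    default 1 keeps any up-regulated gene). Ranking is by adjusted P
    (BD: descending index), ties broken by larger \\|effect\\| then by
    gene id.
    """
    method = table.attrs.get("method", "")
    mask = np.abs(table["prop_diff"].to_numpy()) > propdiff_cut
    if method == "BD":
        primary = -table["statistic"].to_numpy()
    else:
        mask &= table["adj_p"].to_numpy() < adjp_cut
        primary = table["adj_p"].to_numpy()
    if method == "DE":
        mask &= table["effect"].to_numpy() > np.log2(fc_cut)
    sub = table.loc[mask].copy()
    if sub.empty:
        return []
    sub["_primary"] = primary[mask]
    sub["_abs_effect"] = -np.abs(np.nan_to_num(sub["effect"].to_numpy()))
    sub = sub.sort_values(["_primary", "_abs_effect", "gene_id"], kind="stable")
    return sub["gene_id"].head(max_genes).tolist()
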