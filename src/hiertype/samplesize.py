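"""Learning curves, required-sample-size inversion and UMI down-sampling.

Accuracy as a function of training-set size is modelled by an inverse
power law saturating at a plateau ``alpha``. The printed form
``a_n = b n^(-c) + alpha`` requires a negative ``b`` for accuracy to
increase toward the plateau; this module uses the equivalent
parameterization ``a_n = alpha - b n^(-c)`` with ``b > 0`` throughout.
A two-component variant fits separate (b, c) pairs below and above a
transition point ``d`` chosen by residual sum of squares over a grid.

Down-sampling thins UMI counts with a beta-binomial capture model:
``z ~ BetaBinomial(x, rho, p_k)`` with per-entry correlation
``logit(rho) = tau0 + tau1 * log(x + 0.1)``, so ``p_k`` acts as the
relative capture efficiency of the thinned data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .classify import predict, train_classifier
from .config import RunConfig
from .containers import CellAnnotation, CountMatrix, ExpressionMatrix, ValidationError
from .evaluate import accuracy, evaluate_predictions


@dataclass
class LearningCurve:
    """Fitted inverse-power-law learning curve."""

    kind: str  # "single" | "two_component"
    params: dict  # single: b, c, alpha; two_component: b1,c1,b2,c2,d,alpha
    rss: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("single", "two_component"):
            raise ValueError(f"unknown curve kind {self.kind!r}")


@dataclass
class CaptureModel:
    """Beta-binomial capture model parameters for down-sampling."""

    tau0: float
    tau1: float
    p_k: float

    def __post_init__(self) -> None:
        if not 0 < self.p_k <= 1:
            raise ValidationError("p_k must be in (0, 1]")

    def rho(self, x: np.ndarray) -> np.ndarray:
        logit = self.tau0 + self.tau1 * np.log(np.asarray(x, dtype=float) + 0.1)
        return 1.0 / (1.0 + np.exp(-logit))


def _stratified_split(
    labels: np.ndarray, n_train: int, rng: np.random.Generator, min_per_type: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Training indices of size ~n_train keeping >= min_per_type per type."""
    n = len(labels)
    types = sorted(set(labels))
    if n_train < min_per_type * len(types) or n_train >= n:
        raise ValidationError(
            f"cannot draw {n_train} training cells from {n} with "
            f"{len(types)} types"
        )
    train: list[np.ndarray] = []
    for t in types:
        idx = np.flatnonzero(labels == t)
        quota = max(min_per_type, int(round(n_train * len(idx) / n)))
        quota = min(quota, len(idx) - 1)  # keep at least one test cell per type
        train.append(rng.choice(idx, size=quota, replace=False))
    tr = np.sort(np.concatenate(train))
    te = np.setdiff1d(np.arange(n), tr)
    return tr, te


def accuracy_grid(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    ns: list[int],
    T: int = 20,
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Empirical accuracy at each training size over T random splits.

    For each (n, t) the data are split into a stratified training set
    of about n cells and a test set of the remainder; a classifier is
    trained on the former and scored on the latter with the rule that
    counts correct intermediate assignments as correct.
    """
    config = config or RunConfig()
    labels = ann.label_array(expr.cell_ids)
    ref_types = set(labels)
    rng = np.random.default_rng(seed)
    rows = []
    for n in sorted(ns):
        for t in range(1, T + 1):
            tr, te = _stratified_split(labels, n, rng)
            sub_expr = ExpressionMatrix(
                expr.values[:, tr],
                list(expr.gene_ids),
                [expr.cell_ids[i] for i in tr],
                expr.normalized,
            )
            sub_ann = CellAnnotation(
                {expr.cell_ids[i]: labels[i] for i in tr}
            )
            clf = train_classifier(sub_expr, sub_ann, config)
            test_expr = ExpressionMatrix(
                expr.values[:, te],
                list(expr.gene_ids),
                [expr.cell_ids[i] for i in te],
                expr.normalized,
            )
            records = predict(clf, test_expr)
            truth = CellAnnotation({expr.cell_ids[i]: labels[i] for i in te})
            evals = evaluate_predictions(records, truth, ref_types, clf.tree)
            rows.append((int(n), t, accuracy(evals, "with_both")))
    return pd.DataFrame(rows, columns=["n", "t", "accuracy"])


def mean_accuracy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average accuracy per sample size from an accuracy table."""
    g = table.groupby("n")["accuracy"].mean()
    return g.index.to_numpy(float), g.to_numpy(float)


def _single_model(theta: np.ndarray, n: np.ndarray) -> np.ndarray:
    b, c, alpha = theta
    return alpha - b * n ** (-c)


def fit_curve(ns: np.ndarray, a_n: np.ndarray) -> LearningCurve:
    """Nonlinear least-squares fit of ``a_n = alpha - b n^(-c)``.

    Uses multi-start trust-region least squares with positivity bounds
    on b and c and ``alpha`` in (0, 1]. Nearly flat data produce a
    fit flagged degenerate (b ~ 0 leaves c unidentifiable).
    """
    ns = np.asarray(ns, dtype=float)
    a_n = np.asarray(a_n, dtype=float)
    if len(ns) != len(a_n) or len(np.unique(ns)) < 4:
        raise ValidationError("need >= 4 distinct sample sizes")

    lo = np.array([1e-12, 1e-12, 1e-6])
    hi = np.array([1e6, 50.0, 1.0])
    alpha0 = min(float(a_n.max()) + 0.02, 1.0)
    best = None
    for c0 in (0.1, 0.25, 0.5, 1.0, 2.0):
        gap = max(alpha0 - float(a_n.min()), 1e-6)
        b0 = gap * float(ns.min()) ** c0
        x0 = np.clip(np.array([b0, c0, alpha0]), lo, hi)
        try:
            res = least_squares(
                lambda th: _single_model(th, ns) - a_n,
                x0,
                bounds=(lo, hi),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # noqa: BLE001 - keep scanning starts
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError("learning-curve fit failed from every start")
    rss, (b, c, alpha) = best
    degenerate = b < 1e-8 or float(np.std(a_n)) < 1e-12
    return LearningCurve(
        "single",
        {"b": float(b), "c": float(c), "alpha": float(alpha)},
        rss,
        degenerate,
    )


def _two_model(theta: np.ndarray, n: np.ndarray, d: float) -> np.ndarray:
    b1, c1, b2, c2, alpha = theta
    small = n < d
    out = np.empty_like(n, dtype=float)
    out[small] = alpha - b1 * n[small] ** (-c1)
    out[~small] = alpha - b2 * n[~small] ** (-c2)
    return out


def fit_two_component(
    ns: np.ndarray, a_n: np.ndarray, d_grid: list[float] | None = None
) -> LearningCurve:
    """Two-component inverse power law with a transition point d.

    For each candidate d the remaining five parameters are fit by
    least squares (no continuity constraint at d, matching the
    indicator form of the model) and the d with the smallest residual
    sum of squares wins; ties go to the smaller d. The default grid
    is the interior of the observed sample sizes.
    """
    ns = np.asarray(ns, dtype=float)
    a_n = np.asarray(a_n, dtype=float)
    uniq = np.unique(ns)
    if len(uniq) < 6:
        raise ValidationError("two-component fit needs >= 6 distinct sample sizes")
    if d_grid is None:
        d_grid = list(uniq[2:-1])  # >= 2 points below, >= 2 above each d
    single = fit_curve(ns, a_n)
    s = single.params
    lo = np.array([1e-12, 1e-12, 1e-12, 1e-12, 1e-6])
    hi = np.array([1e6, 50.0, 1e6, 50.0, 1.0])

    best = None
    for d in d_grid:
        d = float(d)
        if (ns < d).sum() < 2 or (ns >= d).sum() < 2:
            continue
        starts = [
            np.array([s["b"], s["c"], s["b"], s["c"], s["alpha"]]),
            np.array([2 * s["b"], s["c"], 0.5 * s["b"], s["c"], s["alpha"]]),
        ]
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            try:
                res = least_squares(
                    lambda th: _two_model(th, ns, d) - a_n,
                    x0,
                    bounds=(lo, hi),
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                )
            except Exception:  # noqa: BLE001
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0] - 1e-14:
                best = (rss, res.x, d)
    if best is None:
        raise RuntimeError("two-component fit failed on the whole grid")
    rss, (b1, c1, b2, c2, alpha), d = best
    if d in (d_grid[0], d_grid[-1]):
        warnings.warn(f"selected transition point d={d} lies on the grid boundary")
    return LearningCurve(
        "two_component",
        {
            "b1": float(b1),
            "c1": float(c1),
            "b2": float(b2),
            "c2": float(c2),
            "d": float(d),
            "alpha": float(alpha),
        },
        rss,
    )


def predict_accuracy(curve: LearningCurve, n: float | np.ndarray):
    """Expected accuracy at sample size n under a fitted curve."""
    n = np.asarray(n, dtype=float)
    p = curve.params
    if curve.kind == "single":
        out = p["alpha"] - p["b"] * n ** (-p["c"])
    else:
        out = np.where(
            n < p["d"],
            p["alpha"] - p["b1"] * n ** (-p["c1"]),
            p["alpha"] - p["b2"] * n ** (-p["c2"]),
        )
    return float(out) if out.ndim == 0 else out


def required_n(curve: LearningCurve, target_a: float) -> float:
    """Smallest sample size reaching the target accuracy.

    Raises for targets at or above the plateau alpha, which no sample
    size can reach.
    """
    p = curve.params
    if target_a >= p["alpha"]:
        raise ValidationError(
            f"unreachable accuracy: target {target_a} >= plateau {p['alpha']}"
        )
    if curve.kind == "single":
        return float((p["b"] / (p["alpha"] - target_a)) ** (1.0 / p["c"]))
    n2 = (p["b2"] / (p["alpha"] - target_a)) ** (1.0 / p["c2"])
    if n2 >= p["d"]:
        return float(n2)
    n1 = (p["b1"] / (p["alpha"] - target_a)) ** (1.0 / p["c1"])
    return float(n1) if n1 < p["d"] else float(p["d"])


def downsample_counts(
    counts: CountMatrix, capture: CaptureModel, seed: int = 0
) -> CountMatrix:
    """Beta-binomial thinning of a UMI count matrix.

    Each entry x is replaced by ``z ~ BetaBinomial(x, rho, p_k)``
    drawn as Binomial(x, q) with q ~ Beta(a, b),
    a = p_k (1 - rho) / rho and b = (1 - p_k)(1 - rho) / rho, so
    E[z] = p_k * x and z <= x always. p_k = 1 returns the counts
    unchanged.
    """
    x = np.asarray(counts.values)
    if capture.p_k == 1.0:
        return CountMatrix(x.copy(), list(counts.gene_ids), list(counts.cell_ids))
    rng = np.random.default_rng(seed)
    out = np.zeros_like(x)
    nz = x > 0
    xv = x[nz].astype(float)
    rho = capture.rho(xv)
    a = capture.p_k * (1.0 - rho) / rho
    b = (1.0 - capture.p_k) * (1.0 - rho) / rho
    q = rng.beta(a, b)
    out[nz] = rng.binomial(x[nz].astype(np.int64), q)
    return CountMatrix(out, list(counts.gene_ids), list(counts.cell_ids))
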