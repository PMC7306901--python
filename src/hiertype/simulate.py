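"""Synthetic hierarchical scRNA-seq data with planted marker genes.

The generator draws UMI counts from a negative-binomial model with
per-cell library-size variation and a hierarchy of cell types given as
a nested blueprint. At every branch node each child gets five planted
marker-gene blocks, one per discriminative-gene category:

* DE - mean fold-shift in the child's cells;
* DV - extra (mean-preserving) log-normal dispersion of the mean;
* DD - mean-preserving two-point mixture of the per-cell mean,
  changing the distribution shape at equal expectation;
* DP - low-baseline genes whose expressed proportion rises in the
  child;
* BD - a 50/50 within-child mixture of unshifted and strongly shifted
  means, i.e. bimodal expression inside the child.

All effect magnitudes scale linearly with ``separation``; separation 0
gives an exchangeable null with no planted signal. A fixed seed yields
byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellAnnotation, CountMatrix, ValidationError
from .tree import CellTypeTree, tree_from_blueprint

CATEGORIES = ("DE", "DV", "DD", "DP", "BD")

# baseline expression model (log2 mean counts) and library-size spread
BASELINE_LOC = 1.5
BASELINE_SCALE = 0.8
BASELINE_MIN = -2.0
LIBSIZE_SD = 0.3
DP_BASELINE = -1.5  # low baseline so the expressed proportion can move
#: marker genes sit at a moderate, detectable baseline — variance- and
#: shape-type effects are invisible on the log scale for genes whose
#: counts are mostly 0/1, and real marker genes are expressed genes
MARKER_BASELINE = 1.5
#: variance/shape markers need a higher baseline: on mostly-zero genes
#: the log scale cannot express a variance or shape change
DVDD_BASELINE = 3.0
#: bimodal markers start near-silent and switch "on" in half the
#: child's cells, the classic on/off marker pattern the bimodality
#: index targets
BD_BASELINE = -1.0

#: sd (log2) of the genome-wide lineage perturbation each branch-node
#: child inherits: related subtypes share broad expression programs
#: beyond their discrete markers, which is what lets a hierarchy be
#: recovered from mean profiles over any wide gene set
LINEAGE_SD = 0.6
#: on top of the smooth perturbation, each lineage switches a fraction
#: of genes strongly on or off — distinct cell classes differ in which
#: genes are expressed at all, not just in expression level
LINEAGE_FLIP_FRAC = 0.12
LINEAGE_FLIP_SHIFT = 2.5
#: attenuation of planted marker effects per level below the root:
#: subtypes of one class are separated by weaker signals than classes
SUBTYPE_MARKER_SCALE = 0.35

# per-unit-separation effect magnitudes
DE_SHIFT = 2.0  # log2 fold shift
DV_SIGMA = 1.2  # natural-log sd of the mean-preserving multiplier
DD_DELTA = 0.75  # two-point multipliers 1 +/- delta (capped below 1)
DP_SHIFT = 1.5  # log2 shift of low-baseline genes
BD_SHIFT = 4.0  # log2 shift of the "on" half of the child's cells


@dataclass
class PopulationSpec:
    """Specification of a synthetic hierarchical cell population."""

    tree_blueprint: dict
    cells_per_type: int | dict = 200
    n_genes: int = 2000
    markers_per_category: int = 10
    dispersion: float = 5.0
    separation: float = 1.0
    seed: int = 0
    #: multiplier on the broad lineage-divergence programs; 0 leaves the
    #: planted marker blocks as the only between-type signal
    lineage_scale: float = 1.0
    #: explicit plan (node_id -> child_id -> category -> gene indices);
    #: left empty, a deterministic block allocation is generated.
    marker_plan: dict = field(default_factory=dict)

    def tree(self) -> CellTypeTree:
        return tree_from_blueprint(self.tree_blueprint)

    def n_cells(self, label: str) -> int:
        if isinstance(self.cells_per_type, dict):
            n = int(self.cells_per_type[label])
        else:
            n = int(self.cells_per_type)
        if n < 2:
            raise ValidationError(f"cells_per_type for {label!r} must be >= 2")
        return n

    def resolve_marker_plan(self) -> dict:
        """Per-node, per-child, per-category planted gene indices."""
        if self.marker_plan:
            plan = self.marker_plan
        else:
            plan = {}
            cursor = 0
            for node in self.tree().internal_nodes():
                plan[node.node_id] = {}
                for child in node.children:
                    blocks = {}
                    for cat in CATEGORIES:
                        blocks[cat] = list(
                            range(cursor, cursor + self.markers_per_category)
                        )
                        cursor += self.markers_per_category
                    plan[node.node_id][child.node_id] = blocks
        highest = max(
            (g for node in plan.values() for child in node.values()
             for idx in child.values() for g in idx),
            default=-1,
        )
        if highest >= self.n_genes:
            raise ValidationError(
                f"marker plan uses gene index {highest} >= n_genes={self.n_genes}"
            )
        return plan

    def with_single_category(self, category: str) -> "PopulationSpec":
        """Copy of this spec planting only one marker-gene category.

        Useful for measuring one statistic's recall of its own signal
        class against a null background, without the cross-detection
        that simultaneous planting of all five categories causes (a
        strong on/off bimodal gene is also a strong variance signal,
        a strong fold-shift also a strong distribution shift). The
        broad lineage programs are switched off for the same reason —
        they are real differential signal that would crowd the
        rankings.
        """
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        plan = {
            node: {
                child: {category: list(blocks[category])}
                for child, blocks in children.items()
            }
            for node, children in self.resolve_marker_plan().items()
        }
        return PopulationSpec(
            tree_blueprint=self.tree_blueprint,
            cells_per_type=self.cells_per_type,
            n_genes=self.n_genes,
            markers_per_category=self.markers_per_category,
            dispersion=self.dispersion,
            separation=self.separation,
            seed=self.seed,
            lineage_scale=0.0,
            marker_plan=plan,
        )


def _leaf_log_means(spec: PopulationSpec, baseline: np.ndarray, tree, plan,
                    struct_rng: np.random.Generator):
    """Per-leaf log2 mean vectors plus per-leaf category flags.

    Besides the planted marker blocks, every branch-node child carries
    a genome-wide random lineage perturbation shared by all its
    descendant leaves, so related subtypes stay correlated on broad
    gene sets the way real lineages are.
    """
    leaves = tree.labels()
    log_means = {t: baseline.copy() for t in leaves}
    # lineage divergence separates the top-level classes (children of
    # the root) in whole expression programs; subtypes deeper in the
    # tree differ only through their planted marker blocks, the way
    # subtypes of one class share a common broad transcriptome
    for child in tree.root.children:
        shift = struct_rng.normal(0.0, LINEAGE_SD, spec.n_genes)
        flips = struct_rng.random(spec.n_genes) < LINEAGE_FLIP_FRAC
        signs = struct_rng.integers(0, 2, spec.n_genes) * 2 - 1
        shift[flips] += LINEAGE_FLIP_SHIFT * signs[flips]
        for t in child.cell_type_set:
            log_means[t] += shift * spec.separation * spec.lineage_scale
    flags = {t: {cat: np.zeros(spec.n_genes) for cat in ("DV", "DD", "BD")}
             for t in leaves}
    sep = spec.separation
    # marker baselines are pinned for every type: DP genes low (so the
    # expressed proportion can move), the rest moderate (detectable);
    # a plan may plant any subset of the five categories
    baselines = {
        "DE": MARKER_BASELINE,
        "DV": DVDD_BASELINE,
        "DD": DVDD_BASELINE,
        "DP": DP_BASELINE,
        "BD": BD_BASELINE,
    }
    for node in plan.values():
        for child in node.values():
            for t in leaves:
                for cat, level in baselines.items():
                    log_means[t][child.get(cat, [])] = level
    # marker effects below the top level are attenuated: subtype
    # distinctions within a class are subtler than class distinctions
    for node in tree.internal_nodes():
        scale = 1.0 if node.depth == 0 else SUBTYPE_MARKER_SCALE**node.depth
        for child in node.children:
            blocks = plan.get(node.node_id, {}).get(child.node_id, {})
            for t in child.cell_type_set:
                log_means[t][blocks.get("DE", [])] += DE_SHIFT * sep * scale
                log_means[t][blocks.get("DP", [])] += DP_SHIFT * sep * scale
                flags[t]["DV"][blocks.get("DV", [])] = scale
                flags[t]["DD"][blocks.get("DD", [])] = scale
                flags[t]["BD"][blocks.get("BD", [])] = scale
    return log_means, flags


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + mu^2/theta."""
    p = theta / (theta + np.maximum(mu, 1e-12))
    return rng.negative_binomial(theta, p)


def simulate_dataset(
    spec: PopulationSpec, sampling_seed: int | None = None
) -> tuple[CountMatrix, CellAnnotation, CellTypeTree]:
    """Draw a synthetic dataset; returns counts, annotation and true tree.

    ``sampling_seed`` redraws the cells while keeping the population
    structure (baseline means, marker plan) fixed by ``spec.seed`` —
    use it to generate independent query sets from the same population.
    """
    tree = spec.tree()
    plan = spec.resolve_marker_plan()
    struct_rng = np.random.default_rng(spec.seed)
    baseline = np.maximum(
        struct_rng.normal(BASELINE_LOC, BASELINE_SCALE, spec.n_genes), BASELINE_MIN
    )
    cell_rng = np.random.default_rng(
        spec.seed if sampling_seed is None else sampling_seed
    )
    log_means, flags = _leaf_log_means(spec, baseline, tree, plan, struct_rng)
    sep = spec.separation

    blocks, gene_ids = [], [f"g{j:04d}" for j in range(spec.n_genes)]
    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    for t in tree.labels():
        n = spec.n_cells(t)
        lib = np.exp(cell_rng.normal(0.0, LIBSIZE_SD, n))
        mu = 2.0 ** log_means[t][:, np.newaxis] * lib[np.newaxis, :]
        if sep > 0:
            dv = flags[t]["DV"] > 0
            if dv.any():
                sigma = DV_SIGMA * sep * flags[t]["DV"][dv][:, np.newaxis]
                mult = np.exp(
                    cell_rng.normal(0.0, 1.0, (int(dv.sum()), n)) * sigma
                    - 0.5 * sigma**2
                )
                mu[dv, :] *= mult
            dd = flags[t]["DD"] > 0
            if dd.any():
                delta = np.minimum(DD_DELTA * sep * flags[t]["DD"][dd], 0.95)
                sign = cell_rng.integers(0, 2, (int(dd.sum()), n)) * 2 - 1
                mu[dd, :] *= 1.0 + delta[:, np.newaxis] * sign
            bd = flags[t]["BD"] > 0
            if bd.any():
                on = cell_rng.integers(0, 2, (int(bd.sum()), n)).astype(bool)
                shift = 2.0 ** (BD_SHIFT * sep * flags[t]["BD"][bd])[:, np.newaxis]
                mu[bd, :] *= np.where(on, shift, 1.0)
        counts = _nb_sample(cell_rng, mu, spec.dispersion)
        blocks.append(counts)
        ids = [f"{t}.{i}" for i in range(n)]
        cell_ids.extend(ids)
        labels.update({c: t for c in ids})

    matrix = CountMatrix(np.concatenate(blocks, axis=1), gene_ids, cell_ids)
    return matrix, CellAnnotation(labels), tree


def simulate_mixture_cells(
    spec: PopulationSpec, type_a: str, type_b: str, n_cells: int, seed: int
) -> tuple[CountMatrix, CellAnnotation]:
    """Cells straddling two types: equal co-expression of both programs.

    Mean counts are the arithmetic average of the two types' mean
    counts, so each cell carries the shared (ancestral) signature at
    full strength and both private programs at half strength — the
    profile of a transitional or hybrid population that should stop
    at the two types' parent node rather than reach either leaf.
    """
    tree = spec.tree()
    plan = spec.resolve_marker_plan()
    struct_rng = np.random.default_rng(spec.seed)
    baseline = np.maximum(
        struct_rng.normal(BASELINE_LOC, BASELINE_SCALE, spec.n_genes), BASELINE_MIN
    )
    log_means, _ = _leaf_log_means(spec, baseline, tree, plan, struct_rng)
    for t in (type_a, type_b):
        if t not in log_means:
            raise ValidationError(f"unknown type {t!r}")
    rng = np.random.default_rng(seed)
    mean_counts = 0.5 * (2.0 ** log_means[type_a] + 2.0 ** log_means[type_b])
    lib = np.exp(rng.normal(0.0, LIBSIZE_SD, n_cells))
    mu = mean_counts[:, np.newaxis] * lib[np.newaxis, :]
    counts = _nb_sample(rng, mu, spec.dispersion)
    label = f"{type_a}+{type_b}"
    ids = [f"{label}.{i}" for i in range(n_cells)]
    gene_ids = [f"g{j:04d}" for j in range(spec.n_genes)]
    return (
        CountMatrix(counts, gene_ids, ids),
        CellAnnotation({c: label for c in ids}),
    )


def simulate_learning_points(
    b: float,
    c: float,
    alpha: float,
    ns: list[int],
    noise_sd: float = 0.0,
    T: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy draws around the inverse-power-law learning curve.

    The curve is parameterized as ``a_n = alpha - b * n**(-c)`` with
    ``b > 0`` so accuracy rises toward the plateau ``alpha``; values
    are clipped to [0, 1].
    """
    if b <= 0 or c <= 0 or not 0 < alpha <= 1:
        raise ValidationError("require b > 0, c > 0 and 0 < alpha <= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        if n < 2:
            raise ValidationError("sample sizes must be >= 2")
        mean = alpha - b * float(n) ** (-c)
        for t in range(1, T + 1):
            a = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((int(n), t, float(np.clip(a, 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["n", "t", "accuracy"])
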