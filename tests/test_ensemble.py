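import numpy as np
import pytest

from hiertype import RunConfig, ensemble_weight, fit_corr_threshold
from hiertype.ensemble import (
    UNASSIGNED,
    gaussian_mixture_em,
    node_predict,
    train_node,
)
from hiertype.tree import tree_from_blueprint


class TestEnsembleWeight:
    def test_symmetry_point(self):
        assert ensemble_weight(0.5) == 0.0

    def test_arithmetic(self):
        assert ensemble_weight(0.1) == pytest.approx(np.log(9))
        assert ensemble_weight(0.9) == pytest.approx(-np.log(9))

    def test_monotone_decreasing(self):
        eps = np.linspace(0.05, 0.95, 19)
        w = [ensemble_weight(e) for e in eps]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_bounds(self):
        with pytest.raises(ValueError):
            ensemble_weight(0.0)
        with pytest.raises(ValueError):
            ensemble_weight(1.0)


class TestMixtureEm:
    def test_loglik_non_decreasing(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.05, 100), rng.normal(0.8, 0.05, 100)])
        fit = gaussian_mixture_em(x)
        trace = np.asarray(fit["loglik"])
        assert np.all(np.diff(trace) >= -1e-8)

    def test_recovers_well_separated_components(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.05, 300), rng.normal(0.9, 0.02, 300)])
        fit = gaussian_mixture_em(x)
        assert fit["means"][0] == pytest.approx(0.2, abs=0.02)
        assert fit["means"][1] == pytest.approx(0.9, abs=0.02)
        assert fit["weights"][0] == pytest.approx(0.5, abs=0.05)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            gaussian_mixture_em(np.array([0.1, 0.2]))


class TestCorrThreshold:
    def test_bimodal_threshold_in_valley(self, rng):
        """Matches a posterior grid-scan oracle for the crossing point."""
        x = np.concatenate([rng.normal(0.2, 0.05, 250), rng.normal(0.9, 0.02, 250)])
        thr = fit_corr_threshold(x)
        assert 0.4 < thr < 0.8
        # oracle: empirical class posterior crossing on a fine grid
        fit = gaussian_mixture_em(x)
        mu, var, w = fit["means"], fit["vars"], fit["weights"]
        grid = np.linspace(mu[0], mu[1], 20001)
        dens = [
            w[i] / np.sqrt(2 * np.pi * var[i])
            * np.exp(-0.5 * (grid - mu[i]) ** 2 / var[i])
            for i in (0, 1)
        ]
        post = dens[1] / (dens[0] + dens[1])
        oracle = grid[np.argmax(post >= 0.5)]
        assert thr == pytest.approx(oracle, abs=1e-3)

    def test_single_tight_cluster_falls_back(self):
        assert fit_corr_threshold(np.full(100, 0.9), fallback=0.25) == 0.25

    def test_unimodal_gaussian_falls_back(self, rng):
        assert fit_corr_threshold(rng.normal(0.8, 0.05, 500), fallback=0.0) == 0.0

    def test_skewed_unimodal_falls_back(self, rng):
        x = 0.95 - 0.3 * rng.gamma(2.0, 0.08, 800)
        assert fit_corr_threshold(x, fallback=0.0) == 0.0

    def test_too_few_values_fall_back(self, rng):
        assert fit_corr_threshold(rng.normal(0, 1, 5), fallback=0.3) == 0.3


def _node_training_problem(rng, n_per=40, n_genes=120, shift=3.0, permute=False):
    """Two children, block mean shifts; optionally permuted labels."""
    tree = tree_from_blueprint({"L": None, "R": None})
    node = tree.root
    X = rng.normal(1.0, 0.8, (n_genes, 2 * n_per))
    X[:20, :n_per] += shift   # L markers
    X[20:40, n_per:] += shift  # R markers
    labels = np.array(["L"] * n_per + ["R"] * n_per, dtype=object)
    if permute:
        labels = labels[rng.permutation(2 * n_per)]
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    return X, gene_ids, labels, node


class TestTrainNode:
    CFG = RunConfig(selections=("DE",), metrics=("pearson", "spearman"),
                    seed=0, min_cells_per_type=5)

    def test_separated_children_small_eps_large_alpha(self, rng):
        X, genes, labels, node = _node_training_problem(rng)
        model = train_node(X, genes, labels, node, self.CFG)
        assert model is not None
        for bc in model.base:
            assert bc.eps_t == pytest.approx(0.01)  # clipped floor
            assert bc.alpha_t > 4.0

    def test_permuted_labels_near_chance(self, rng):
        X, genes, labels, node = _node_training_problem(rng, n_per=80, permute=True)
        model = train_node(X, genes, labels, node, self.CFG)
        assert model is not None
        for bc in model.base:
            assert 0.3 < bc.eps_t < 0.7
            assert abs(bc.alpha_t) < 1.0

    def test_unreachable_child_dropped(self, rng):
        X, genes, labels, node = _node_training_problem(rng)
        labels[labels == "R"] = "L"
        labels[:3] = "R"  # only 3 R cells, below min_cells_per_type
        with pytest.warns(UserWarning):
            model = train_node(X, genes, labels, node, self.CFG)
        assert model is None  # fewer than 2 reachable children

    def test_reproducible(self, rng):
        X, genes, labels, node = _node_training_problem(rng)
        m1 = train_node(X, genes, labels, node, self.CFG)
        m2 = train_node(X, genes, labels, node, self.CFG)
        assert np.array_equal(m1.alpha_vector, m2.alpha_vector)
        assert [b.gene_ids for b in m1.base] == [b.gene_ids for b in m2.base]


class TestNodePredict:
    def test_in_distribution_queries_assigned(self, rng):
        X, genes, labels, node = _node_training_problem(rng)
        cfg = TestTrainNode.CFG
        model = train_node(X, genes, labels, node, cfg)
        gene_row = {g: i for i, g in enumerate(genes)}
        # fresh cells from the same populations
        Q = rng.normal(1.0, 0.8, (120, 30))
        Q[:20, :15] += 3.0
        Q[20:40, 15:] += 3.0
        out, shares = node_predict(
            model, X, gene_row, labels, Q, gene_row, cfg
        )
        truth = np.array([model.children[0]] * 15 + [model.children[1]] * 15)
        acc = np.mean([o == t for o, t in zip(out, truth)])
        assert acc > 0.95
        assert np.all((shares >= 0) & (shares <= 1))

    def test_unanimous_votes_win_regardless_of_alpha(self, rng):
        X, genes, labels, node = _node_training_problem(rng)
        cfg = TestTrainNode.CFG
        model = train_node(X, genes, labels, node, cfg)
        gene_row = {g: i for i, g in enumerate(genes)}
        q = X[:, [0]]  # a reference L cell
        out, _ = node_predict(model, X, gene_row, labels, q, gene_row, cfg)
        # both base classifiers agree -> ensemble returns that child
        assert sorted(model.child_types[out[0]]) == ["L"]

    def test_fixed_threshold_rejects_weak_matches(self, rng):
        X, genes, labels, node = _node_training_problem(rng)
        cfg = RunConfig(selections=("DE",), metrics=("pearson",), seed=0,
                        min_cells_per_type=5, corr_threshold=0.999)
        model = train_node(X, genes, labels, node, cfg)
        gene_row = {g: i for i, g in enumerate(genes)}
        Q = rng.normal(1.0, 0.8, (120, 10))  # no marker structure
        out, _ = node_predict(model, X, gene_row, labels, Q, gene_row, cfg)
        assert np.all(out == UNASSIGNED)

    def test_zero_alpha_classifier_is_inert(self, rng):
        """Dropping a base classifier whose alpha is ~0 leaves ensemble
        predictions unchanged."""
        X, genes, labels, node = _node_training_problem(rng)
        cfg = TestTrainNode.CFG
        model = train_node(X, genes, labels, node, cfg)
        gene_row = {g: i for i, g in enumerate(genes)}
        Q = rng.normal(1.0, 0.8, (120, 20))
        Q[:20, :10] += 3.0
        Q[20:40, 10:] += 3.0
        out_full, _ = node_predict(model, X, gene_row, labels, Q, gene_row, cfg)
        import copy

        weak = copy.deepcopy(model)
        weak.base[1].alpha_t = 0.0
        out_zero, _ = node_predict(weak, X, gene_row, labels, Q, gene_row, cfg)
        weak.base = [weak.base[0]]
        out_dropped, _ = node_predict(weak, X, gene_row, labels, Q, gene_row, cfg)
        assert np.array_equal(out_zero, out_dropped)
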