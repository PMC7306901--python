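"""Shared synthetic fixtures for the test suite.

Everything is generated programmatically and deterministically; the
small fixtures keep unit tests fast, while the acceptance tests build
their own full-scale datasets.
"""
from __future__ import annotations

import numpy as np
import pytest

from hiertype import (
    CellAnnotation,
    PopulationSpec,
    RunConfig,
    simulate_dataset,
    train_classifier,
)
from hiertype.io import normalize_log


@pytest.fixture(scope="session")
def small_spec() -> PopulationSpec:
    return PopulationSpec(
        tree_blueprint={"A": None, "B": None, "C": None},
        cells_per_type=60,
        n_genes=600,
        markers_per_category=8,
        separation=1.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    counts, ann, tree = simulate_dataset(small_spec)
    return counts, ann, tree


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    counts, ann, tree = small_dataset
    return normalize_log(counts), ann, tree


@pytest.fixture(scope="session")
def fast_config() -> RunConfig:
    return RunConfig(
        selections=("DE",), metrics=("pearson",), seed=101, min_cells_per_type=5
    )


@pytest.fixture(scope="session")
def small_classifier(small_expr, fast_config):
    expr, ann, _ = small_expr
    return train_classifier(expr, ann, fast_config)


@pytest.fixture(scope="session")
def small_query(small_spec):
    counts, ann, _ = simulate_dataset(small_spec, sampling_seed=909)
    return normalize_log(counts), ann


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
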