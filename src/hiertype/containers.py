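"""Core in-memory containers: count/expression matrices and cell annotations.

The canonical orientation everywhere in this package is genes x cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Raw UMI/read counts, genes x cells.

    Parameters
    ----------
    values
        Non-negative integer array of shape (n_genes, n_cells).
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes x cells.

    ``normalized`` records whether size-factor normalization was applied
    before the log transform.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match id lists"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            self.values[rows, :], list(genes), list(self.cell_ids), self.normalized
        )

    def subset_cells(self, cells: list[str]) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in cells]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(cells), self.normalized
        )


@dataclass
class CellAnnotation:
    """Mapping cell id -> cell type label."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, lab in self.labels.items():
            if not str(lab):
                raise ValidationError(f"empty label for cell {cid!r}")
        self.labels = {str(c): str(l) for c, l in self.labels.items()}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, cell_id: str) -> str:
        return self.labels[cell_id]

    def label_array(self, cell_ids: list[str]) -> np.ndarray:
        missing = [c for c in cell_ids if c not in self.labels]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells missing annotation (e.g. {missing[:3]})"
            )
        return np.array([self.labels[c] for c in cell_ids], dtype=object)

    def types(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def validate_against(self, matrix) -> None:
        cells = set(matrix.cell_ids)
        missing = [c for c in self.labels if c not in cells]
        if missing:
            raise ValidationError(
                f"annotated cells absent from matrix (e.g. {missing[:3]})"
            )
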