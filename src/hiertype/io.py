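"""Reading/writing count matrices and annotations; normalization; model archives.

Supported on-disk formats
-------------------------
* MatrixMarket ``.mtx`` with ``genes.tsv`` / ``barcodes.tsv`` sidecars
  (1-based indices per the standard; sidecar lengths disambiguate
  orientation, which is coerced to genes x cells).
* Dense CSV/TSV with genes as rows, a header row of cell ids and the
  gene id in the first column.
* Annotation CSV with columns ``cell_id,label``.
* Model archives: a zip of JSON metadata plus ``.npy`` arrays.
"""
from __future__ import annotations

import io as _io
import json
import warnings
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellAnnotation, CountMatrix, ExpressionMatrix, ValidationError

MODEL_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed input files."""


def _read_sidecar(path: Path) -> list[str]:
    ids = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line:
            # 10x-style sidecars may carry extra tab-separated columns
            ids.append(line.split("\t")[0])
    return ids


def read_counts(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix from ``.mtx`` (+ sidecars) or dense CSV/TSV.

    For MatrixMarket input the gene and barcode files default to
    ``genes.tsv`` and ``barcodes.tsv`` next to the matrix. The stored
    orientation is detected by matching sidecar lengths against the
    matrix dimensions and transposed to genes x cells when needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            suffix
        )
        if format is None:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")

    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        for p in (genes_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar file: {p}")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        genes = _read_sidecar(genes_path)
        cells = _read_sidecar(barcodes_path)
        if mat.shape == (len(genes), len(cells)):
            pass
        elif mat.shape == (len(cells), len(genes)):
            mat = mat.T
        else:
            raise FormatError(
                f"matrix shape {mat.shape} matches neither "
                f"({len(genes)} genes, {len(cells)} cells) nor its transpose"
            )
        return CountMatrix(mat, genes, cells)

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"malformed {format} file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path} has no cell columns")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"{path} contains non-numeric entries")
        return CountMatrix(
            values, [str(g) for g in df.index], [str(c) for c in df.columns]
        )

    raise FormatError(f"unknown format {format!r}")


def write_counts(
    counts: CountMatrix,
    path: str | Path,
    format: str = "mtx",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> None:
    path = Path(path)
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        )
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.values))
        genes_path.write_text("\n".join(counts.gene_ids) + "\n")
        barcodes_path.write_text("\n".join(counts.cell_ids) + "\n")
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        counts.to_frame().to_csv(path, sep=sep)
    else:
        raise FormatError(f"unknown format {format!r}")


def read_annotation(path: str | Path) -> CellAnnotation:
    df = pd.read_csv(path)
    required = {"cell_id", "label"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    dup = df["cell_id"].duplicated()
    if dup.any():
        raise ValidationError("duplicate cell ids in annotation")
    return CellAnnotation(dict(zip(df["cell_id"].astype(str), df["label"].astype(str))))


def write_annotation(ann: CellAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": list(ann.labels), "label": list(ann.labels.values())}
    ).to_csv(path, index=False)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Library-size factors scaled to mean 1; all-zero cells get factor 1."""
    totals = counts.values.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.all():
        warnings.warn("all cells have zero counts; size factors set to 1")
        return np.ones_like(totals)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells; their size factor set to 1")
    mean_total = totals[~zero].mean()
    factors = totals / mean_total
    factors[zero] = 1.0
    return factors


def normalize_log(counts: CountMatrix) -> ExpressionMatrix:
    """Size-factor normalization followed by log2(x + 1).

    Each cell's counts are divided by its library-size factor
    (cell total / mean total), matching size-factor standardisation of
    raw counts, then log-transformed with pseudocount 1 in base 2.
    """
    factors = size_factors(counts)
    scaled = counts.values / factors[np.newaxis, :]
    return ExpressionMatrix(
        np.log2(scaled + 1.0),
        list(counts.gene_ids),
        list(counts.cell_ids),
        normalized=True,
    )


class ModelFormatError(ValueError):
    """Raised when a model archive is corrupt or has the wrong schema."""


def save_model(model, path: str | Path) -> None:
    """Serialize a model to a zip archive of JSON metadata + npy arrays.

    ``model`` must implement ``to_archive()`` returning
    ``(meta: dict, arrays: dict[str, ndarray])``.
    """
    meta, arrays = model.to_archive()
    meta = dict(meta)
    meta["schema_version"] = MODEL_SCHEMA_VERSION
    meta["class"] = type(model).__name__
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.save(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(f"{name}.npy", buf.getvalue())


def load_model(path: str | Path):
    """Load a model archive written by :func:`save_model`."""
    from . import classify, ensemble  # local import to avoid a cycle

    registry = {
        "TrainedClassifier": classify.TrainedClassifier,
        "NodeModel": ensemble.NodeModel,
    }
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("schema_version") != MODEL_SCHEMA_VERSION:
                raise ModelFormatError(
                    f"schema version {meta.get('schema_version')} != "
                    f"{MODEL_SCHEMA_VERSION}"
                )
            arrays = {}
            for name in zf.namelist():
                if name.endswith(".npy"):
                    arrays[name[:-4]] = np.load(
                        _io.BytesIO(zf.read(name)), allow_pickle=False
                    )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"corrupt model archive {path}: {exc}") from exc
    cls = registry.get(meta.get("class"))
    if cls is None:
        raise ModelFormatError(f"unknown model class {meta.get('class')!r}")
    return cls.from_archive(meta, arrays)
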