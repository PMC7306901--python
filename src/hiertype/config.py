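"""Run configuration shared by training, prediction and the CLI."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

ALL_SELECTIONS = ("DE", "DV", "DD", "BD", "DP")
ALL_METRICS = (
    "pearson",
    "spearman",
    "kendall",
    "cosine",
    "jaccard",
    "weighted_rank",
)


@dataclass
class RunConfig:
    """Tunable parameters of the classifier.

    Defaults follow the framework's standard settings: K = 10 nearest
    neighbours, ensemble weight threshold 0.7, at most 5 children per
    branch node, top-50 genes per contrast at adjusted P < 0.01 and
    proportion difference > 0.05, expression threshold 1 on the log2
    scale.
    """

    k: int = 10
    weight_threshold: float = 0.7
    #: "dynamic" fits a two-component Gaussian mixture per query batch;
    #: a float fixes the similarity rejection threshold for all metrics.
    corr_threshold: float | str = "dynamic"
    #: used when the mixture fit degenerates, finds no bimodality or has
    #: too few values: 0 disables correlation rejection in that case
    #: (the weight threshold still applies), since without a detected
    #: low-similarity component there is no evidence of foreign cells
    fallback_corr_threshold: float = 0.0
    kmax: int = 5
    selections: tuple[str, ...] = ALL_SELECTIONS
    metrics: tuple[str, ...] = ALL_METRICS
    seed: int = 0
    min_cells_per_type: int = 10
    #: log-scale expression above which a gene counts as "expressed"
    expr_threshold: float = 1.0
    #: fold-change filter for DE gene selection, natural (non-log) scale
    fc_cut: float = 1.0
    adjp_cut: float = 0.01
    max_genes: int = 50
    propdiff_cut: float = 0.05
    #: cap on reference cells used for leave-one-out training-error estimation
    eps_max_cells: int = 200
    #: log-expression threshold for binarizing vectors in the Jaccard metric
    jaccard_threshold: float = 0.0
    #: minimum fraction of model genes that must be present in a query
    gene_overlap_floor: float = 0.5
    #: minimum number of similarity values required to fit the mixture model
    min_mixture_n: int = 20

    def __post_init__(self) -> None:
        self.selections = tuple(self.selections)
        self.metrics = tuple(self.metrics)
        bad = set(self.selections) - set(ALL_SELECTIONS)
        if bad:
            raise ValueError(f"unknown gene selections: {sorted(bad)}")
        bad = set(self.metrics) - set(ALL_METRICS)
        if bad:
            raise ValueError(f"unknown similarity metrics: {sorted(bad)}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.weight_threshold <= 1:
            raise ValueError("weight_threshold must be in [0, 1]")
        if isinstance(self.corr_threshold, str) and self.corr_threshold != "dynamic":
            raise ValueError("corr_threshold must be 'dynamic' or a number")

    @property
    def n_base(self) -> int:
        return len(self.selections) * len(self.metrics)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` text config file."""
        d: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            d[key] = _parse_value(key, val)
        return cls.from_dict(d)


def _parse_value(key: str, val: str):
    if key in ("selections", "metrics"):
        return tuple(s.strip() for s in val.split(",") if s.strip())
    if key == "corr_threshold" and val == "dynamic":
        return val
    try:
        return int(val)
    except ValueError:
        pass
    try:
        return float(val)
    except ValueError:
        return val
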