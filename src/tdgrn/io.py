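"""Expression-matrix, edge-list and configuration I/O.

The on-disk formats are deliberately plain:

* expression matrix — TSV/CSV, first column gene identifier, remaining
  columns ordered time points (the column order IS the temporal order);
* edge list — two tab-separated columns ``regulator<TAB>target`` with an
  optional third lag column that is ignored on input;
* inferred network — ``regulator<TAB>target<TAB>lag<TAB>score``;
* run configuration — flat YAML/key-value mapping mirroring
  :class:`RunConfig` field names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionDataset",
    "GoldNetwork",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "normalize",
    "read_config",
    "write_config",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x time-points real expression matrix with identifiers.

    Rows are genes, columns are equally spaced time points in temporal
    order.  Values are arbitrary expression units; no missing values are
    allowed.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_timepoints)
    time_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if self.time_labels is not None:
            object.__setattr__(
                self, "time_labels", tuple(str(t) for t in self.time_labels)
            )
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = values.shape
        if n != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {n} expression rows"
            )
        if len(set(self.gene_ids)) != n:
            dupes = sorted(
                {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            )
            raise ValueError(f"duplicate gene ids: {', '.join(dupes)}")
        if n < 2:
            raise ValueError("need at least 2 genes")
        if m < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.time_labels is not None and len(self.time_labels) != m:
            raise ValueError("time_labels length does not match matrix width")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def index_of(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        cols = (
            list(self.time_labels)
            if self.time_labels is not None
            else [f"t{i}" for i in range(self.n_timepoints)]
        )
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=cols)


@dataclass(frozen=True)
class GoldNetwork:
    """Directed reference edge set used for evaluation.

    Self-loops are retained (some benchmark networks contain them) and
    flagged so that evaluation can choose whether the pair universe
    includes self-pairs.
    """

    edges: frozenset[tuple[str, str]]
    include_self_loops: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", frozenset((str(a), str(b)) for a, b in self.edges)
        )

    @property
    def self_loops(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, b in self.edges if a == b)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class BatConfig:
    """Bat-algorithm settings for parameter optimisation.

    Frequencies are drawn in ``[f_min, f_max]``; ``loudness0``/``pulse0``
    are the initial loudness A0 and pulse emission rate r0; ``alpha``
    shrinks loudness geometrically and ``gamma`` ramps the pulse rate.
    """

    n_bats: int = 30
    n_iters: int = 100
    f_min: float = 0.0
    f_max: float = 2.0
    loudness0: float = 0.9
    pulse0: float = 0.5
    alpha: float = 0.9
    gamma: float = 0.9

    def __post_init__(self) -> None:
        if self.f_min > self.f_max:
            raise ValueError("f_min must be <= f_max")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.gamma < 1.0):
            raise ValueError("alpha and gamma must lie in (0, 1)")


@dataclass
class OptimizerConfig:
    """Evolutionary structure-search settings for tree fitting."""

    pop_size: int = 50
    max_generations: int = 100
    crossover_prob: float = 0.7
    mutation_prob: float = 0.3
    tournament_size: int = 3
    param_opt_every: int = 5
    param_opt_fraction: float = 0.2
    target_rmse: float = 1e-3
    parsimony: float = 0.02
    max_depth: int = 4
    function_arities: tuple[int, ...] = (2, 3)
    bat: BatConfig = field(default_factory=BatConfig)

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        for p in (self.crossover_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 < self.param_opt_fraction <= 1.0):
            raise ValueError("param_opt_fraction must lie in (0, 1]")
        if self.parsimony < 0:
            raise ValueError("parsimony penalty must be non-negative")
        if isinstance(self.bat, dict):
            self.bat = BatConfig(**self.bat)

    @classmethod
    def small(cls) -> "OptimizerConfig":
        """Search settings sized for few-gene benchmark time courses.

        With <= 10 genes, L around 2 and about 50 time points the candidate
        design matrices are tiny; a 20-tree population over 15 generations
        with short bat refinements converges in about a second per target
        while leaving the full-size defaults available for harder problems.
        """
        return cls(
            pop_size=20,
            max_generations=15,
            param_opt_every=3,
            param_opt_fraction=0.25,
            target_rmse=0.02,
            bat=BatConfig(n_bats=10, n_iters=20),
        )


_NORMALIZATIONS = ("minmax", "zscore", "none")
_ENCODINGS = ("real", "phase")


@dataclass
class RunConfig:
    """Global run parameters for one network-inference run.

    ``tau_max`` is the maximum time lag (in sampling intervals) scanned by
    the delayed association measures; ``L`` is the number of candidate
    regulators kept per target gene.
    """

    tau_max: int = 6
    L: int = 2
    min_lag: int = 0
    normalization: str = "minmax"
    encoding: str = "real"
    seed: int = 0
    n_runs: int = 1
    mi_bins: int | None = None
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self) -> None:
        if self.tau_max < 0 or self.min_lag < 0:
            raise ValueError("lags must be non-negative")
        if self.min_lag > self.tau_max:
            raise ValueError("min_lag must be <= tau_max")
        if self.L < 1:
            raise ValueError("L must be positive")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")
        if self.encoding not in _ENCODINGS:
            raise ValueError(f"encoding must be one of {_ENCODINGS}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if isinstance(self.optimizer, dict):
            self.optimizer = OptimizerConfig(**self.optimizer)


class ParseError(ValueError):
    """Malformed input file (carries row/column context in the message)."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path: str | Path) -> ExpressionDataset:
    """Read a TSV/CSV expression matrix.

    First column holds gene identifiers; the remaining column order is
    taken as the temporal order of the time points.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: could not parse expression table: {exc}") from exc
    if df.shape[1] < 1:
        raise ParseError(f"{path}: fewer than 2 columns (gene id + time points)")
    ids = [str(g) for g in df.index]
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            raise ParseError(f"{path}: duplicate gene id {g!r}")
        seen.add(g)
    for gene, row in df.iterrows():
        bad = row[pd.to_numeric(row, errors="coerce").isna()]
        if len(bad):
            col = bad.index[0]
            raise ParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at gene {gene!r}, "
                f"column {col!r}"
            )
    values = df.to_numpy(dtype=float)
    return ExpressionDataset(
        gene_ids=tuple(ids),
        values=values,
        time_labels=tuple(str(c) for c in df.columns),
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write an expression matrix as TSV (inverse of :func:`read_expression`)."""
    dataset.to_frame().to_csv(Path(path), sep="\t", index_label="gene")


def read_edge_list(path: str | Path) -> GoldNetwork:
    """Read a two-column directed edge list (optional third lag column ignored)."""
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("regulator"):
                continue  # header row of a network TSV
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'regulator<TAB>target', "
                    f"got {line!r}"
                )
            edges.add((parts[0], parts[1]))
    return GoldNetwork(edges=frozenset(edges))


def write_edge_list(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for reg, tgt in edges:
            fh.write(f"{reg}\t{tgt}\n")


def normalize(dataset: ExpressionDataset, mode: str = "minmax") -> ExpressionDataset:
    """Per-gene normalisation of an expression matrix.

    ``minmax`` maps each gene row onto [0, 1]; constant rows map to 0.5 by
    convention.  ``zscore`` standardises each row (constant rows map to 0).
    ``none`` returns the dataset unchanged.  The input is never mutated.
    """
    if mode not in _NORMALIZATIONS:
        raise ValueError(f"mode must be one of {_NORMALIZATIONS}")
    if mode == "none":
        return dataset
    values = dataset.values.copy()
    if mode == "minmax":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        const = span[:, 0] == 0
        span[const] = 1.0
        values = (values - lo) / span
        values[const] = 0.5
    else:  # zscore
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        const = sd[:, 0] == 0
        sd[const] = 1.0
        values = (values - mu) / sd
        values[const] = 0.0
    return ExpressionDataset(
        gene_ids=dataset.gene_ids, values=values, time_labels=dataset.time_labels
    )


def _config_to_dict(config: RunConfig) -> dict:
    def unpack(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return unpack(config)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def read_config(path: str | Path) -> RunConfig:
    """Read a flat YAML/key-value run configuration."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: configuration must be a key-value mapping")
    opt = raw.pop("optimizer", None)
    config = RunConfig(**raw)
    if opt is not None:
        bat = opt.pop("bat", None)
        if "function_arities" in opt:
            opt["function_arities"] = tuple(opt["function_arities"])
        config.optimizer = OptimizerConfig(**opt)
        if bat is not None:
            config.optimizer.bat = BatConfig(**bat)
    return config
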