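"""Core containers shared across the pipeline.

Values live in pandas DataFrames (genes in rows, samples in columns) with a
parallel sample-metadata table; networks are networkx graphs with ``weight``
and ``sign`` edge attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: recognised per-replicate quality codes for Ct entries
STATUS_OK = "ok"
STATUS_UNDETERMINED = "undetermined"
STATUS_FLAGGED = "flagged"
STATUS_CODES = (STATUS_OK, STATUS_UNDETERMINED, STATUS_FLAGGED)

SAMPLE_META_COLUMNS = ("stage", "batch", "condition", "replicate")


def _check_sample_meta(values: pd.DataFrame, samples: pd.DataFrame) -> None:
    if not values.columns.equals(samples.index):
        raise ValueError("sample metadata index must match value columns")
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")


@dataclass
class CtTable:
    """Raw quantification cycles (genes x sample-replicates) with quality flags.

    ``values`` holds Ct cycles (NaN where a reaction gave no signal);
    ``status`` is a parallel table of {ok, undetermined, flagged};
    ``samples`` carries stage / batch / condition / replicate per column.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.status.shape:
            raise ValueError("values and status must have identical shape")
        _check_sample_meta(self.values, self.samples)
        bad = set(np.unique(self.status.values.astype(str))) - set(STATUS_CODES)
        if bad:
            raise ValueError(f"unknown status codes: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def bad_fraction(self) -> pd.Series:
        """Per-gene fraction of undetermined-or-flagged replicates."""
        bad = self.status.isin([STATUS_UNDETERMINED, STATUS_FLAGGED])
        return bad.mean(axis=1)


@dataclass
class ExpressionMatrix:
    """Relative expression (genes x samples) plus sample metadata.

    ``scale`` records whether ``values`` are fold-ratios ("ratio", strictly
    positive) or already log2-transformed ("log2").
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "ratio"

    def __post_init__(self) -> None:
        if self.scale not in ("ratio", "log2"):
            raise ValueError(f"scale must be 'ratio' or 'log2', got {self.scale!r}")
        _check_sample_meta(self.values, self.samples)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2_values(self) -> pd.DataFrame:
        """Values on the log2 scale regardless of the stored scale."""
        if self.scale == "log2":
            return self.values.copy()
        return np.log2(self.values)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.samples.loc[values.columns].copy(),
                                scale if scale is not None else self.scale)

    def subset_samples(self, mask) -> "ExpressionMatrix":
        cols = self.values.columns[np.asarray(mask, dtype=bool)]
        return ExpressionMatrix(self.values[cols].copy(), self.samples.loc[cols].copy(), self.scale)


@dataclass
class StandardCurve:
    """Least-squares line of Ct against log10(dilution fraction)."""

    slope: float  # cycles per log10-dilution, negative for a valid curve
    intercept: float  # cycles at dilution 1
    r_squared: float
    dilution_points: list[tuple[float, float]]  # (dilution fraction, mean Ct)

    def quantify(self, cts) -> np.ndarray:
        """Relative quantity (same unit as dilution fractions) for Ct values."""
        cts = np.asarray(cts, dtype=float)
        return 10.0 ** ((cts - self.intercept) / self.slope)


@dataclass
class PartialCorrelationEnsemble:
    """Leave-one-gene-out first-order partial correlation matrices.

    One member per held-out gene; each member is a symmetric
    (n-1) x (n-1) DataFrame with unit diagonal over the remaining genes.
    """

    members: dict[str, pd.DataFrame]
    gene_ids: list[str]
    n_samples: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PrecisionEstimate:
    """One CLIME solution: sparse symmetric Omega-hat for a member matrix."""

    omega: pd.DataFrame
    lam: float
    feasibility_residual: float  # max_b ||sigma @ omega_col_b - e_b||_inf before symmetrisation
    held_out_gene: str | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.omega.index)


@dataclass
class ConsensusNetwork:
    """Consensus graph with per-edge occurrence frequency over an ensemble.

    Edge attributes: ``frequency`` (occurrences / eligible members), ``sign``
    (+1 or -1), ``weight`` (mean |Omega| over occurrences), ``occurrences``,
    ``eligible``.
    """

    graph: nx.Graph
    threshold: float = 0.95

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": min(u, v), "gene_b": max(u, v), **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        cols = ["gene_a", "gene_b", "weight", "sign", "frequency", "occurrences", "eligible"]
        table = pd.DataFrame(rows, columns=cols)
        return table.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


@dataclass
class SyntheticTruth:
    """Ground truth for simulation: per-stage graphs and precision matrices.

    ``stages`` is the ordered developmental axis; ``stage_graphs`` may hold
    additional perturbation conditions keyed by labels outside ``stages``.
    ``batch_params`` maps batch label -> (additive shift in log2 units,
    multiplicative scale on the log2 values).
    """

    stages: list[str]
    stage_graphs: dict[str, nx.Graph]
    precision_matrices: dict[str, np.ndarray]
    gene_ids: list[str]
    planned_losers: list[str]
    planned_gainers: list[str]
    batch_params: dict[str, tuple[float, float]]
    seed: int
    conditions: dict[str, str] = field(default_factory=dict)  # label -> condition tag

    @property
    def labels(self) -> list[str]:
        """All simulated labels: ordered stages first, then extra conditions."""
        extra = [k for k in self.stage_graphs if k not in self.stages]
        return list(self.stages) + extra

    def condition_of(self, label: str) -> str:
        return self.conditions.get(label, "control")


@dataclass
class ConnectivityDelta:
    """Signed degree change of one gene across ordered stage networks."""

    gene_id: str
    delta: int
    per_pair_deltas: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        if self.per_pair_deltas and self.delta != sum(self.per_pair_deltas.values()):
            raise ValueError("delta must equal the sum of per-pair deltas")


@dataclass
class PermutationResult:
    """Observed first-neighbour connectivity against a random-gene-set null."""

    query_gene: str
    observed: int
    null_values: np.ndarray
    p_raw: float
    p_adjusted: float
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if len(self.null_values) > 1 else 0.0


def gene_names(n: int, prefix: str = "G") -> list[str]:
    """Deterministic zero-padded gene identifiers G001, G002, ..."""
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def sample_meta(sample_ids, stage, batch, condition="control", replicate=None) -> pd.DataFrame:
    """Build a sample-metadata table; scalar arguments are broadcast."""
    idx = pd.Index(sample_ids, name="sample")
    n = len(idx)
    if replicate is None:
        replicate = list(range(1, n + 1))

    def _col(x):
        if isinstance(x, str) or np.isscalar(x):
            return [x] * n
        x = list(x)
        if len(x) != n:
            raise ValueError("metadata column length does not match sample count")
        return x

    return pd.DataFrame(
        {"stage": _col(stage), "batch": _col(batch),
         "condition": _col(condition), "replicate": _col(replicate)},
        index=idx,
    )
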