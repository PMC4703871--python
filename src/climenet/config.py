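"""Run configuration: every tunable of the pipeline in one document.

Defaults follow the analysis conventions the package implements: 20
regularisation values equi-spaced in [0.01, 1], 10th-percentile edge
filtering, 95% consensus frequency, tie-aware top-20 connectivity lists,
k = 10 imputation neighbours, MAD multiplier 3 and 1,000 permutation
replicates. Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    # simulation
    n_genes: int = 30
    stages: list[str] = field(default_factory=lambda: ["PND14", "PND21", "PND28"])
    n_rewire: int = 5
    graph_model: str = "scale-free"
    n_per_stage: int = 150
    noise_sd: float = 0.1
    with_perturbation: bool = True
    # Ct encoding
    ct_intercept: float = 20.0
    ct_slope: float = -1.0
    ct_detection_limit: float = 35.0
    flag_rate: float = 0.02
    # preprocessing
    max_bad_fraction: float = 0.5
    reference_gene: str | None = None  # default: last gene of the panel
    calibrator_stage: str | None = None  # default: earliest stage
    mad_multiplier: float = 3.0
    impute_k: int = 10
    batch_correction: bool = True
    # network inference
    lambda_points: int = 20
    lambda_min: float = 0.01
    lambda_max: float = 1.0
    edge_percentile: float = 10.0
    consensus_freq: float = 0.95
    score_order: str = "filter_then_score"
    log_binning: bool = False
    lp_backend: str = "simplex"
    # connectivity / permutation
    top_k: int = 20
    perm_reps: int = 1000
    # reproducibility
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config requires an explicit seed")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {self.schema_version}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        doc = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)
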