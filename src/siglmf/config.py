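"""Pipeline configuration: one YAML file, one root seed.

Defaults reproduce the published GDSC-tuned hyperparameter set: k = 20
nearest neighbors, alpha = 0.5 and beta = 0.1 graph strengths,
lambda_c = lambda_d = 0.5 variance controls, similarity weights
(lambda, gamma, phi, psi, rho) = (2, 2, 2, 5, 2) — the IC50 layer carries
the largest weight — classification threshold 0.4, r = 1 and L = 95
(L is clipped to min(n, m) at training time).  Unknown keys in a config
file are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .lmf import LmfHyperParams
from .screening import AutoencoderSpec


@dataclass
class SyntheticSettings:
    """Study conditions of the synthetic panel the `simulate` stage emits."""

    n_cell_lines: int = 150
    n_drugs: int = 20
    latent_dim: int = 5
    noise_sd: float = 0.3
    n_genes: int = 100
    n_signal_genes: int = 30
    n_cnv_features: int = 60
    n_cnv_signal: int = 15
    tissues: int = 4
    missing_frac: float = 0.1
    n_signatures: int = 3
    mean_run_len: float = 4.0
    close_frac: float = 0.5
    mean_mutations: float = 80.0


@dataclass
class PipelineConfig:
    seed: int = 0

    # imputation
    impute_k: int = 5
    impute_weighting: str = "as-printed"
    max_missing_frac: float = 0.5

    # autoencoder + Boruta screening
    hidden_units: int = 100
    ae_epochs: int = 500
    ae_learning_rate: float = 0.01
    keep_fraction: float = 0.5
    boruta_mode: str = "per-drug-union"
    boruta_max_iter: int = 40
    boruta_alpha: float = 0.05
    boruta_trees: int = 500

    # mutational signatures
    n_signatures: int = 3
    close_threshold_bp: int = 2000
    rho_threshold: float = 0.2
    rho_use_abs: bool = False
    normalized_activities: bool = False
    hmm_restarts: int = 3
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-4
    signature_profiles: str | None = None   # TSV path: 96 rows x t signatures

    # similarity / factorization (published defaults)
    k: int = 20
    alpha: float = 0.5
    beta: float = 0.1
    lambda_c: float = 0.5
    lambda_d: float = 0.5
    sim_weights: tuple = (2, 2, 2, 5, 2)
    threshold: float = 0.4
    r: float = 1.0
    L: int = 95
    n_iter: int = 1000
    learning_rate: float = 0.1
    ic50_log: bool = False
    cold_start_weighted: bool = True
    tree_max_depth: int = 6

    # cross-validation
    n_folds: int = 10
    n_repeats: int = 30

    # optional input paths (filled by the CLI)
    inputs: dict = field(default_factory=dict)
    synthetic: SyntheticSettings = field(default_factory=SyntheticSettings)

    def lmf_hyper(self) -> LmfHyperParams:
        return LmfHyperParams(
            L=self.L, r=self.r, lambda_c=self.lambda_c, lambda_d=self.lambda_d,
            alpha=self.alpha, beta=self.beta, k=self.k,
            sim_weights=tuple(self.sim_weights), threshold=self.threshold,
            n_iter=self.n_iter, learning_rate=self.learning_rate,
            seed=self.seed)

    def autoencoder_spec(self) -> AutoencoderSpec:
        return AutoencoderSpec(hidden_units=self.hidden_units,
                               epochs=self.ae_epochs,
                               learning_rate=self.ae_learning_rate,
                               seed=self.seed)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim_weights"] = list(self.sim_weights)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in data and isinstance(data["synthetic"], dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticSettings)}
            syn_unknown = set(data["synthetic"]) - syn_known
            if syn_unknown:
                raise ValueError(f"unknown synthetic config keys: {sorted(syn_unknown)}")
            data["synthetic"] = SyntheticSettings(**data["synthetic"])
        if "sim_weights" in data:
            data["sim_weights"] = tuple(data["sim_weights"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
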