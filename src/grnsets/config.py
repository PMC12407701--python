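"""Run configuration and deterministic seed derivation.

Every stochastic operation in the pipeline draws from a seed derived as a
stable hash of ``(master_seed, stage, unit_id)`` — no hidden global
randomness, and per-unit seeds are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from a master seed and a label path (< 2**31)."""
    key = json.dumps([int(master_seed), *[str(p) for p in parts]]).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration driving the end-to-end pipeline.

    Defaults follow the study conditions: 1,000 multi-start seeds per model,
    the six-point uneven sampling design with 4 wild-type / 2 knock-out
    replicates, experiment-wide max-scaling, the 1,000-lowest-cost
    acceptability rank for the wild-type family, depth-5 decision tree with
    5-fold cross-validation.  ``model_indices`` restricts the wild-type family
    to a subset for reduced-scale runs; ``genes``/``regulators`` select a
    smaller base family altogether.
    """

    master_seed: int = 1
    n_starts: int = 1000
    workers: int = 1

    # synthetic-data stage
    true_model: str = "unified"
    noise_cv: float = 0.2
    scaling_scope: str = "experiment_global"
    experiments: tuple[str, ...] = ("WT", "eud1_KO", "sult1_KO")

    # family selection
    genes: tuple[str, ...] = ("eud-1", "nhr-40", "sult-1")
    regulators: tuple[str, ...] = ("E", "N", "S")
    model_indices: Optional[list[int]] = None

    # acceptability thresholds
    acceptable_rank: int = 1000
    ko_threshold_mode: str = "largest_gap"

    # classifier
    classifier_max_depth: int = 5
    classifier_criterion: str = "gini"
    classifier_folds: int = 5
    upsample_minority: bool = False

    # numerics
    sigma_floor: float = 1e-6
    preset_protein_ic: float = 1e-3
    rtol: float = 1e-6
    atol: float = 1e-9
    maxiter: int = 1000
    maxfun: Optional[int] = None

    # sweep grid
    sweep_sampling_counts: tuple[int, ...] = (4, 6, 9, 13, 25, 73)
    sweep_cvs: tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.35, 0.5)

    def validate(self) -> "RunConfig":
        if self.master_seed < 0 or self.master_seed >= 2**31:
            raise ConfigError("master_seed must be in [0, 2**31)")
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")
        if self.workers < 1:
            raise ConfigError("workers must be >= 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.scaling_scope not in ("experiment_global", "per_gene"):
            raise ConfigError(f"unknown scaling scope {self.scaling_scope!r}")
        if self.ko_threshold_mode not in ("largest_gap", "rank_k"):
            raise ConfigError(f"unknown threshold mode {self.ko_threshold_mode!r}")
        if self.classifier_criterion not in ("gini", "entropy"):
            raise ConfigError(f"unknown tree criterion {self.classifier_criterion!r}")
        for name in ("sigma_floor", "preset_protein_ic", "rtol", "atol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        return self

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        for key, value in doc.items():
            if isinstance(value, tuple):
                doc[key] = list(value)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(doc) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in doc.items():
            if isinstance(value, list) and key != "model_indices":
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(doc)
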