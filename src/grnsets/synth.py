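"""Synthetic expression datasets with the study's statistical structure.

The experimental design being emulated: bulk RNA-seq for the three network
genes at six developmental time points (0, 12, 24, 48, 60, 72 h after
synchronization), four biological replicates in the wild type and two in each
knock-out, values max-scaled to [0, 1] per experiment.  Observation noise is
multiplicative — a mean-centred Gaussian whose standard deviation is
proportional to the signal, ``y = x * (1 + cv * Z)`` — which matches the
signal-dependent scatter seen in such data.  Noise is applied to the true
model trajectory, draws below a small positive floor are truncated (not
resampled), and everything is reproducible from an integer seed.

This module does not simulate read counts; it models post-normalisation
expression values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import ParameterSet, compile_model, simulate_mrna, simulate, IntegrationFailure
from .terms import RegulatoryModel

#: the uneven experimental sampling grid (hours post-synchronization)
DESIGN_TIMES = (0.0, 12.0, 24.0, 48.0, 60.0, 72.0)
EXPERIMENTS = ("WT", "eud1_KO", "sult1_KO")
KNOCKOUT_OF_EXPERIMENT = {"eud1_KO": "eud-1", "sult1_KO": "sult-1"}

#: truncation floor for noisy draws (values, not counts, so merely "tiny")
VALUE_FLOOR = 1e-6

DATA_COLUMNS = ("experiment", "gene", "time_h", "replicate", "value")


class SyntheticDataError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative-noise specification: sd(y) = cv * x."""

    cv: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise SyntheticDataError("cv must be non-negative")


@dataclass
class ExpressionDataset:
    """Long-format expression observations for one experiment.

    ``table`` has columns (experiment, gene, time_h, replicate, value);
    ``scaling`` records the max-scaling applied, if any.
    """

    experiment: str
    table: pd.DataFrame
    scaling: Optional[dict] = None

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["gene"]))

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.table["time_h"].unique())


def default_true_params(seed_scale: float = 1.0) -> ParameterSet:
    """Ground-truth kinetic parameters for synthetic studies.

    Chosen so the mRNA trajectories are positive, dynamic over the 72 h
    window, and of order 0.1-1 in scaled expression units (the regime the
    max-scaled data occupy), with the hidden proteins traversing their Hill
    half-max constants so every regulatory edge is actually exercised.
    """
    return ParameterSet(
        alpha={"eud-1": 0.02, "nhr-40": 0.02, "sult-1": 0.02},
        k_tx={"eud-1": 0.45 * seed_scale, "nhr-40": 0.6 * seed_scale, "sult-1": 0.5 * seed_scale},
        k_m=0.2,
        k_p=0.08,
        K={1: 6.0, 2: 2.5, 3: 9.0, 4: 8.0, 5: 5.0, 6: 7.0},
        m0={"eud-1": 0.05, "nhr-40": 0.3, "sult-1": 0.05},
        p0={"E": 1e-3, "N": 2.0, "S": 1e-3},
    )


def generate_dataset(
    model: RegulatoryModel,
    params: ParameterSet,
    times,
    replicates: int,
    noise: NoiseSpec,
    experiment: str = "synthetic",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ExpressionDataset:
    """Sample a noisy dataset from a model trajectory.

    Each observation is ``y = x * (1 + cv * Z)`` with independent standard
    normal ``Z`` per (gene, time, replicate); draws below ``VALUE_FLOOR`` are
    truncated to the floor.  Deterministic given ``noise.seed``.
    """
    if replicates < 1:
        raise SyntheticDataError("replicates must be >= 1")
    traj = simulate(model, params, times, rtol=rtol, atol=atol)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for g, gene in enumerate(traj.genes):
        x = traj.mrna[g]
        draws = x[:, None] * (1.0 + noise.cv * rng.standard_normal((x.size, replicates)))
        draws = np.maximum(draws, VALUE_FLOOR)
        for j, t in enumerate(traj.times):
            for r in range(replicates):
                rows.append((experiment, gene, float(t), r + 1, draws[j, r]))
    table = pd.DataFrame(rows, columns=DATA_COLUMNS)
    return ExpressionDataset(experiment=experiment, table=table)


def max_scale(dataset: ExpressionDataset, scope: str = "experiment_global") -> ExpressionDataset:
    """Scale values by the maximum across time points and replicates.

    ``experiment_global`` (the default, matching one maximum per experiment)
    divides every value by the single experiment-wide maximum; ``per_gene``
    rescales each gene by its own maximum.  Idempotent in either scope.
    """
    if scope not in ("experiment_global", "per_gene"):
        raise SyntheticDataError(f"unknown scaling scope {scope!r}")
    table = dataset.table.copy()
    if not (table["value"] > 0).any():
        raise SyntheticDataError("cannot max-scale an all-zero dataset")
    if scope == "experiment_global":
        maximum = float(table["value"].max())
        table["value"] = table["value"] / maximum
        meta = {"scope": scope, "max": maximum}
    else:
        maxima = table.groupby("gene")["value"].transform("max")
        meta = {
            "scope": scope,
            "max": table.groupby("gene")["value"].max().to_dict(),
        }
        table["value"] = table["value"] / maxima
    return ExpressionDataset(experiment=dataset.experiment, table=table, scaling=meta)


def experimental_design(experiment: str) -> tuple[tuple[float, ...], int]:
    """Sampling times and replicate count for each experimental condition."""
    if experiment == "WT":
        return DESIGN_TIMES, 4
    if experiment in KNOCKOUT_OF_EXPERIMENT:
        return DESIGN_TIMES, 2
    raise SyntheticDataError(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")


@dataclass(frozen=True)
class SweepCell:
    """One (sampling count, noise level) cell of a misspecification sweep."""

    sampling_count: int
    cv: float
    times: tuple[float, ...]
    experimental_regime: bool = False


def sweep_grid(
    sampling_counts,
    cvs,
    experimental_count: int = 6,
    experimental_cv: float = 0.2,
) -> list[SweepCell]:
    """Cartesian sampling-rate x noise-level grid over the 72 h window.

    Each sampling count maps to equally spaced times over [0, 72] h, except
    the single flagged "approximate experimental regime" cell (the
    experimental count at the experimental cv), which uses the uneven design
    times instead.
    """
    cells = []
    for count, cv in product(sampling_counts, cvs):
        if count < 2:
            raise SyntheticDataError("sampling counts must be >= 2")
        if cv < 0:
            raise SyntheticDataError("cv must be non-negative")
        flagged = count == experimental_count and cv == experimental_cv
        times = DESIGN_TIMES if flagged else tuple(np.linspace(0.0, 72.0, count))
        cells.append(SweepCell(sampling_count=count, cv=cv, times=times, experimental_regime=flagged))
    return cells
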