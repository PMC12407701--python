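"""Misspecification sweeps, cost-curve ranking and prediction uncertainty.

Three analyses built on the family fits:

* a sampling-rate x noise-level sweep in which synthetic data are generated
  from a known "true" structure in every grid cell and the true plus several
  misspecified candidate structures are refit, mapping where structures stop
  being practically distinguishable;
* the cost curve: structures of a family sorted by their best negative
  log-likelihood, with an acceptability threshold drawn either at a fixed
  rank or at the largest consecutive jump of the curve;
* the one-standard-deviation prediction band ``x_i * (1 +/- sigma_hat)``
  implied by the multiplicative error model, whose width tracks fit quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import derive_seed
from .fitting import Bounds, FitOptions, FitResult, PENALTY, fit_model
from .synth import NoiseSpec, SweepCell, generate_dataset
from .terms import RegulatoryModel


class SweepError(ValueError):
    pass


@dataclass
class SweepResult:
    """Long-format sweep table: one row per (cell, candidate [, repetition])."""

    table: pd.DataFrame

    def cell(self, sampling_count: int, cv: float) -> pd.DataFrame:
        t = self.table
        return t[(t["sampling_count"] == sampling_count) & (t["cv"] == cv)]


def misspecification_sweep(
    true_model: RegulatoryModel,
    true_params,
    candidates: dict[str, RegulatoryModel],
    cells: list[SweepCell],
    n_starts: int = 50,
    seed: int = 0,
    replicates: int = 4,
    repetitions: int = 1,
    bounds: Bounds = Bounds(),
    options: Optional[FitOptions] = None,
) -> SweepResult:
    """Fit every candidate structure to seeded synthetic data in every cell.

    One dataset per cell by default (each heat-map value is a single draw);
    ``repetitions`` adds independently seeded datasets per cell for
    stochastic statements.  Cell-level failures are flagged and the sweep
    continues.  Deterministic given ``seed``.
    """
    if not any(c.structure_equal(true_model) for c in candidates.values()):
        raise SweepError("candidates must include the true structure")
    rows = []
    for cell in cells:
        for rep in range(repetitions):
            data_seed = derive_seed(seed, "sweep-data", cell.sampling_count, cell.cv, rep)
            try:
                dataset = generate_dataset(
                    true_model,
                    true_params,
                    np.asarray(cell.times),
                    replicates,
                    NoiseSpec(cv=cell.cv, seed=data_seed),
                )
            except Exception as exc:  # cell-level failure: flag and continue
                for name in candidates:
                    rows.append(
                        dict(
                            sampling_count=cell.sampling_count,
                            cv=cell.cv,
                            repetition=rep,
                            candidate=name,
                            nll=np.nan,
                            failed=True,
                            experimental_regime=cell.experimental_regime,
                            error=str(exc),
                        )
                    )
                continue
            for name, model in candidates.items():
                fit_seed = derive_seed(seed, "sweep-fit", cell.sampling_count, cell.cv, rep, name)
                result = fit_model(
                    model, dataset, n_starts=n_starts, bounds=bounds, seed=fit_seed, options=options
                )
                rows.append(
                    dict(
                        sampling_count=cell.sampling_count,
                        cv=cell.cv,
                        repetition=rep,
                        candidate=name,
                        nll=result.nll,
                        failed=result.failed,
                        experimental_regime=cell.experimental_regime,
                        error="",
                    )
                )
    return SweepResult(table=pd.DataFrame(rows))


def structure_recovery(
    true_model: RegulatoryModel,
    true_params,
    candidates: dict[str, RegulatoryModel],
    times,
    cv: float,
    n_repetitions: int,
    n_starts: int,
    seed: int = 0,
    replicates: int = 4,
    options: Optional[FitOptions] = None,
) -> pd.DataFrame:
    """Repeated single-cell sweep: refit all candidates to fresh datasets.

    Returns a table (repetition, candidate, nll) used to ask how often the
    generating structure attains the lowest cost among the candidates.
    """
    cell = SweepCell(sampling_count=len(tuple(times)), cv=cv, times=tuple(times))
    result = misspecification_sweep(
        true_model,
        true_params,
        candidates,
        [cell],
        n_starts=n_starts,
        seed=seed,
        replicates=replicates,
        repetitions=n_repetitions,
        options=options,
    )
    return result.table[["repetition", "candidate", "nll", "failed"]]


@dataclass
class CostCurve:
    """Structures sorted by best nll, with optional acceptability labels."""

    table: pd.DataFrame  # columns: rank, model_index, nll [, acceptable]

    @property
    def nll(self) -> np.ndarray:
        return self.table["nll"].to_numpy()


def cost_curve(fit_table: pd.DataFrame) -> CostCurve:
    """Stable sort of a family fit table by nll (ties broken by model index)."""
    if len(fit_table) == 0:
        raise SweepError("empty fit table")
    ordered = fit_table.sort_values(["nll", "model_index"], kind="stable").reset_index(drop=True)
    curve = ordered[["model_index", "nll"]].copy()
    curve.insert(0, "rank", np.arange(len(curve)))
    return CostCurve(table=curve)


def select_acceptance_threshold(curve: CostCurve, mode: str = "rank_k", k: int = 1000) -> CostCurve:
    """Label the acceptable structures on a cost curve.

    ``rank_k`` marks the ``k`` lowest-cost structures acceptable (the
    wild-type convention); ``largest_gap`` splits at the maximal consecutive
    nll jump (the knock-out curves show one discrete jump).
    """
    table = curve.table.copy()
    n = len(table)
    if mode == "rank_k":
        if not 0 < k < n:
            raise SweepError(f"rank_k requires 0 < k < {n}")
        table["acceptable"] = table["rank"] < k
    elif mode == "largest_gap":
        diffs = np.diff(table["nll"].to_numpy())
        if diffs.size == 0 or np.max(diffs) <= 0:
            raise SweepError("no gap in a constant cost curve")
        cut = int(np.argmax(diffs))
        table["acceptable"] = table["rank"] <= cut
    else:
        raise SweepError(f"unknown threshold mode {mode!r}")
    return CostCurve(table=table)


def uncertainty_band(fit: FitResult) -> pd.DataFrame:
    """One-standard-deviation prediction band, ``x_i * (1 +/- sigma_hat)``.

    The lower edge is floored at 0 for display; band width is
    ``2 * sigma_hat * x_i``, so poorer fits (larger profiled noise) produce
    wider bands.
    """
    if fit.failed or fit.predictions is None:
        raise SweepError("cannot build a band for a failed fit")
    band = fit.predictions.copy()
    x = band["prediction"].to_numpy()
    band["lower"] = np.maximum(0.0, x * (1.0 - fit.sigma_hat))
    band["upper"] = x * (1.0 + fit.sigma_hat)
    return band
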