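"""Multiplicative-error maximum-likelihood fitting of network structures.

For observations ``y_i`` with model predictions ``x_i(theta)`` under the
multiplicative error model ``y = x (1 + sigma Z)``, the negative
log-likelihood is

    -l(theta, sigma | y) = n log sigma + sum_i log x_i(theta)
                           + 1/(2 sigma^2) * sum_i ((y_i - x_i) / x_i)^2.

The noise scale is a nuisance parameter with an exact analytic profile,
``sigma_hat^2 = (1/n) sum_i ((y_i - x_i)/x_i)^2`` (floored), so each structure
is fit by minimising the sigma-profiled objective over the kinetic parameters
only.  Optimisation is multi-start bounded L-BFGS-B: Latin-hypercube starting
points mapped log-uniformly over wide per-group ranges, optimised in log10
coordinates (the bounds span 9-17 decades, so log coordinates are the only
sanely conditioned choice).  Trajectory failures and non-positive predictions
return a large finite penalty rather than raising, which keeps doomed starts
cheap; a fit whose best value is the penalty is flagged failed.

Free parameters per structure: basal and maximal transcription rates, shared
degradation rates and mRNA initial conditions (unscaled group); the half-max
constants its term actually uses, and the scaled NHR-40 protein initial
condition when N appears in at least one production term (scaled group).  The
EUD-1 and SULT-1 protein initial conditions are fixed to a low preset value,
reflecting that those genes' expression stays low in all experiments and
those initial conditions are not identifiable in structures that never read
them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .config import derive_seed
from .dynamics import (
    CompiledModel,
    ParameterSet,
    compile_model,
    integrate_mrna,
    simulate_mrna,
)
from .synth import ExpressionDataset
from .terms import GENE_POSITION, ModelFamily, RegulatoryModel, model_from_index

PENALTY = 1e10
SIGMA_FLOOR = 1e-6
PRESET_PROTEIN_IC = 1e-3

UNSCALED = "unscaled"
SCALED = "scaled"


class FittingError(ValueError):
    pass


@dataclass(frozen=True)
class Bounds:
    """Optimizer box bounds and Latin-hypercube start ranges, per group.

    Unscaled kinetic parameters (rates, mRNA initial conditions) are bounded
    in [1e-5, 1e4 + 1]; parameters carrying the translation-rate scaling
    (half-max constants, scaled protein initial condition) in [1e-9, 1e8 + 1].
    Starting points are drawn log-uniformly from strictly interior ranges.
    """

    unscaled_lower: float = 1e-5
    unscaled_upper: float = 1e4 + 1
    scaled_lower: float = 1e-9
    scaled_upper: float = 1e8 + 1
    unscaled_lhs: tuple[float, float] = (1e-4, 1e4)
    scaled_lhs: tuple[float, float] = (1e-8, 1e8)

    def __post_init__(self) -> None:
        for lower, lhs, upper in (
            (self.unscaled_lower, self.unscaled_lhs, self.unscaled_upper),
            (self.scaled_lower, self.scaled_lhs, self.scaled_upper),
        ):
            if not lower < lhs[0] < lhs[1] < upper:
                raise FittingError("require lower < LHS-low < LHS-high < upper per group")

    def box(self, group: str) -> tuple[float, float]:
        if group == UNSCALED:
            return self.unscaled_lower, self.unscaled_upper
        return self.scaled_lower, self.scaled_upper

    def lhs_range(self, group: str) -> tuple[float, float]:
        return self.unscaled_lhs if group == UNSCALED else self.scaled_lhs


@dataclass
class FitOptions:
    """Numerical knobs for the optimisation loop."""

    maxiter: int = 1000
    maxfun: Optional[int] = None
    gtol: float = 1e-8
    rtol: float = 1e-6
    atol: float = 1e-9
    mxstep: int = 3000
    sigma_floor: float = SIGMA_FLOOR
    preset_protein_ic: float = PRESET_PROTEIN_IC
    profile_sigma: bool = True
    #: screen-and-polish multi-start: when set, every start first runs with
    #: this evaluation cap, then the ``polish_top`` best finishing points are
    #: optimised to full precision (warm restarts).  ``None`` runs every
    #: start to completion.  Deep optima are often invisible after a cheap
    #: screen, so the polish pool should stay generous (default 12).
    race_budget: Optional[int] = None
    polish_top: int = 12


@dataclass
class FitResult:
    """Best fit of one structure to one dataset."""

    model_index: Optional[int]
    model: RegulatoryModel
    theta: dict[str, float]
    params: Optional[ParameterSet]
    sigma_hat: float
    nll: float
    predictions: Optional[pd.DataFrame]
    start_nlls: np.ndarray
    n_failed_starts: int
    converged: bool
    failed: bool
    seed: int


def negative_log_likelihood(x, y, sigma: float) -> float:
    """Exact multiplicative-error negative log-likelihood.

    Returns the penalty value (1e10) for any non-positive or non-finite
    prediction, signalling an infeasible trajectory.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FittingError("x and y must have the same shape")
    if sigma <= 0:
        raise FittingError("sigma must be positive")
    if x.size == 0:
        raise FittingError("need at least one observation")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        return PENALTY
    n = x.size
    rel = (y - x) / x
    return float(n * np.log(sigma) + np.sum(np.log(x)) + 0.5 / sigma**2 * np.sum(rel**2))


def profile_sigma(x, y, sigma_floor: float = SIGMA_FLOOR) -> float:
    """Analytic profile of the noise scale: sigma_hat^2 = mean squared relative residual."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise FittingError("need at least one observation")
    rel = (y - x) / x
    return max(sigma_floor, float(np.sqrt(np.mean(rel**2))))


def lhs_starts(n_starts: int, groups, bounds: Bounds, seed: int, scramble: bool = True) -> np.ndarray:
    """Latin-hypercube starting points, log-uniform per dimension.

    ``groups`` assigns each dimension to the unscaled or scaled range; every
    dimension has exactly one sample per stratum of the unit interval.  With
    ``scramble=False`` samples sit at stratum midpoints (deterministic grid).
    """
    if n_starts < 1:
        raise FittingError("n_starts must be >= 1")
    groups = list(groups)
    sampler = qmc.LatinHypercube(d=len(groups), seed=seed, scramble=scramble)
    unit = sampler.random(n_starts)
    out = np.empty_like(unit)
    for j, group in enumerate(groups):
        lo, hi = bounds.lhs_range(group)
        out[:, j] = 10.0 ** (np.log10(lo) + unit[:, j] * (np.log10(hi) - np.log10(lo)))
    return out


def free_parameters(model: RegulatoryModel) -> list[tuple[str, str]]:
    """Ordered (name, group) pairs of the free parameter vector for a structure."""
    names: list[tuple[str, str]] = []
    for gene in model.genes:
        names.append((f"alpha_{gene}", UNSCALED))
        names.append((f"ktx_{gene}", UNSCALED))
    names.append(("k_m", UNSCALED))
    names.append(("k_p", UNSCALED))
    for gene in model.genes:
        names.append((f"m0_{gene}", UNSCALED))
    for gene in model.genes:
        term = model.terms[gene]
        if term is None:
            continue
        pos = GENE_POSITION[gene]
        names.append((f"K_{pos}", SCALED))
        if len(term.factors) == 2:
            names.append((f"K_{pos + 3}", SCALED))
    uses_n = any(
        term is not None and "N" in term.regulators for term in model.terms.values()
    )
    if uses_n and "N" in model.proteins:
        names.append(("p0_N", SCALED))
    return names


def params_from_theta(
    model: RegulatoryModel,
    theta: dict[str, float],
    preset_protein_ic: float = PRESET_PROTEIN_IC,
) -> ParameterSet:
    """Assemble a full :class:`ParameterSet` from the free-parameter vector."""
    K = {int(name.split("_")[1]): value for name, value in theta.items() if name.startswith("K_")}
    p0 = {protein: preset_protein_ic for protein in model.proteins}
    if "p0_N" in theta:
        p0["N"] = theta["p0_N"]
    return ParameterSet(
        alpha={g: theta[f"alpha_{g}"] for g in model.genes},
        k_tx={g: theta[f"ktx_{g}"] for g in model.genes},
        k_m=theta["k_m"],
        k_p=theta["k_p"],
        K=K,
        m0={g: theta[f"m0_{g}"] for g in model.genes},
        p0=p0,
    )


def _prepare_observations(model: RegulatoryModel, dataset: ExpressionDataset):
    table = dataset.table
    genes = model.genes
    missing = set(genes) - set(table["gene"])
    if missing:
        raise FittingError(f"dataset lacks observations for {sorted(missing)}")
    table = table[table["gene"].isin(genes)].reset_index(drop=True)
    utimes = np.sort(table["time_h"].unique())
    time_idx = {t: i for i, t in enumerate(utimes)}
    gene_idx = {g: i for i, g in enumerate(genes)}
    gi = table["gene"].map(gene_idx).to_numpy()
    ti = table["time_h"].map(time_idx).to_numpy()
    y = table["value"].to_numpy(dtype=float)
    if np.any(y < 0):
        raise FittingError("negative observation values")
    return table, utimes.astype(float), gi, ti, y


class _SlotObjective:
    """Sigma-profiled negative log-likelihood as a function of log10 parameters.

    The model structure is packed once; each evaluation writes the free
    parameter values straight into copies of the packed arrays (no dict or
    dataclass construction on the hot path) and integrates with the
    low-overhead LSODA entry point.
    """

    def __init__(self, model, names, utimes, gi, ti, y, opts: FitOptions):
        template = params_from_theta(
            model, {name: 1.0 for name in names}, opts.preset_protein_ic
        )
        base = compile_model(model, template)
        self.base = base
        self.n_genes = len(base.genes)
        self.utimes = utimes
        self.gi = gi
        self.ti = ti
        self.y = y
        self.opts = opts
        n = self.n_genes
        gene_pos = {g: i for i, g in enumerate(model.genes)}
        protein_pos = {p: i for i, p in enumerate(base.proteins)}
        first_k = {}   # half-max index -> gene slot for first factors
        second_k = {}  # half-max index -> gene slot for second factors
        for gene in model.genes:
            term = model.terms[gene]
            if term is None:
                continue
            pos = GENE_POSITION[gene]
            first_k[pos] = gene_pos[gene]
            if len(term.factors) == 2:
                second_k[pos + 3] = gene_pos[gene]
        self.slots: list[tuple[str, int]] = []
        for name in names:
            if name.startswith("alpha_"):
                self.slots.append(("alphas", gene_pos[name[6:]]))
            elif name.startswith("ktx_"):
                self.slots.append(("ktx", gene_pos[name[4:]]))
            elif name == "k_m":
                self.slots.append(("km", 0))
            elif name == "k_p":
                self.slots.append(("kp", 0))
            elif name.startswith("m0_"):
                self.slots.append(("y0", gene_pos[name[3:]]))
            elif name.startswith("K_"):
                index = int(name[2:])
                if index in first_k:
                    self.slots.append(("kmain", first_k[index]))
                else:
                    self.slots.append(("ksec", second_k[index]))
            elif name == "p0_N":
                self.slots.append(("y0", n + protein_pos["N"]))
            else:  # pragma: no cover - free_parameters and this list move together
                raise FittingError(f"unmapped free parameter {name!r}")

    def __call__(self, log10_vec: np.ndarray) -> float:
        values = 10.0**log10_vec
        base = self.base
        alphas = base.alphas.copy()
        ktx = base.ktx.copy()
        kmain = base.kmain.copy()
        ksec = base.ksec.copy()
        y0 = base.y0.copy()
        km = base.km
        kp = base.kp
        for value, (kind, position) in zip(values, self.slots):
            if kind == "alphas":
                alphas[position] = value
            elif kind == "ktx":
                ktx[position] = value
            elif kind == "km":
                km = value
            elif kind == "kp":
                kp = value
            elif kind == "y0":
                y0[position] = value
            elif kind == "kmain":
                kmain[position] = value
            else:
                ksec[position] = value
        args = (alphas, ktx, km, kp, kmain, ksec, base.codes, base.ktrans)
        opts = self.opts
        mrna = integrate_mrna(
            y0, args, self.n_genes, self.utimes,
            rtol=opts.rtol, atol=opts.atol, mxstep=opts.mxstep,
        )
        if mrna is None:
            return PENALTY
        x = mrna[self.gi, self.ti]
        if np.any(x <= 0):
            return PENALTY
        sigma = profile_sigma(x, self.y, opts.sigma_floor)
        return negative_log_likelihood(x, self.y, sigma)


def fit_model(
    model: RegulatoryModel,
    dataset: ExpressionDataset,
    n_starts: int = 1000,
    bounds: Bounds = Bounds(),
    seed: int = 0,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of one structure.

    Runs L-BFGS-B (in log10 parameter coordinates) from ``n_starts``
    Latin-hypercube starting points and returns the best finishing point with
    the profiled noise scale and per-observation predictions.  Per-start
    results are retained so nested-subset monotonicity can be checked.
    """
    opts = options or FitOptions()
    spec = free_parameters(model)
    names = [name for name, _ in spec]
    groups = [group for _, group in spec]
    table, utimes, gi, ti, y = _prepare_observations(model, dataset)

    objective = _SlotObjective(model, names, utimes, gi, ti, y, opts)

    starts = lhs_starts(n_starts, groups, bounds, seed=derive_seed(seed, "lhs"))
    log_bounds = [tuple(np.log10(bounds.box(group))) for group in groups]
    minimize_options = {"maxiter": opts.maxiter, "gtol": opts.gtol}
    if opts.maxfun is not None:
        minimize_options["maxfun"] = opts.maxfun

    start_nlls = np.full(n_starts, PENALTY)
    finishing = np.log10(starts)

    def optimize(s: int, local_options: dict) -> None:
        res = minimize(
            objective, finishing[s], method="L-BFGS-B", bounds=log_bounds,
            options=local_options,
        )
        if res.fun <= start_nlls[s]:
            start_nlls[s] = res.fun
            finishing[s] = res.x

    if opts.race_budget is None:
        for s in range(n_starts):
            optimize(s, minimize_options)
    else:
        screen_options = dict(minimize_options)
        screen_options["maxfun"] = int(opts.race_budget)
        for s in range(n_starts):
            optimize(s, screen_options)
        order = sorted(range(n_starts), key=lambda s: (start_nlls[s], s))
        for s in order[: max(1, opts.polish_top)]:
            if start_nlls[s] < PENALTY:
                optimize(s, minimize_options)

    best_start = int(np.argmin(start_nlls))
    best_nll = float(start_nlls[best_start])
    best_vec = finishing[best_start] if best_nll < PENALTY else None
    best_success = best_vec is not None

    failed = best_vec is None or best_nll >= PENALTY
    n_failed = int(np.sum(start_nlls >= PENALTY))
    if failed:
        return FitResult(
            model_index=model.model_index,
            model=model,
            theta={},
            params=None,
            sigma_hat=float("nan"),
            nll=PENALTY,
            predictions=None,
            start_nlls=start_nlls,
            n_failed_starts=n_failed,
            converged=False,
            failed=True,
            seed=seed,
        )

    values = 10.0**best_vec
    theta = {name: float(value) for name, value in zip(names, values)}
    params = params_from_theta(model, theta, opts.preset_protein_ic)
    compiled = compile_model(model, params)
    mrna = simulate_mrna(compiled, utimes, rtol=opts.rtol, atol=opts.atol, mxstep=opts.mxstep)
    x = mrna[gi, ti]
    sigma = profile_sigma(x, y, opts.sigma_floor)
    predictions = table.copy()
    predictions["prediction"] = x
    return FitResult(
        model_index=model.model_index,
        model=model,
        theta=theta,
        params=params,
        sigma_hat=sigma,
        nll=float(best_nll),
        predictions=predictions,
        start_nlls=start_nlls,
        n_failed_starts=n_failed,
        converged=best_success,
        failed=False,
        seed=seed,
    )


def _fit_one_for_family(
    family: ModelFamily,
    index: int,
    dataset: ExpressionDataset,
    n_starts: int,
    bounds: Bounds,
    master_seed: int,
    options: Optional[FitOptions],
) -> dict:
    model = model_from_index(family, index)
    result = fit_model(
        model,
        dataset,
        n_starts=n_starts,
        bounds=bounds,
        seed=derive_seed(master_seed, "fit", index),
        options=options,
    )
    record = {
        "model_index": index,
        "nll": result.nll,
        "sigma_hat": result.sigma_hat,
        "converged": result.converged,
        "failed": result.failed,
        "n_failed_starts": result.n_failed_starts,
        "seed": result.seed,
    }
    record.update(result.theta)
    return record


def fit_family(
    family: ModelFamily,
    dataset: ExpressionDataset,
    n_starts: int = 1000,
    seed: int = 0,
    workers: int = 1,
    bounds: Bounds = Bounds(),
    options: Optional[FitOptions] = None,
    model_indices=None,
    checkpoint_dir=None,
) -> pd.DataFrame:
    """Fit every structure of a family (or an index subset) to one dataset.

    Per-model seeds are derived from the master seed and the model index, so
    results are reproducible and independent of execution order; partial
    failures are recorded, not fatal.  With ``checkpoint_dir``, finished
    models are stored as JSON records and skipped on re-runs.  Returns a table
    sorted by nll (ties broken by model index).
    """
    indices = list(range(family.size)) if model_indices is None else list(model_indices)
    for index in indices:
        if not 0 <= index < family.size:
            raise FittingError(f"model index {index} out of range for family of {family.size}")
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)

    records: list[dict] = []
    todo = []
    for index in indices:
        if ckpt is not None:
            path = ckpt / f"model_{index}.json"
            if path.exists():
                records.append(json.loads(path.read_text()))
                continue
        todo.append(index)

    def run(index: int) -> dict:
        return _fit_one_for_family(family, index, dataset, n_starts, bounds, seed, options)

    if workers > 1 and len(todo) > 1:
        from joblib import Parallel, delayed

        fresh = Parallel(n_jobs=workers)(delayed(run)(index) for index in todo)
    else:
        fresh = [run(index) for index in todo]
    for record in fresh:
        if ckpt is not None:
            (ckpt / f"model_{record['model_index']}.json").write_text(json.dumps(record))
        records.append(record)

    table = pd.DataFrame(records)
    return table.sort_values(["nll", "model_index"], kind="stable").reset_index(drop=True)
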