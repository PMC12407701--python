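"""Deterministic dynamics of the transcription/translation network models.

Each modelled gene g contributes two states: its mRNA ``M_g`` (observed) and
its protein ``P_g`` (hidden).  In the symmetry-reduced coordinates used for
fitting,

    dM_g/dt = alpha_g + k_tx_g * F_g(P; K) - k_m * M_g
    dP_g/dt = M_g - k_p * P_g

where ``F_g`` is the gene's Hill-type production term (a product of one or two
factors in {0,1}, optionally squared), ``k_m``/``k_p`` are shared mRNA/protein
degradation rates, and the proteins and half-max constants carry the
translation rate implicitly.  The unreduced model keeps an explicit
translation rate ``k_t`` (``dP_g/dt = k_t * M_g - k_p * P_g``) and is invariant
under the scaling symmetry (P, K, k_t) -> (xi*P, xi*K, xi*k_t) for any
xi > 0 — the mRNA observables do not change.  Setting xi = 1/k_t removes the
symmetry and yields the reduced coordinates.

The public integrator is :func:`simulate` (adaptive LSODA via
``scipy.integrate.solve_ivp``).  :func:`simulate_mrna` is the low-overhead
path used inside optimisation loops: the same LSODA algorithm driven through
``scipy.integrate.odeint`` with a step cap, returning mRNA trajectories or
``None`` on failure instead of raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import ODEintWarning, odeint, solve_ivp

from .terms import (
    ACTIVATION,
    GENE_POSITION,
    ProductionTerm,
    RegulatoryModel,
)

#: default integration tolerances for trajectory reporting
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
#: negative excursions beyond this are flagged as integration failures,
#: not clipped, so that pathological parameters surface during fitting
NEGATIVITY_TOL = -1e-9

warnings.filterwarnings("ignore", category=ODEintWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning, module="scipy.integrate")


class DynamicsError(ValueError):
    """Invalid model/parameter combination."""


class IntegrationFailure(RuntimeError):
    """The ODE solver failed or produced non-finite/negative states."""


@dataclass
class ParameterSet:
    """Kinetic parameters and initial conditions for one structure.

    ``alpha``/``k_tx``/``m0`` are keyed by gene name, ``p0`` by protein letter
    and ``K`` by half-max index 1..6 (gene at wild-type position i uses K_i for
    its first Hill factor and K_{i+3} for the second factor of a pair).  When
    ``translation_rate`` is ``None`` the parameters are in the symmetry-reduced
    coordinates; otherwise the model is unreduced with explicit k_t.
    """

    alpha: dict[str, float]
    k_tx: dict[str, float]
    k_m: float
    k_p: float
    K: dict[int, float]
    m0: dict[str, float]
    p0: dict[str, float]
    translation_rate: Optional[float] = None

    def validate(self) -> None:
        values = (
            list(self.alpha.values())
            + list(self.k_tx.values())
            + [self.k_m, self.k_p]
            + list(self.K.values())
            + list(self.m0.values())
            + list(self.p0.values())
        )
        if self.translation_rate is not None:
            values.append(self.translation_rate)
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise DynamicsError("all parameters must be finite and strictly positive")
        if any(k not in range(1, 7) for k in self.K):
            raise DynamicsError("half-max indices must lie in 1..6")


def production_value(
    term: Optional[ProductionTerm],
    protein_levels,
    halfmax: tuple[float, Optional[float]],
) -> float:
    """Evaluate one production term at the given protein levels.

    Each Hill factor lies in [0, 1]; squared terms square the single factor.
    A ``None`` term (regulated production removed by a knock-out) is 0.
    """
    if term is None:
        return 0.0
    k_values = list(halfmax)
    if len(term.factors) == 2 and (len(k_values) < 2 or k_values[1] is None):
        raise DynamicsError("two-factor term requires a second half-max constant")
    value = 1.0
    for (reg, sign), K in zip(term.factors, k_values):
        if K is None or K <= 0:
            raise DynamicsError("half-max constants must be positive")
        level = protein_levels[reg]
        if level < 0:
            raise DynamicsError("protein levels must be non-negative")
        hill = level / (K + level) if sign == ACTIVATION else K / (K + level)
        value *= hill
    if term.exponent == 2:
        value *= value
    return value


@njit(cache=True)
def _rhs_odeint(y, t, alphas, ktx, km, kp, kmain, ksec, codes, ktrans):  # pragma: no cover
    # odeint-native argument order (state first); body shared with _rhs_kernel
    return _rhs_kernel(y, alphas, ktx, km, kp, kmain, ksec, codes, ktrans)


@njit(cache=True)
def _rhs_kernel(y, alphas, ktx, km, kp, kmain, ksec, codes, ktrans):  # pragma: no cover
    n = alphas.shape[0]
    dy = np.empty(2 * n)
    for g in range(n):
        reg1 = codes[g, 0]
        if reg1 >= 0:
            p = y[n + reg1]
            k = kmain[g]
            f = p / (k + p) if codes[g, 1] == 0 else k / (k + p)
            if codes[g, 4] == 2:
                f = f * f
            reg2 = codes[g, 2]
            if reg2 >= 0:
                p2 = y[n + reg2]
                k2 = ksec[g]
                f2 = p2 / (k2 + p2) if codes[g, 3] == 0 else k2 / (k2 + p2)
                f = f * f2
        else:
            f = 0.0
        dy[g] = alphas[g] + ktx[g] * f - km * y[g]
        dy[n + g] = ktrans * y[g] - kp * y[n + g]
    return dy


@dataclass
class CompiledModel:
    """A structure + parameters packed into flat arrays for the ODE kernel."""

    genes: tuple[str, ...]
    proteins: tuple[str, ...]
    alphas: np.ndarray
    ktx: np.ndarray
    km: float
    kp: float
    kmain: np.ndarray
    ksec: np.ndarray
    codes: np.ndarray
    y0: np.ndarray
    ktrans: float

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return _rhs_kernel(
            y, self.alphas, self.ktx, self.km, self.kp, self.kmain, self.ksec, self.codes, self.ktrans
        )

    @property
    def args(self) -> tuple:
        return (
            self.alphas, self.ktx, self.km, self.kp,
            self.kmain, self.ksec, self.codes, self.ktrans,
        )


def compile_model(model: RegulatoryModel, params: ParameterSet) -> CompiledModel:
    """Validate and pack a model/parameter pair for integration."""
    params.validate()
    genes = model.genes
    proteins = model.proteins
    protein_pos = {p: i for i, p in enumerate(proteins)}
    n = len(genes)
    alphas = np.empty(n)
    ktx = np.empty(n)
    kmain = np.ones(n)
    ksec = np.ones(n)
    codes = np.full((n, 5), -1, dtype=np.int64)
    for g, gene in enumerate(genes):
        alphas[g] = params.alpha[gene]
        ktx[g] = params.k_tx[gene]
        term = model.terms[gene]
        codes[g, 4] = 1
        if term is None:
            continue
        pos = GENE_POSITION[gene]
        for j, (reg, sign) in enumerate(term.factors):
            if reg not in protein_pos:
                raise DynamicsError(f"{gene} term references protein {reg} not in the model")
            k_index = pos if j == 0 else pos + 3
            if k_index not in params.K:
                raise DynamicsError(f"missing half-max constant K_{k_index} for {gene}")
            codes[g, 2 * j] = protein_pos[reg]
            codes[g, 2 * j + 1] = 0 if sign == ACTIVATION else 1
            if j == 0:
                kmain[g] = params.K[k_index]
            else:
                ksec[g] = params.K[k_index]
        codes[g, 4] = term.exponent
    y0 = np.empty(2 * n)
    for g, gene in enumerate(genes):
        y0[g] = params.m0[gene]
        y0[n + g] = params.p0[proteins[g]]
    ktrans = 1.0 if params.translation_rate is None else params.translation_rate
    return CompiledModel(
        genes=genes,
        proteins=proteins,
        alphas=alphas,
        ktx=ktx,
        km=params.k_m,
        kp=params.k_p,
        kmain=kmain,
        ksec=ksec,
        codes=codes,
        y0=y0,
        ktrans=ktrans,
    )


def rhs(model: RegulatoryModel, state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Time derivative of the state vector ``[M_g..., P_g...]`` (gene order)."""
    compiled = compile_model(model, params)
    state = np.asarray(state, dtype=float)
    if state.shape != compiled.y0.shape:
        raise DynamicsError(f"state must have shape {compiled.y0.shape}")
    return compiled.rhs(0.0, state)


@dataclass
class Trajectories:
    """Integrated trajectories; the observables are the mRNA states only."""

    times: np.ndarray
    genes: tuple[str, ...]
    proteins: tuple[str, ...]
    mrna: np.ndarray      # shape (n_genes, n_times)
    protein: np.ndarray   # shape (n_genes, n_times) — hidden states

    def mrna_for(self, gene: str) -> np.ndarray:
        return self.mrna[self.genes.index(gene)]

    def to_frame(self):
        import pandas as pd

        rows = []
        for g, gene in enumerate(self.genes):
            for j, t in enumerate(self.times):
                rows.append((t, f"mRNA:{gene}", self.mrna[g, j]))
                rows.append((t, f"protein:{self.proteins[g]}", self.protein[g, j]))
        return pd.DataFrame(rows, columns=["time", "state", "value"])


class _EvalBudgetExceeded(Exception):
    pass


def simulate(
    model: RegulatoryModel,
    params: ParameterSet,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    max_rhs_evals: int = 200_000,
) -> Trajectories:
    """Integrate the model from t = 0 and report all states at ``times``.

    Raises :class:`IntegrationFailure` on solver failure, non-finite states or
    negative excursions beyond tolerance (never silently clipped).  The
    right-hand-side evaluation budget bounds runaway stiffness from
    pathological parameters; admissible dynamics use a few thousand.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise DynamicsError("times must be a non-empty 1-D array")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise DynamicsError("times must be non-negative and strictly increasing")
    compiled = compile_model(model, params)
    t_end = float(times[-1])
    if t_end == 0.0:
        states = compiled.y0[:, None].repeat(times.size, axis=1)
    else:
        evals = 0

        def guarded_rhs(t, y):
            nonlocal evals
            evals += 1
            if evals > max_rhs_evals:
                raise _EvalBudgetExceeded
            return compiled.rhs(t, y)

        try:
            sol = solve_ivp(
                guarded_rhs,
                (0.0, t_end),
                compiled.y0,
                method=method,
                t_eval=times,
                rtol=rtol,
                atol=atol,
            )
        except _EvalBudgetExceeded:
            raise IntegrationFailure(
                f"rhs evaluation budget ({max_rhs_evals}) exceeded; pathological stiffness"
            ) from None
        if not sol.success or sol.y.shape[1] != times.size:
            raise IntegrationFailure(f"solver failed: {sol.message}")
        states = sol.y
    if not np.all(np.isfinite(states)):
        raise IntegrationFailure("non-finite state encountered")
    if states.min() < NEGATIVITY_TOL:
        raise IntegrationFailure(f"negative state excursion {states.min():.3e}")
    n = len(compiled.genes)
    return Trajectories(
        times=times,
        genes=compiled.genes,
        proteins=compiled.proteins,
        mrna=states[:n],
        protein=states[n:],
    )


def integrate_mrna(
    y0: np.ndarray,
    args: tuple,
    n_genes: int,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    mxstep: int = 3000,
) -> Optional[np.ndarray]:
    """Low-level fast mRNA integration used inside optimisation loops.

    Same LSODA algorithm as :func:`simulate` driven through the lower-overhead
    ``odeint`` entry point (the compiled right-hand side is called without any
    Python wrapper) with a step cap; returns ``None`` instead of raising so
    penalised objective evaluations stay cheap.
    """
    prepend = times[0] > 0.0
    t = np.concatenate(([0.0], times)) if prepend else times
    if t.size == 1:
        states = y0[None, :]
    else:
        with np.errstate(all="ignore"):
            states, info = odeint(
                _rhs_odeint,
                y0,
                t,
                args=args,
                rtol=rtol,
                atol=atol,
                mxstep=mxstep,
                full_output=True,
            )
        if info["message"] != "Integration successful.":
            return None
    if prepend:
        states = states[1:]
    mrna = states[:, :n_genes].T
    if not np.all(np.isfinite(mrna)) or mrna.min() < NEGATIVITY_TOL:
        return None
    return mrna


def simulate_mrna(
    compiled: CompiledModel,
    times: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    mxstep: int = 3000,
) -> Optional[np.ndarray]:
    """Fast mRNA-only integration of a packed model (see :func:`integrate_mrna`)."""
    return integrate_mrna(
        compiled.y0, compiled.args, len(compiled.genes), times,
        rtol=rtol, atol=atol, mxstep=mxstep,
    )


def apply_scaling_symmetry(params: ParameterSet, xi: float) -> ParameterSet:
    """Apply the scaling symmetry (P, K, k_t) -> (xi*P, xi*K, xi*k_t).

    Defined on the unreduced model only (explicit translation rate).  The mRNA
    parameters are untouched, so the observable dynamics are invariant for any
    xi > 0; xi = 1/k_t lands in the reduced coordinates.
    """
    if params.translation_rate is None:
        raise DynamicsError("scaling symmetry applies to the unreduced model only")
    if not np.isfinite(xi) or xi <= 0:
        raise DynamicsError("xi must be a positive finite scale factor")
    return replace(
        params,
        K={k: v * xi for k, v in params.K.items()},
        p0={p: v * xi for p, v in params.p0.items()},
        translation_rate=params.translation_rate * xi,
    )


def reduce_parameters(params: ParameterSet) -> ParameterSet:
    """Remove the scaling symmetry by setting xi = 1/k_t (reduced coordinates)."""
    if params.translation_rate is None:
        raise DynamicsError("parameters are already in reduced coordinates")
    reduced = apply_scaling_symmetry(params, 1.0 / params.translation_rate)
    return replace(reduced, translation_rate=None)
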