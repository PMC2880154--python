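"""SIS eco-epidemiological dynamics over genotypes and sexes.

For each genotype i the system tracks susceptible and infected densities
of both sexes.  Births (from :func:`sisevol.genetics.birth_rates`) are
split 1:1 between the sexes; transmission is density dependent (mass
action) with a force of infection β_sex · I_tot where I_tot sums infected
hosts of every sex and genotype (infectivity is independent of sex and
genotype); recovery returns hosts to the susceptible class of the same
sex and genotype (no acquired immunity); virulence α adds mortality while
infected:

    dS_f^i/dt = B_i/2 − d_f^i S_f^i − β_f S_f^i I_tot + γ_f^i I_f^i
    dI_f^i/dt = β_f S_f^i I_tot − (d_f^i + α_f + γ_f^i) I_f^i

and symmetrically for males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .genetics import (DegeneratePopulationError, PhenotypeTable, S_F, I_F,
                       S_M, I_M, birth_rates)
from .params import ParameterSet
from .tradeoffs import Phenotype

__all__ = [
    "EquilibriumResult", "derivatives", "integrate_to_equilibrium",
    "carrying_capacity", "disease_free_state", "basic_reproductive_ratio",
    "resident_equilibrium", "EXTINCTION_DENSITY",
]

#: densities below this (summed over compartments) count as extinct
EXTINCTION_DENSITY = 1e-8

#: default residual tolerance max|dX/dt| for declaring equilibrium
EQUILIBRIUM_TOL = 1e-9


@dataclass
class EquilibriumResult:
    """Outcome of an equilibrium computation.

    ``state`` has shape (n_genotypes, 4) with columns [S_f, I_f, S_m, I_m].
    ``kind`` is one of "extinct", "disease-free", "endemic".
    """

    state: np.ndarray
    kind: str
    prevalence_f: float
    prevalence_m: float
    converged: bool
    residual: float

    @property
    def N(self) -> float:
        return float(self.state.sum())

    @property
    def I_tot(self) -> float:
        return float(self.state[:, I_F].sum() + self.state[:, I_M].sum())


def derivatives(state: np.ndarray, params: ParameterSet,
                phenotypes: PhenotypeTable, delta: np.ndarray) -> np.ndarray:
    """Time derivatives of the full genotype-resolved SIS system.

    ``state`` may be flat or (n, 4); the result matches the input shape.
    """
    y = np.asarray(state, dtype=float)
    Y = y.reshape(-1, 4)
    if np.any(Y < -1e-6):
        raise FloatingPointError("negative densities passed to derivatives")
    try:
        B = birth_rates(Y, params, phenotypes, delta)
    except DegeneratePopulationError:
        B = np.zeros(phenotypes.n)
    I_tot = Y[:, I_F].sum() + Y[:, I_M].sum()
    dY = np.empty_like(Y)
    inf_f = params.beta_f * Y[:, S_F] * I_tot
    inf_m = params.beta_m * Y[:, S_M] * I_tot
    dY[:, S_F] = B / 2 - phenotypes.d_f * Y[:, S_F] - inf_f \
        + phenotypes.gamma_f * Y[:, I_F]
    dY[:, I_F] = inf_f - (phenotypes.d_f + params.alpha_f
                          + phenotypes.gamma_f) * Y[:, I_F]
    dY[:, S_M] = B / 2 - phenotypes.d_m * Y[:, S_M] - inf_m \
        + phenotypes.gamma_m * Y[:, I_M]
    dY[:, I_M] = inf_m - (phenotypes.d_m + params.alpha_m
                          + phenotypes.gamma_m) * Y[:, I_M]
    return dY.reshape(y.shape)


def _prevalences(Y: np.ndarray) -> tuple[float, float]:
    f_tot = Y[:, S_F].sum() + Y[:, I_F].sum()
    m_tot = Y[:, S_M].sum() + Y[:, I_M].sum()
    prev_f = Y[:, I_F].sum() / f_tot if f_tot > 0 else 0.0
    prev_m = Y[:, I_M].sum() / m_tot if m_tot > 0 else 0.0
    return float(prev_f), float(prev_m)


def _classify(Y: np.ndarray, converged: bool, residual: float) -> EquilibriumResult:
    Y = Y.copy()
    Y[Y < EXTINCTION_DENSITY * 1e-3] = 0.0
    N = Y.sum()
    I_tot = Y[:, I_F].sum() + Y[:, I_M].sum()
    if N < EXTINCTION_DENSITY:
        kind = "extinct"
    elif I_tot < EXTINCTION_DENSITY:
        kind = "disease-free"
        Y[:, I_F] = 0.0
        Y[:, I_M] = 0.0
    else:
        kind = "endemic"
    prev_f, prev_m = _prevalences(Y)
    return EquilibriumResult(state=Y, kind=kind, prevalence_f=prev_f,
                             prevalence_m=prev_m, converged=converged,
                             residual=residual)


def integrate_to_equilibrium(
    initial: np.ndarray,
    params: ParameterSet,
    phenotypes: PhenotypeTable,
    delta: np.ndarray,
    tol: float = EQUILIBRIUM_TOL,
    t_max: float = 2.0e4,
    chunk: float = 250.0,
    polish: bool = True,
) -> EquilibriumResult:
    """Integrate the ODE system until max|dX/dt| < ``tol`` or ``t_max``.

    Integration proceeds in chunks; once the residual is small the state is
    optionally polished with a Newton-type root solve on the derivative map
    (accepted only if it stays non-negative and reduces the residual).
    Non-convergence by ``t_max`` is reported with ``converged=False``.
    """
    y = np.asarray(initial, dtype=float).ravel().copy()
    if np.any(y < 0):
        raise ValueError("initial densities must be non-negative")
    if y.sum() == 0:
        raise ValueError("initial population is empty")

    def rhs(t: float, yy: np.ndarray) -> np.ndarray:
        return derivatives(np.clip(yy, 0.0, None), params, phenotypes, delta)

    t = 0.0
    residual = float(np.max(np.abs(rhs(0.0, y))))
    while t < t_max and residual >= tol:
        sol = solve_ivp(rhs, (0.0, chunk), y, method="LSODA",
                        rtol=1e-9, atol=1e-12)
        if not sol.success:
            return _classify(np.clip(y, 0.0, None).reshape(-1, 4), False, residual)
        y = np.clip(sol.y[:, -1], 0.0, None)
        t += chunk
        residual = float(np.max(np.abs(rhs(0.0, y))))
        if polish and residual < 1e-4:
            res = root(lambda yy: derivatives(np.clip(yy, 0.0, None), params,
                                              phenotypes, delta),
                       y, method="hybr")
            if res.success:
                cand = res.x
                if np.min(cand) > -1e-10:
                    cand = np.clip(cand, 0.0, None)
                    cand_res = float(np.max(np.abs(rhs(0.0, cand))))
                    if cand_res < residual:
                        y, residual = cand, cand_res
    converged = residual < tol
    return _classify(y.reshape(-1, 4), converged, residual)


def carrying_capacity(params: ParameterSet, phen_f: Phenotype,
                      phen_m: Phenotype | None = None) -> float:
    """Disease-free equilibrium host density of a monomorphic population.

    Births balance female deaths at b(1 − qN)/2 = d_f, so
    K = (1 − 2 d_f / b) / q — female mortality alone sets total density,
    because births are proportional to female density only.  Returns 0
    (population not viable) when b ≤ 2 d_f.
    """
    if params.b <= 0:
        return 0.0
    K = (1.0 - 2.0 * phen_f.d / params.b) / params.q
    return max(K, 0.0)


def disease_free_state(params: ParameterSet, phen_f: Phenotype,
                       phen_m: Phenotype) -> np.ndarray:
    """Disease-free equilibrium state (1, 4) of a monomorphic population.

    Total density K splits between the sexes in inverse proportion to
    their death rates: S_f = K d_m/(d_f+d_m), S_m = K d_f/(d_f+d_m); with
    equal death rates each sex holds K/2.
    """
    K = carrying_capacity(params, phen_f, phen_m)
    denom = phen_f.d + phen_m.d
    S_f = K * phen_m.d / denom
    S_m = K * phen_f.d / denom
    return np.array([[S_f, 0.0, S_m, 0.0]])


def basic_reproductive_ratio(params: ParameterSet, phen_f: Phenotype,
                             phen_m: Phenotype) -> float:
    """R₀ of the pathogen at the disease-free equilibrium.

    Next-generation value: an infected host of sex s stays infected for
    1/(d_s + α_s + γ_s) and infects susceptible females at rate β_f S̄_f
    and males at β_m S̄_m, giving the rank-one next-generation matrix
    eigenvalue

        R₀ = β_f S̄_f/(d_f+α_f+γ_f) + β_m S̄_m/(d_m+α_m+γ_m),

    which collapses to K β/(d+α+γ) for symmetric sexes.  Raises
    ``ValueError`` if the disease-free population is not viable (K ≤ 0).
    """
    K = carrying_capacity(params, phen_f, phen_m)
    if K <= 0:
        raise ValueError("no viable disease-free population (K <= 0)")
    dfe = disease_free_state(params, phen_f, phen_m)[0]
    T_f = 1.0 / (phen_f.d + params.alpha_f + phen_f.gamma)
    T_m = 1.0 / (phen_m.d + params.alpha_m + phen_m.gamma)
    return params.beta_f * dfe[S_F] * T_f + params.beta_m * dfe[S_M] * T_m


# a single-genotype cross always breeds true: delta is the 1x1x1 identity
_DELTA_MONO = np.ones((1, 1, 1))


def _mono_table(phen_f: Phenotype, phen_m: Phenotype) -> PhenotypeTable:
    return PhenotypeTable(
        d_f=np.array([phen_f.d]), gamma_f=np.array([phen_f.gamma]),
        phi_f=np.array([phen_f.phi]), d_m=np.array([phen_m.d]),
        gamma_m=np.array([phen_m.gamma]), phi_m=np.array([phen_m.phi]),
    )


def resident_equilibrium(
    params: ParameterSet,
    phen_f: Phenotype,
    phen_m: Phenotype,
    seed_infection: bool = True,
    initial: np.ndarray | None = None,
    tol: float = EQUILIBRIUM_TOL,
    t_max: float = 2.0e4,
) -> EquilibriumResult:
    """Ecological equilibrium of a monomorphic (single-genotype) resident.

    Starts from the analytic disease-free state, seeds a small infection
    when the pathogen can invade (R₀ > 1), and integrates to equilibrium.
    ``initial`` warm-starts the integration (e.g. from a neighbouring
    parameter set during sweeps).
    """
    table = _mono_table(phen_f, phen_m)
    K = carrying_capacity(params, phen_f, phen_m)
    if K <= 0:
        empty = np.zeros((1, 4))
        return EquilibriumResult(state=empty, kind="extinct", prevalence_f=0.0,
                                 prevalence_m=0.0, converged=True, residual=0.0)
    if initial is not None:
        y0 = np.asarray(initial, dtype=float).reshape(1, 4).copy()
        if seed_infection and y0[0, I_F] + y0[0, I_M] < EXTINCTION_DENSITY:
            y0[0, I_F] = y0[0, I_M] = 1e-3 * K
    else:
        y0 = disease_free_state(params, phen_f, phen_m)
        if seed_infection and basic_reproductive_ratio(params, phen_f, phen_m) > 1.0:
            y0 = y0.copy()
            y0[0, I_F] = 1e-2 * y0[0, S_F]
            y0[0, I_M] = 1e-2 * y0[0, S_M]
    return integrate_to_equilibrium(y0, params, table, _DELTA_MONO,
                                    tol=tol, t_max=t_max)
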