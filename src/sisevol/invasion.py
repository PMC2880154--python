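"""Invasion fitness of rare mutant alleles.

A monomorphic resident (one allele at each locus) sits at its ecological
equilibrium.  A mutant allele introduced at one locus at vanishingly low
frequency initially occurs almost exclusively in heterozygotes at that
locus (mutant homozygotes and double heterozygotes are second order in
rarity), so the linearized dynamics of the four mutant-carrying classes
(S_f, I_f, S_m, I_m of the heterozygote) govern invasion: the mutant
spreads iff the dominant eigenvalue of that 4×4 linear operator is
positive.

The linearized birth inflow follows Mendelian bookkeeping: a heterozygote
mother crossed with resident fathers passes the mutant to half her
offspring, and a heterozygote father fertilises resident mothers in
proportion to his relative effective reproductive weight, again passing
the mutant to half of those offspring:

    B_het ≈ b(1 − qN̄) [ F_het/2 + F̄ M_het / (2 M̄) ]

with all resident quantities (N̄, F̄, M̄, Ī) frozen at the resident
equilibrium.  When the mutant equals the resident allele the equilibrium
state itself is a null vector of the operator, so self-invasion is
exactly neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecodynamics import EquilibriumResult, resident_equilibrium
from .genetics import Allele, FEMALE_LOCUS, MALE_LOCUS, S_F, I_F, S_M, I_M
from .params import ParameterSet
from .tradeoffs import Phenotype, TradeoffModel, phenotype_of

__all__ = ["EPS_NEUTRAL", "ResidentContext", "resident_context",
           "mutant_subsystem", "invasion_fitness", "InvasionResult",
           "PIPGrid", "pip"]

#: eigenvalues within this band of zero are treated as neutral
EPS_NEUTRAL = 1e-6


@dataclass
class ResidentContext:
    """A resident strategy with its phenotypes and ecological equilibrium."""

    params: ParameterSet
    model_f: TradeoffModel
    model_m: TradeoffModel
    x_f: float
    x_m: float
    phen_f: Phenotype
    phen_m: Phenotype
    equilibrium: EquilibriumResult


def resident_context(
    x_f: float,
    x_m: float,
    params: ParameterSet,
    model_f: TradeoffModel,
    model_m: TradeoffModel,
    initial: np.ndarray | None = None,
    seed_infection: bool = True,
) -> ResidentContext:
    """Equilibrate a monomorphic resident with traits (x_f, x_m)."""
    phen_f = phenotype_of(x_f, model_f, params)
    phen_m = phenotype_of(x_m, model_m, params)
    eq = resident_equilibrium(params, phen_f, phen_m,
                              seed_infection=seed_infection, initial=initial)
    return ResidentContext(params=params, model_f=model_f, model_m=model_m,
                           x_f=x_f, x_m=x_m, phen_f=phen_f, phen_m=phen_m,
                           equilibrium=eq)


def mutant_subsystem(ctx: ResidentContext, mutant: Allele) -> np.ndarray:
    """4×4 linear operator for the rare mutant heterozygote classes.

    Rows/columns are ordered [S_f, I_f, S_m, I_m].  Raises ``ValueError``
    if the resident equilibrium is extinct or not converged.
    """
    eq = ctx.equilibrium
    if eq.kind == "extinct":
        raise ValueError("resident population is extinct; invasion undefined")
    if not eq.converged:
        raise ValueError("resident equilibrium did not converge")
    p = ctx.params
    st = eq.state[0]
    N = eq.N
    I_bar = st[I_F] + st[I_M]
    F_bar = st[S_F] + ctx.phen_f.phi * st[I_F]
    M_bar = st[S_M] + ctx.phen_m.phi * st[I_M]
    if M_bar <= 0:
        raise ValueError("resident has zero male reproductive weight")

    # heterozygote phenotype: mutated locus averages resident and mutant
    # alleles; the other sex expresses the unchanged resident trait
    if mutant.locus == FEMALE_LOCUS:
        x_het = 0.5 * (ctx.x_f + mutant.value)
        ph_f = phenotype_of(x_het, ctx.model_f, p)
        ph_m = ctx.phen_m
    else:
        x_het = 0.5 * (ctx.x_m + mutant.value)
        ph_f = ctx.phen_f
        ph_m = phenotype_of(x_het, ctx.model_m, p)

    fac = p.b * max(1.0 - p.q * N, 0.0)
    bf = fac / 4.0                 # per-sex inflow from heterozygote mothers
    bm = fac * F_bar / (4.0 * M_bar)  # ... from heterozygote fathers
    J = np.array([
        [bf - ph_f.d - p.beta_f * I_bar, bf * ph_f.phi + ph_f.gamma,
         bm, bm * ph_m.phi],
        [p.beta_f * I_bar, -(ph_f.d + p.alpha_f + ph_f.gamma), 0.0, 0.0],
        [bf, bf * ph_f.phi,
         bm - ph_m.d - p.beta_m * I_bar, bm * ph_m.phi + ph_m.gamma],
        [0.0, 0.0, p.beta_m * I_bar, -(ph_m.d + p.alpha_m + ph_m.gamma)],
    ])
    return J


@dataclass
class InvasionResult:
    """Dominant eigenvalue and verdict for one (resident, mutant) pair."""

    resident: tuple[float, float]
    mutant: Allele
    dominant_eigenvalue: float
    invades: bool


def invasion_fitness(resident, mutant: Allele,
                     params: ParameterSet | None = None,
                     model_f: TradeoffModel | None = None,
                     model_m: TradeoffModel | None = None) -> InvasionResult:
    """Invasion fitness of ``mutant`` against a resident strategy.

    ``resident`` is either a ready :class:`ResidentContext` or an
    (x_f, x_m) pair, in which case ``params`` and the trade-off models are
    required and the resident equilibrium is computed here.
    """
    if isinstance(resident, ResidentContext):
        ctx = resident
    else:
        if params is None or model_f is None or model_m is None:
            raise TypeError("params and trade-off models required when "
                            "resident is a trait pair")
        ctx = resident_context(resident[0], resident[1], params, model_f, model_m)
    J = mutant_subsystem(ctx, mutant)
    lam = float(np.max(np.linalg.eigvals(J).real))
    return InvasionResult(resident=(ctx.x_f, ctx.x_m), mutant=mutant,
                          dominant_eigenvalue=lam, invades=lam > EPS_NEUTRAL)


@dataclass
class PIPGrid:
    """Pairwise-invasion plot: sign of invasion fitness on a trait grid."""

    locus: int
    resident_grid: np.ndarray
    mutant_grid: np.ndarray
    eigenvalues: np.ndarray  # shape (n_resident, n_mutant); NaN = failed cell
    signs: np.ndarray        # -1 / 0 / +1, 0 within the neutral band

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.resident_grid):
            for j, m in enumerate(self.mutant_grid):
                rows.append({"resident": r, "mutant": m,
                             "eigenvalue": self.eigenvalues[i, j],
                             "sign": self.signs[i, j]})
        return pd.DataFrame(rows)


def pip(locus: int, params: ParameterSet, model_f: TradeoffModel,
        model_m: TradeoffModel, grid: np.ndarray | None = None,
        grid_size: int = 21, fixed_other_trait: float = 0.5) -> PIPGrid:
    """Pairwise-invasion plot at one locus, other locus fixed monomorphic.

    Residents whose equilibrium fails to converge are recorded as NaN
    columns rather than fabricated.
    """
    if grid is None:
        grid = np.linspace(0.02, 0.98, grid_size)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("PIP grid must lie strictly inside (0, 1)")
    n = len(grid)
    eig = np.full((n, n), np.nan)
    warm: np.ndarray | None = None
    for i, r in enumerate(grid):
        x_f, x_m = ((r, fixed_other_trait) if locus == FEMALE_LOCUS
                    else (fixed_other_trait, r))
        ctx = resident_context(x_f, x_m, params, model_f, model_m, initial=warm)
        if not ctx.equilibrium.converged or ctx.equilibrium.kind == "extinct":
            continue
        warm = ctx.equilibrium.state
        for j, m in enumerate(grid):
            res = invasion_fitness(ctx, Allele(locus=locus, value=float(m)))
            eig[i, j] = res.dominant_eigenvalue
    signs = np.zeros_like(eig)
    signs[eig > EPS_NEUTRAL] = 1.0
    signs[eig < -EPS_NEUTRAL] = -1.0
    signs[np.isnan(eig)] = np.nan
    return PIPGrid(locus=locus, resident_grid=grid, mutant_grid=grid.copy(),
                   eigenvalues=eig, signs=signs)
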