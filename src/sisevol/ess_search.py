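"""Numerical search for joint evolutionarily stable strategies.

The ESS of the two sex-limited traits (x_f*, x_m*) is a resident strategy
against which no rare mutant allele at either locus has positive invasion
fitness.  It is located as a fixed point of alternating best responses:
given the resident, the mutant trait value maximising invasion fitness is
found at each locus in turn (coarse grid, then bounded scalar refinement)
and the resident is moved toward it, until the best response at both loci
coincides with the resident.  The reported fixed point is then certified
by scanning a fine mutant grid at both loci and recording the largest
eigenvalue found.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genetics import Allele, FEMALE_LOCUS, MALE_LOCUS
from .invasion import (EPS_NEUTRAL, ResidentContext, invasion_fitness,
                       resident_context)
from .params import ParameterSet
from .tradeoffs import Phenotype, TradeoffModel

__all__ = ["ESSResult", "best_response", "find_ess", "find_ess_multistart",
           "sweep", "TRAIT_LO", "TRAIT_HI"]

# search domain kept strictly inside (0, 1); the trade-off shapes diverge
# at the boundary so nothing of interest lives outside this window
TRAIT_LO = 0.01
TRAIT_HI = 0.99


@dataclass
class ESSResult:
    """A candidate joint ESS with its ecological diagnostics.

    ``certificate`` is the maximum mutant eigenvalue over the verification
    grid at both loci; an interior ESS requires it to be ≤ the neutral
    band.  ``status`` is "interior-ESS", "boundary" or "not-found".
    """

    x_f_star: float
    x_m_star: float
    phen_f: Phenotype
    phen_m: Phenotype
    prevalence_f: float
    prevalence_m: float
    N: float
    equilibrium_kind: str
    status: str
    certificate: float
    iterations: int
    convergence_stable: bool | None = None


def _fitness_fn(ctx: ResidentContext, locus: int):
    def lam(m: float) -> float:
        return invasion_fitness(ctx, Allele(locus=locus, value=float(m))
                                ).dominant_eigenvalue
    return lam


def best_response(ctx: ResidentContext, locus: int,
                  candidate_grid: np.ndarray | None = None) -> float:
    """Mutant trait value maximising invasion fitness at one locus.

    Scans ``candidate_grid`` (default 21 points across the search domain),
    then refines the best cell with a bounded golden-section/Brent search.
    If no mutant improves on neutrality the resident value is returned
    (ties break toward the resident).
    """
    if candidate_grid is None:
        candidate_grid = np.linspace(TRAIT_LO, TRAIT_HI, 21)
    lam = _fitness_fn(ctx, locus)
    resident_value = ctx.x_f if locus == FEMALE_LOCUS else ctx.x_m
    values = np.array([lam(m) for m in candidate_grid])
    k = int(np.argmax(values))
    # refine inside the bracketing cells around the best grid point
    lo = candidate_grid[max(k - 1, 0)]
    hi = candidate_grid[min(k + 1, len(candidate_grid) - 1)]
    if hi > lo:
        opt = minimize_scalar(lambda m: -lam(m), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-7})
        best_m, best_lam = float(opt.x), -float(opt.fun)
        if values[k] > best_lam:
            best_m, best_lam = float(candidate_grid[k]), float(values[k])
    else:
        best_m, best_lam = float(candidate_grid[k]), float(values[k])
    if best_lam <= EPS_NEUTRAL:
        return float(resident_value)
    return best_m


def _selection_gradient(params, model_f, model_m, x: np.ndarray, locus: int,
                        warm: np.ndarray | None = None,
                        h: float = 5e-4) -> tuple[float, np.ndarray]:
    """Central-difference selection gradient ∂λ/∂m at m = x[locus]."""
    ctx = resident_context(x[0], x[1], params, model_f, model_m, initial=warm)
    lam = _fitness_fn(ctx, locus)
    lo = max(x[locus] - h, TRAIT_LO)
    hi = min(x[locus] + h, TRAIT_HI)
    g = (lam(hi) - lam(lo)) / (hi - lo)
    return float(g), ctx.equilibrium.state


def _polish_singular_point(params, model_f, model_m, x: np.ndarray,
                           warm: np.ndarray | None,
                           window: float = 1e-2, rounds: int = 3) -> np.ndarray:
    """Refine a singular strategy by zeroing the selection gradient.

    The argmax-based best response locates the fitness peak only to the
    flatness of the eigenvalue landscape; the selection gradient is far
    better conditioned near the peak, so a few Gauss–Seidel rounds of
    1-D root finding on it sharpen the fixed point by 1–2 digits.
    """
    from scipy.optimize import brentq

    x = x.copy()
    for _ in range(rounds):
        moved = 0.0
        for locus in (FEMALE_LOCUS, MALE_LOCUS):
            def g_of(v: float) -> float:
                xt = x.copy()
                xt[locus] = v
                g, _ = _selection_gradient(params, model_f, model_m, xt, locus,
                                           warm=warm)
                return g
            lo = max(x[locus] - window, TRAIT_LO)
            hi = min(x[locus] + window, TRAIT_HI)
            try:
                g_lo, g_hi = g_of(lo), g_of(hi)
                if g_lo * g_hi > 0:
                    continue
                root = brentq(g_of, lo, hi, xtol=1e-8, rtol=1e-12)
            except (ValueError, RuntimeError):
                continue
            moved = max(moved, abs(root - x[locus]))
            x[locus] = float(root)
        if moved < 1e-8:
            break
    return x


def _certificate(ctx: ResidentContext, n_grid: int = 101) -> tuple[float, float]:
    """(max eigenvalue, max |eigenvalue|) over a fine mutant grid, both loci."""
    grid = np.linspace(TRAIT_LO, TRAIT_HI, n_grid)
    lam_max = -np.inf
    abs_max = 0.0
    for locus in (FEMALE_LOCUS, MALE_LOCUS):
        lam = _fitness_fn(ctx, locus)
        for m in grid:
            v = lam(m)
            lam_max = max(lam_max, v)
            abs_max = max(abs_max, abs(v))
    return float(lam_max), float(abs_max)


def _convergence_stable(params, model_f, model_m, x: np.ndarray,
                        h: float = 5e-3) -> bool:
    """Sign test of the selection gradient on either side of the ESS."""
    eps = 1e-4
    for locus in (FEMALE_LOCUS, MALE_LOCUS):
        for side in (-1.0, 1.0):
            xr = x.copy()
            xr[locus] = float(np.clip(xr[locus] + side * h, TRAIT_LO, TRAIT_HI))
            ctx = resident_context(xr[0], xr[1], params, model_f, model_m)
            lam = _fitness_fn(ctx, locus)
            # invasion fitness of the resident itself is exactly neutral, so
            # lam(x + eps)/eps is the local selection gradient
            g = lam(xr[locus] + eps) / eps
            if side * g > 1e-4:  # gradient points away from the ESS
                return False
    return True


def find_ess(
    params: ParameterSet,
    model_f: TradeoffModel,
    model_m: TradeoffModel,
    init: tuple[float, float] = (0.5, 0.5),
    coarse_grid: int = 21,
    tol: float = 1e-4,
    max_iter: int = 200,
    relax: float = 0.5,
    certify: bool = True,
    check_convergence_stability: bool = False,
) -> ESSResult:
    """Locate the joint ESS (x_f*, x_m*) by alternating best responses.

    The resident is relaxed a fraction ``relax`` of the way toward each
    locus's best response (damping guards against overshoot cycles);
    convergence requires the undamped best response at both loci to lie
    within ``tol`` of the resident.  Residents driven to the edge of the
    search domain are reported with status "boundary"; exhausting
    ``max_iter`` yields "not-found".
    """
    x = np.array(init, dtype=float)
    grid = np.linspace(TRAIT_LO, TRAIT_HI, coarse_grid)
    warm: np.ndarray | None = None
    status = "not-found"
    iterations = 0
    ctx = None
    for iterations in range(1, max_iter + 1):
        deltas = np.zeros(2)
        for locus in (FEMALE_LOCUS, MALE_LOCUS):
            ctx = resident_context(x[0], x[1], params, model_f, model_m,
                                   initial=warm)
            if ctx.equilibrium.kind == "extinct" or not ctx.equilibrium.converged:
                raise RuntimeError("resident equilibrium failed during ESS search")
            warm = ctx.equilibrium.state
            br = best_response(ctx, locus, grid)
            deltas[locus] = abs(br - x[locus])
            x[locus] = float(np.clip(x[locus] + relax * (br - x[locus]),
                                     TRAIT_LO, TRAIT_HI))
        if np.all(deltas < tol):
            status = "interior-ESS"
            break
    if status == "interior-ESS":
        x = _polish_singular_point(params, model_f, model_m, x, warm)
    ctx = resident_context(x[0], x[1], params, model_f, model_m, initial=warm)
    edge = min(x[0] - TRAIT_LO, TRAIT_HI - x[0],
               x[1] - TRAIT_LO, TRAIT_HI - x[1])
    if status == "interior-ESS" and edge < 2 * tol:
        status = "boundary"
    certificate = np.nan
    if certify and status != "not-found":
        certificate, abs_max = _certificate(ctx)
        if status == "interior-ESS":
            if certificate > 10 * EPS_NEUTRAL:
                status = "not-found"
            elif (ctx.equilibrium.kind == "disease-free"
                  and abs_max <= EPS_NEUTRAL):
                # pathogen eradicated and the whole trait axis neutral:
                # the iteration stalled on a selection-free plateau, not
                # at a genuine fitness peak
                status = "neutral"
    conv = None
    if check_convergence_stability and status == "interior-ESS":
        conv = _convergence_stable(params, model_f, model_m, x)
    eq = ctx.equilibrium
    return ESSResult(
        x_f_star=float(x[0]), x_m_star=float(x[1]),
        phen_f=ctx.phen_f, phen_m=ctx.phen_m,
        prevalence_f=eq.prevalence_f, prevalence_m=eq.prevalence_m,
        N=eq.N, equilibrium_kind=eq.kind, status=status,
        certificate=float(certificate), iterations=iterations,
        convergence_stable=conv,
    )


def find_ess_multistart(
    params: ParameterSet,
    model_f: TradeoffModel,
    model_m: TradeoffModel,
    inits: tuple[tuple[float, float], ...] = (
        (0.5, 0.5), (0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)),
    tol: float = 1e-4,
    **kwargs,
) -> list[ESSResult]:
    """Run :func:`find_ess` from several starting points; distinct fixed
    points (beyond ``tol`` apart) are all returned."""
    found: list[ESSResult] = []
    for init in inits:
        try:
            res = find_ess(params, model_f, model_m, init=init, tol=tol,
                           **kwargs)
        except RuntimeError:
            continue  # e.g. a non-viable starting resident
        if res.status == "not-found":
            continue
        if not any(abs(res.x_f_star - r.x_f_star) < 10 * tol
                   and abs(res.x_m_star - r.x_m_star) < 10 * tol
                   for r in found):
            found.append(res)
    return found


def _result_row(res: ESSResult) -> dict:
    return {
        "x_f_star": res.x_f_star, "x_m_star": res.x_m_star,
        "gamma_f": res.phen_f.gamma, "d_f": res.phen_f.d, "phi_f": res.phen_f.phi,
        "gamma_m": res.phen_m.gamma, "d_m": res.phen_m.d, "phi_m": res.phen_m.phi,
        "prevalence_f": res.prevalence_f, "prevalence_m": res.prevalence_m,
        "N": res.N, "equilibrium": res.equilibrium_kind,
        "status": res.status, "certificate": res.certificate,
    }


def sweep(
    params_base: ParameterSet,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray] | None,
    model_f: TradeoffModel,
    model_m: TradeoffModel | None = None,
    tol: float = 1e-4,
    init: tuple[float, float] = (0.5, 0.5),
    **ess_kwargs,
) -> pd.DataFrame:
    """Tabulate the joint ESS over a 1-D or 2-D parameter grid.

    Each axis is ``(field_name, values)`` where the field name is either a
    :class:`ParameterSet` field or one of the joint aliases ``"beta"`` /
    ``"alpha"`` (which set the female and male values together).  The
    search warm-starts each cell from its neighbour along axis1; cells
    whose search fails are recorded with status "not-found", never
    interpolated.
    """
    model_m = model_m or model_f
    alias = {"beta": ("beta_f", "beta_m"), "alpha": ("alpha_f", "alpha_m")}
    valid = set(ParameterSet().to_dict())

    def apply(params: ParameterSet, name: str, value: float) -> ParameterSet:
        fields = alias.get(name, (name,))
        for f in fields:
            if f not in valid:
                raise KeyError(f"unknown parameter axis {name!r}")
        return params.replace(**{f: float(value) for f in fields})

    name1, grid1 = axis1
    axes2 = [(None, None)] if axis2 is None else [(axis2[0], v) for v in axis2[1]]
    rows = []
    for name2, v2 in axes2:
        prev_init = init
        for v1 in np.asarray(grid1, dtype=float):
            p = apply(params_base, name1, v1)
            if name2 is not None:
                p = apply(p, name2, v2)
            row = {name1: float(v1)}
            if name2 is not None:
                row[name2] = float(v2)
            try:
                res = find_ess(p, model_f, model_m, init=prev_init, tol=tol,
                               **ess_kwargs)
                row.update(_result_row(res))
                if res.status in ("interior-ESS", "boundary"):
                    prev_init = (res.x_f_star, res.x_m_star)
            except RuntimeError as exc:
                row.update({"status": "failed", "error": str(exc)})
            rows.append(row)
    return pd.DataFrame(rows)
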