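"""Brute-force validation of the eigenvalue invasion criterion.

Instead of linearizing, this module integrates the full nonlinear
genotype-resolved system with the mutant allele segregating (three
genotypes at the mutated locus × the monomorphic other locus × two sexes
× two compartments = 12 equations), starting from the resident
equilibrium perturbed by rare mutant heterozygotes.  The verdict — mutant
allele frequency grows, declines or stays neutral — is read off the slope
of log frequency, and should agree in sign with the dominant eigenvalue
of the linearized mutant subsystem whenever selection is not vanishingly
weak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .ecodynamics import EXTINCTION_DENSITY, derivatives, resident_equilibrium
from .genetics import (Allele, FEMALE_LOCUS, GenotypeSpace, PhenotypeTable,
                       offspring_tensor)
from .params import ParameterSet
from .tradeoffs import TradeoffModel, phenotype_of

__all__ = ["PolymorphicRun", "simulate_invasion", "mutant_allele_frequency",
           "SLOPE_NEUTRAL"]

#: |slope of log mutant frequency| below this (per unit time) is neutral
SLOPE_NEUTRAL = 1e-4


@dataclass
class PolymorphicRun:
    """Trajectory summary of one rare-mutant introduction."""

    space: GenotypeSpace
    locus: int
    times: np.ndarray
    frequencies: np.ndarray
    verdict: str  # "grew" | "declined" | "neutral" | "extinct"
    slope: float

    @property
    def initial_frequency(self) -> float:
        return float(self.frequencies[0])


def mutant_allele_frequency(state: np.ndarray, space: GenotypeSpace,
                            locus: int, mutant_value: float) -> float:
    """Density-weighted frequency of the mutant allele at ``locus``."""
    Y = np.asarray(state, dtype=float).reshape(-1, 4)
    totals = Y.sum(axis=1)
    if totals.sum() <= 0:
        return 0.0
    counts = np.empty(space.n)
    for i, g in enumerate(space.genotypes):
        pair = g.female_pair if locus == FEMALE_LOCUS else g.male_pair
        counts[i] = sum(1 for a in pair if a == mutant_value) / 2.0
    return float((counts * totals).sum() / totals.sum())


def simulate_invasion(
    resident: tuple[float, float],
    mutant: Allele,
    params: ParameterSet,
    model_f: TradeoffModel,
    model_m: TradeoffModel,
    freq0: float = 1e-6,
    horizon: float = 2000.0,
    n_chunks: int = 40,
    decisive_log_change: float = 3.0,
) -> PolymorphicRun:
    """Introduce a rare mutant and watch its allele frequency.

    The run starts from the resident's ecological equilibrium with a
    fraction ``2·freq0`` of each resident compartment converted to mutant
    heterozygotes (allele frequency ``freq0``; mutant homozygotes start at
    zero, being second order in rarity).  Integration exits early once the
    log frequency has moved by ``decisive_log_change``.  The verdict comes
    from the log-frequency slope over the final third of the recorded
    trajectory.
    """
    if freq0 > 1e-4:
        raise ValueError("freq0 must be <= 1e-4 (the mutant must be rare)")
    x_f, x_m = resident
    res_value = x_f if mutant.locus == FEMALE_LOCUS else x_m
    if mutant.value == res_value:
        # identical alleles: the 'mutant' is indistinguishable, frequency
        # is constant by construction; short-circuit to a neutral run
        times = np.array([0.0, horizon])
        freqs = np.array([freq0, freq0])
        return PolymorphicRun(
            space=GenotypeSpace([x_f], [x_m]), locus=mutant.locus,
            times=times, frequencies=freqs, verdict="neutral", slope=0.0)

    phen_f = phenotype_of(x_f, model_f, params)
    phen_m = phenotype_of(x_m, model_m, params)
    eq = resident_equilibrium(params, phen_f, phen_m)
    if eq.kind == "extinct" or not eq.converged:
        raise RuntimeError("resident equilibrium unavailable for oracle run")

    if mutant.locus == FEMALE_LOCUS:
        space = GenotypeSpace([x_f, mutant.value], [x_m])
    else:
        space = GenotypeSpace([x_f], [x_m, mutant.value])
    table = PhenotypeTable.build(space, model_f, model_m, params)
    delta = offspring_tensor(space)

    from .genetics import Genotype
    res_pair_f = (x_f, x_f)
    res_pair_m = (x_m, x_m)
    if mutant.locus == FEMALE_LOCUS:
        het = Genotype((x_f, mutant.value), res_pair_m)
    else:
        het = Genotype(res_pair_f, (x_m, mutant.value))
    i_res = space.index_of(Genotype(res_pair_f, res_pair_m))
    i_het = space.index_of(het)

    Y0 = np.zeros((space.n, 4))
    Y0[i_res] = eq.state[0] * (1.0 - 2.0 * freq0)
    Y0[i_het] = eq.state[0] * 2.0 * freq0

    def rhs(t, y):
        return derivatives(np.clip(y, 0.0, None), params, table, delta)

    times = [0.0]
    freqs = [mutant_allele_frequency(Y0, space, mutant.locus, mutant.value)]
    y = Y0.ravel().copy()
    t = 0.0
    chunk = horizon / n_chunks
    verdict = None
    decisive = False
    log_f0 = np.log(freqs[0])
    while t < horizon:
        sol = solve_ivp(rhs, (0.0, chunk), y, method="LSODA",
                        rtol=1e-9, atol=1e-14)
        if not sol.success:
            break
        y = np.clip(sol.y[:, -1], 0.0, None)
        t += chunk
        if y.sum() < EXTINCTION_DENSITY:
            verdict = "extinct"
            break
        f = mutant_allele_frequency(y, space, mutant.locus, mutant.value)
        times.append(t)
        freqs.append(f)
        if f <= 0:
            break
        if abs(np.log(f) - log_f0) > decisive_log_change:
            decisive = True
            break

    times_arr = np.array(times)
    freqs_arr = np.array(freqs)
    if verdict is None:
        pos = freqs_arr > 0
        tt, ff = times_arr[pos], np.log(freqs_arr[pos])
        if pos.sum() < 2:
            verdict, slope = "declined", -np.inf
        elif decisive:
            # early exit on a >= e^3-fold move: sign of the overall change
            slope = float((ff[-1] - ff[0]) / (tt[-1] - tt[0]))
            verdict = "grew" if slope > 0 else "declined"
        else:
            n_tail = max(3, len(tt) // 3)
            if len(tt) < 3:
                slope = float((ff[-1] - ff[0]) / (tt[-1] - tt[0]))
            else:
                slope = float(np.polyfit(tt[-n_tail:], ff[-n_tail:], 1)[0])
            if slope > SLOPE_NEUTRAL:
                verdict = "grew"
            elif slope < -SLOPE_NEUTRAL:
                verdict = "declined"
            else:
                verdict = "neutral"
    else:
        slope = -np.inf
    return PolymorphicRun(space=space, locus=mutant.locus, times=times_arr,
                          frequencies=freqs_arr, verdict=verdict, slope=slope)
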