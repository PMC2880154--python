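"""Diploid two-locus genetics with sex-limited expression.

Both sexes carry two autosomal loci.  The pair of alleles at the female
locus determines the proxy trait x_f expressed in females only; the male
locus likewise determines x_m expressed in males only.  Allele effects are
additive, so a heterozygote's trait is the arithmetic mean of the two
allele values.  Inheritance is Mendelian with free recombination (no
linkage disequilibrium).

Reproduction follows Bateman's principle: total births are limited by
female fecundity (density dependent), while males compete for access to
females so a male genotype's share of paternity equals its relative
effective reproductive weight.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .params import ParameterSet
from .tradeoffs import TradeoffModel, phenotype_of

__all__ = [
    "FEMALE_LOCUS", "MALE_LOCUS", "Allele", "Genotype", "GenotypeSpace",
    "OffspringDistribution", "PhenotypeTable", "genotype_trait",
    "mendelian_offspring", "offspring_tensor", "birth_rates",
    "DegeneratePopulationError",
]

FEMALE_LOCUS = 0
MALE_LOCUS = 1

# state-column layout used throughout: [S_f, I_f, S_m, I_m] per genotype
S_F, I_F, S_M, I_M = 0, 1, 2, 3


class DegeneratePopulationError(RuntimeError):
    """Raised when births are requested from a population with effective
    females present but zero total effective male reproductive weight."""


@dataclass(frozen=True)
class Allele:
    """One allele: which locus it sits at and its additive trait value."""

    locus: int
    value: float

    def __post_init__(self) -> None:
        if self.locus not in (FEMALE_LOCUS, MALE_LOCUS):
            raise ValueError("locus must be FEMALE_LOCUS (0) or MALE_LOCUS (1)")
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"allele value {self.value} outside (0, 1)")


def _as_pair(pair: Iterable[float]) -> tuple[float, float]:
    a, b = sorted(pair)
    return (float(a), float(b))


@dataclass(frozen=True)
class Genotype:
    """Unordered allele pairs at the female and male loci."""

    female_pair: tuple[float, float]
    male_pair: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "female_pair", _as_pair(self.female_pair))
        object.__setattr__(self, "male_pair", _as_pair(self.male_pair))


def genotype_trait(g: Genotype, sex: str) -> float:
    """Expressed proxy trait of genotype ``g`` in an individual of ``sex``.

    Sex-limited expression: a female expresses the mean of her female-locus
    pair, a male the mean of his male-locus pair; the other locus is
    carried but silent.
    """
    if sex == "female":
        pair = g.female_pair
    elif sex == "male":
        pair = g.male_pair
    else:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    return 0.5 * (pair[0] + pair[1])


class GenotypeSpace:
    """Enumeration of all diploid genotypes over fixed allele sets.

    With n1 alleles at the female locus and n2 at the male locus the space
    holds n1(n1+1)/2 × n2(n2+1)/2 unordered genotypes, indexed densely.
    """

    def __init__(self, female_alleles: Sequence[float],
                 male_alleles: Sequence[float]) -> None:
        self.female_alleles = tuple(sorted(set(float(a) for a in female_alleles)))
        self.male_alleles = tuple(sorted(set(float(a) for a in male_alleles)))
        if not self.female_alleles or not self.male_alleles:
            raise ValueError("need at least one allele per locus")
        f_pairs = list(itertools.combinations_with_replacement(self.female_alleles, 2))
        m_pairs = list(itertools.combinations_with_replacement(self.male_alleles, 2))
        self.genotypes: tuple[Genotype, ...] = tuple(
            Genotype(fp, mp) for fp in f_pairs for mp in m_pairs
        )
        self.index: dict[Genotype, int] = {g: i for i, g in enumerate(self.genotypes)}

    @property
    def n(self) -> int:
        return len(self.genotypes)

    def index_of(self, g: Genotype) -> int:
        try:
            return self.index[g]
        except KeyError:
            raise ValueError(f"genotype {g} not in this genotype space") from None

    def trait_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_f, x_m) expressed trait per genotype, as arrays of length n."""
        x_f = np.array([genotype_trait(g, "female") for g in self.genotypes])
        x_m = np.array([genotype_trait(g, "male") for g in self.genotypes])
        return x_f, x_m


@dataclass
class OffspringDistribution:
    """Genotype distribution of offspring from one (mother, father) cross."""

    space: GenotypeSpace
    proportions: np.ndarray

    def as_dict(self) -> dict[Genotype, float]:
        return {g: float(p) for g, p in zip(self.space.genotypes, self.proportions)
                if p > 0.0}

    def __getitem__(self, g: Genotype) -> float:
        return float(self.proportions[self.space.index_of(g)])


def _gametes(pair: tuple[float, float]) -> dict[float, float]:
    """Allele → probability transmitted (1/2 each; merged if homozygous)."""
    out: dict[float, float] = {}
    for a in pair:
        out[a] = out.get(a, 0.0) + 0.5
    return out


def _pair_distribution(mother_pair, father_pair) -> dict[tuple[float, float], float]:
    dist: dict[tuple[float, float], float] = {}
    for am, pm in _gametes(mother_pair).items():
        for af, pf in _gametes(father_pair).items():
            key = _as_pair((am, af))
            dist[key] = dist.get(key, 0.0) + pm * pf
    return dist


def mendelian_offspring(mother: Genotype, father: Genotype,
                        space: GenotypeSpace) -> OffspringDistribution:
    """Offspring genotype proportions δ for a fixed (mother, father) pair.

    Each parent transmits one allele per locus with probability 1/2,
    independently across loci (free recombination); e.g. a heterozygote ×
    heterozygote cross at one locus yields 1/4 : 1/2 : 1/4.
    """
    probs = np.zeros(space.n)
    f_dist = _pair_distribution(mother.female_pair, father.female_pair)
    m_dist = _pair_distribution(mother.male_pair, father.male_pair)
    for fp, pf in f_dist.items():
        for mp, pm in m_dist.items():
            probs[space.index_of(Genotype(fp, mp))] += pf * pm
    return OffspringDistribution(space=space, proportions=probs)


def offspring_tensor(space: GenotypeSpace) -> np.ndarray:
    """δ[i, j, k]: proportion of offspring genotype i from mother j, father k."""
    n = space.n
    delta = np.zeros((n, n, n))
    for j, mother in enumerate(space.genotypes):
        for k, father in enumerate(space.genotypes):
            delta[:, j, k] = mendelian_offspring(mother, father, space).proportions
    return delta


@dataclass
class PhenotypeTable:
    """Per-genotype expressed phenotypes for each sex, as dense arrays."""

    d_f: np.ndarray
    gamma_f: np.ndarray
    phi_f: np.ndarray
    d_m: np.ndarray
    gamma_m: np.ndarray
    phi_m: np.ndarray

    @property
    def n(self) -> int:
        return len(self.d_f)

    @classmethod
    def build(cls, space: GenotypeSpace, model_f: TradeoffModel,
              model_m: TradeoffModel, params: ParameterSet) -> "PhenotypeTable":
        x_f, x_m = space.trait_arrays()
        ph_f = [phenotype_of(x, model_f, params) for x in x_f]
        ph_m = [phenotype_of(x, model_m, params) for x in x_m]
        return cls(
            d_f=np.array([p.d for p in ph_f]),
            gamma_f=np.array([p.gamma for p in ph_f]),
            phi_f=np.array([p.phi for p in ph_f]),
            d_m=np.array([p.d for p in ph_m]),
            gamma_m=np.array([p.gamma for p in ph_m]),
            phi_m=np.array([p.phi for p in ph_m]),
        )


def birth_rates(state: np.ndarray, params: ParameterSet,
                phenotypes: PhenotypeTable, delta: np.ndarray) -> np.ndarray:
    """Birth rate B_i of each offspring genotype (both sexes combined).

    B_i = b(1 − qN) Σ_j Σ_k δ_{i,j,k} F_j (M_k / Σ_u M_u), where
    F_j = S_f^j + φ_f^j I_f^j is the effective fecund female density and
    M_k = S_m^k + φ_m^k I_m^k the effective male reproductive weight.  The
    density-dependence factor is clamped at zero above carrying density.

    Raises :class:`DegeneratePopulationError` if effective females are
    present but every male weight is zero (no fathers available).
    """
    Y = np.asarray(state, dtype=float).reshape(-1, 4)
    if Y.shape[0] != phenotypes.n:
        raise ValueError("state and phenotype table disagree on genotype count")
    N = Y.sum()
    F = Y[:, S_F] + phenotypes.phi_f * Y[:, I_F]
    M = Y[:, S_M] + phenotypes.phi_m * Y[:, I_M]
    M_sum = M.sum()
    fac = params.b * max(1.0 - params.q * N, 0.0)
    if M_sum <= 0.0:
        if fac > 0.0 and F.sum() > 0.0:
            raise DegeneratePopulationError(
                "effective females present but total male reproductive weight is zero"
            )
        return np.zeros(phenotypes.n)
    return fac * np.einsum("ijk,j,k->i", delta, F, M / M_sum)
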