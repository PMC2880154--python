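"""Genotype-to-phenotype mapping under immunity / life-history trade-offs.

A single proxy trait ``x`` in (0, 1) per sex controls a pair of phenotypic
traits through one of three trade-off models:

* model (i)   — resistance with a constitutive cost: recovery rate γ and
  background death rate d both increase with x; fecundity during infection
  φ stays at its baseline.
* model (ii)  — tolerance with a constitutive cost: relative fecundity
  during infection φ and background death rate d both increase with x;
  recovery stays at its baseline γ₀.
* model (iii) — resistance with a facultative cost: recovery rate γ
  increases while fecundity during infection φ decreases with x; the
  background death rate stays at d₀.

The default shapes for the constitutive-cost models (i) and (ii) are

    Γ(x) = γ₀ · x / (1 − x)        (anchored so Γ(1/2) = γ₀)
    D(x) = d₀ / (1 − x²)           (≈ d₀ at small x, diverging as x → 1)
    Φ(x) = x                        (tolerance benefit, model ii)

chosen so that the cost accelerates in the benefit, which is what allows
interior evolutionarily stable strategies to exist.  Model (iii) needs a
different balance: because its cost is facultative (paid only while
infected), both the benefit and the cost of resistance scale with the
force of infection, and an unbounded, accelerating recovery benefit such
as Γ above makes ever-higher resistance asymptotically free — selection
then drives the pathogen extinct and the trait goes neutral.  Its
defaults are therefore a saturating benefit and an accelerating cost,

    Γ₃(x) = γ₀ · √(2x)             (anchored so Γ₃(1/2) = γ₀)
    Ψ(x) = 1 − x²                   (fecundity cost, model iii)

which admit interior ESSs with an endemic pathogen across the default
parameter ranges.  Alternative shapes plug in through the callables on
:class:`TradeoffModel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .params import ParameterSet

__all__ = ["Phenotype", "TradeoffModel", "tradeoff_model", "phenotype_of",
           "sex_phenotypes"]

ShapeFn = Callable[[float, ParameterSet], float]


@dataclass(frozen=True)
class Phenotype:
    """Expressed life-history traits of one sex of one genotype.

    d: background death rate (> 0); gamma: recovery rate (>= 0);
    phi: relative fecundity during infection, in [0, 1].
    """

    d: float
    gamma: float
    phi: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("death rate d must be positive")
        if self.gamma < 0:
            raise ValueError("recovery rate gamma must be non-negative")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")


def _gamma_default(x: float, p: ParameterSet) -> float:
    return p.gamma0 * x / (1.0 - x)


def _d_default(x: float, p: ParameterSet) -> float:
    return p.d0 / (1.0 - x * x)


def _phi_increasing(x: float, p: ParameterSet) -> float:
    return x


def _gamma_saturating(x: float, p: ParameterSet) -> float:
    return p.gamma0 * (2.0 * x) ** 0.5


def _phi_decreasing(x: float, p: ParameterSet) -> float:
    return 1.0 - x * x


@dataclass(frozen=True)
class TradeoffModel:
    """A mapping from the proxy trait x to (d, γ, φ).

    ``kind`` selects one of the built-in models ("i", "ii", "iii"); any of
    the three shape callables may be overridden to explore alternative
    trade-off families (including test-only degenerate ones).  A callable
    left as ``None`` falls back to the model's default for that trait.
    """

    kind: str
    gamma: Optional[ShapeFn] = None
    d: Optional[ShapeFn] = None
    phi: Optional[ShapeFn] = None

    def __post_init__(self) -> None:
        if self.kind not in ("i", "ii", "iii", "custom"):
            raise ValueError(f"unknown trade-off kind {self.kind!r}")


def tradeoff_model(kind: str, **shapes: ShapeFn) -> TradeoffModel:
    """Convenience constructor: ``tradeoff_model("i")`` etc."""
    return TradeoffModel(kind=kind, **shapes)


def phenotype_of(x: float, model: TradeoffModel, params: ParameterSet) -> Phenotype:
    """Phenotype of an individual with proxy trait ``x`` under ``model``.

    Raises ``ValueError`` for x outside the open interval (0, 1).
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"trait x={x} outside the open interval (0, 1)")
    kind = model.kind
    if kind == "i":
        gamma_fn = model.gamma or _gamma_default
        d_fn = model.d or _d_default
        phi_fn = model.phi or (lambda x, p: p.phi0)
    elif kind == "ii":
        gamma_fn = model.gamma or (lambda x, p: p.gamma0)
        d_fn = model.d or _d_default
        phi_fn = model.phi or _phi_increasing
    elif kind == "iii":
        gamma_fn = model.gamma or _gamma_saturating
        d_fn = model.d or (lambda x, p: p.d0)
        phi_fn = model.phi or _phi_decreasing
    else:  # custom: default to baselines for anything not supplied
        gamma_fn = model.gamma or (lambda x, p: p.gamma0)
        d_fn = model.d or (lambda x, p: p.d0)
        phi_fn = model.phi or (lambda x, p: p.phi0)
    return Phenotype(d=d_fn(x, params), gamma=gamma_fn(x, params),
                     phi=phi_fn(x, params))


def sex_phenotypes(
    x_f: float,
    x_m: float,
    model_f: TradeoffModel,
    model_m: TradeoffModel,
    params: ParameterSet,
) -> tuple[Phenotype, Phenotype]:
    """Female and male phenotypes from sex-specific traits and trade-offs.

    Passing the same model for both sexes gives the main setting in which
    both sexes obey identical trade-off functions; distinct models express
    built-in (genetic) differences between the sexes.
    """
    return (phenotype_of(x_f, model_f, params),
            phenotype_of(x_m, model_m, params))
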