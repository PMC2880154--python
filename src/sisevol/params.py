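"""Ecological and epidemiological parameters.

All rates are per unit time, densities in arbitrary units.  The defaults
describe a host population regulated by density-dependent fecundity
(logistic-like), exposed to a directly transmitted pathogen with
density-dependent (mass action) transmission and no acquired immunity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ParameterSet"]


@dataclass(frozen=True)
class ParameterSet:
    """Non-evolving model parameters.

    Attributes
    ----------
    b : maximum female fecundity (births per female per unit time at zero
        density).
    q : density-dependent reduction in fecundity; births scale with
        ``1 - q N`` where ``N`` is total host density.
    d0 : baseline natural death rate (both sexes).
    gamma0 : baseline recovery rate.
    beta_f, beta_m : sex-specific infection (transmission) rates.
    alpha_f, alpha_m : sex-specific virulence, i.e. disease-induced
        additional death rates.
    phi0 : baseline relative fecundity / reproductive success during
        infection (1 = no fecundity loss).
    """

    b: float = 1.0
    q: float = 0.01
    d0: float = 0.25
    gamma0: float = 2.0
    beta_f: float = 0.2
    beta_m: float = 0.2
    alpha_f: float = 0.75
    alpha_m: float = 0.75
    phi0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b", "q", "d0", "gamma0", "beta_f", "beta_m",
                     "alpha_f", "alpha_m", "phi0"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if not 0.0 <= self.phi0 <= 1.0:
            raise ValueError("phi0 must lie in [0, 1]")

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ParameterSet":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        """Load parameters from a flat ``key: value`` YAML file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)
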