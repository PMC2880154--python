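"""Scripted reproductions of the headline ESS surfaces.

Three experiments mirror the model's main analyses:

* :func:`figure2_sweep` — no extrinsic sex differences: joint sweeps of
  susceptibility β or virulence α with both sexes equal, tracking the
  (identical) ESS of both sexes.
* :func:`figure3_surface` — sex-specific susceptibility: the joint ESS on
  a (β_f, β_m) grid, with sex-specific prevalence and the region where
  female immunocompetence exceeds male; for model (i) the 50 %
  male-prevalence crossing along each β_m column is located.
* :func:`figure4_surface` — sex-specific virulence: as above on an
  (α_f, α_m) grid.

All grids default to a reduced 8×8 resolution so a full surface completes
on one CPU in minutes; resolutions are configurable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ess_search import sweep
from .params import ParameterSet
from .tradeoffs import TradeoffModel, tradeoff_model

__all__ = ["figure2_sweep", "figure3_surface", "figure4_surface",
           "immunocompetence_column", "write_outputs",
           "DEFAULT_BETA_RANGE", "DEFAULT_ALPHA_RANGE"]

DEFAULT_BETA_RANGE = (0.05, 0.4)
DEFAULT_ALPHA_RANGE = (0.2, 2.0)


def _model(model: str | TradeoffModel) -> TradeoffModel:
    return model if isinstance(model, TradeoffModel) else tradeoff_model(model)


def immunocompetence_column(kind: str) -> str:
    """Which ESS trait measures immunocompetence for each trade-off model.

    Models (i) and (iii) evolve the recovery rate γ (resistance); model
    (ii) evolves the relative fecundity during infection φ (tolerance).
    """
    return {"i": "gamma", "ii": "phi", "iii": "gamma"}[kind]


def figure2_sweep(
    model: str | TradeoffModel,
    axis: str = "beta",
    grid: np.ndarray | None = None,
    params: ParameterSet | None = None,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """ESS traits along a joint (sex-symmetric) β or α sweep.

    With all extrinsic parameters equal between the sexes the two loci
    evolve to identical trait values; the per-cell column ``symmetric``
    records that |x_f* − x_m*| < 10·tol as a sanity flag.
    """
    if axis not in ("beta", "alpha"):
        raise ValueError("axis must be 'beta' or 'alpha'")
    m = _model(model)
    params = params or ParameterSet()
    if grid is None:
        rng = DEFAULT_BETA_RANGE if axis == "beta" else DEFAULT_ALPHA_RANGE
        grid = np.linspace(*rng, 8)
    df = sweep(params, (axis, np.asarray(grid)), None, m, tol=tol)
    df.insert(0, "model", m.kind)
    df["symmetric"] = (df["x_f_star"] - df["x_m_star"]).abs() < 10 * tol
    return df


def _surface(model: TradeoffModel, name_f: str, name_m: str,
             grid_f: np.ndarray, grid_m: np.ndarray,
             params: ParameterSet, tol: float) -> pd.DataFrame:
    df = sweep(params, (name_f, np.asarray(grid_f)),
               (name_m, np.asarray(grid_m)), model, tol=tol)
    df.insert(0, "model", model.kind)
    trait = immunocompetence_column(model.kind)
    df["female_exceeds_male"] = df[f"{trait}_f"] > df[f"{trait}_m"]
    return df


def _male_prevalence_crossing(df: pd.DataFrame, by: str, along: str,
                              level: float = 0.5) -> pd.DataFrame:
    """Locate where male prevalence crosses ``level`` along each column."""
    rows = []
    for key, sub in df.groupby(by):
        sub = sub.sort_values(along)
        prev = sub["prevalence_m"].to_numpy()
        axis = sub[along].to_numpy()
        crossing = np.nan
        for a, b, pa, pb in zip(axis[:-1], axis[1:], prev[:-1], prev[1:]):
            if (pa - level) * (pb - level) <= 0 and pa != pb:
                crossing = a + (level - pa) * (b - a) / (pb - pa)
                break
        rows.append({by: key, f"{along}_at_male_prevalence_{level:g}": crossing})
    return pd.DataFrame(rows)


def figure3_surface(
    model: str | TradeoffModel,
    beta_f_grid: np.ndarray | None = None,
    beta_m_grid: np.ndarray | None = None,
    params: ParameterSet | None = None,
    tol: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Joint ESS over a (β_f, β_m) grid.

    Returns the per-cell table and, for model (i), the 50 % male-prevalence
    crossing of β_m within each β_f column (the prevalence feedback that
    turns the ES male recovery rate around); ``None`` otherwise.
    """
    m = _model(model)
    params = params or ParameterSet()
    if beta_f_grid is None:
        beta_f_grid = np.linspace(*DEFAULT_BETA_RANGE, 8)
    if beta_m_grid is None:
        beta_m_grid = np.linspace(*DEFAULT_BETA_RANGE, 8)
    df = _surface(m, "beta_f", "beta_m", beta_f_grid, beta_m_grid, params, tol)
    crossings = None
    if m.kind == "i":
        crossings = _male_prevalence_crossing(df, by="beta_f", along="beta_m")
    return df, crossings


def figure4_surface(
    model: str | TradeoffModel,
    alpha_f_grid: np.ndarray | None = None,
    alpha_m_grid: np.ndarray | None = None,
    params: ParameterSet | None = None,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Joint ESS over an (α_f, α_m) grid."""
    m = _model(model)
    params = params or ParameterSet()
    if alpha_f_grid is None:
        alpha_f_grid = np.linspace(*DEFAULT_ALPHA_RANGE, 8)
    if alpha_m_grid is None:
        alpha_m_grid = np.linspace(*DEFAULT_ALPHA_RANGE, 8)
    return _surface(m, "alpha_f", "alpha_m", alpha_f_grid, alpha_m_grid,
                    params, tol)


def write_outputs(df: pd.DataFrame, out_dir: str | Path, name: str,
                  config: dict | None = None) -> Path:
    """Write a results table plus a JSON run manifest; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    config = dict(config or {})
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"name": name, "config": config, "config_sha256": digest,
                "rows": int(len(df))}
    with open(out_dir / f"{name}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return csv_path
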