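"""Parameter sweeps and tidy tabular outputs.

A sweep varies one scaled parameter over a grid, re-solving the
equilibrium and the triggering chain at every point, and returns a tidy
DataFrame: one row per grid point, columns for all inputs plus the free
densities, occupancy fractions, triggering probabilities, functional
sensitivity w and the solver residual.  CSV output carries a provenance
header (parameter hash, seed, version) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import __version__
from .degeneracy import EnergyEnsemble, degeneracy_curve
from .dimensional import apply_mutant, mutant_scenarios
from .params import ScaledParameters
from .triggering import triggering_rate

__all__ = [
    "parse_grid",
    "run_sweep",
    "write_csv",
    "params_hash",
    "find_sensitivity_minimum",
    "mutant_degeneracy_curves",
]

SWEEPABLE = ("m_T", "x_T", "r_T", "alpha", "delta", "nu", "kappa",
             "gamma_off", "gamma_kin", "gamma_R")


def parse_grid(spec: str, log: bool = False) -> np.ndarray:
    """Parse ``start:stop:count`` into an inclusive grid (log-spaced if asked)."""
    try:
        start_s, stop_s, count_s = spec.split(":")
        start, stop, count = float(start_s), float(stop_s), int(count_s)
    except ValueError as exc:
        raise ValueError(f"grid must be 'start:stop:count', got {spec!r}") from exc
    if count < 1:
        raise ValueError(f"grid count must be >= 1, got {count}")
    if count == 1:
        return np.array([start])
    if log:
        if start <= 0 or stop <= 0:
            raise ValueError("log grids need positive endpoints")
        return np.geomspace(start, stop, count)
    return np.linspace(start, stop, count)


def run_sweep(
    params: ScaledParameters, var: str, grid: np.ndarray | str, log: bool = False
) -> pd.DataFrame:
    """Evaluate the model along a one-parameter grid.

    ``var`` is any scaled parameter name; ``grid`` is either an array or a
    ``start:stop:count`` string.
    """
    if var not in SWEEPABLE:
        raise ValueError(f"unknown sweep variable {var!r}; one of {SWEEPABLE}")
    if isinstance(grid, str):
        grid = parse_grid(grid, log=log)
    rows = []
    for value in np.asarray(grid, dtype=float):
        p = params.replace(**{var: float(value)})
        res = triggering_rate(p)
        eq = res.equilibrium
        row = p.model_dump()
        row.update(
            x=eq.x, r=eq.r, eps=eq.eps, zeta=eq.zeta,
            P00=res.P00, P0_star=res.P0_star, w=res.w, residual=eq.residual,
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["sweep_var"] = var
    return df


def find_sensitivity_minimum(
    params: ScaledParameters,
    var: str = "x_T",
    lo: float = 1.0,
    hi: float = 200.0,
    points: int = 400,
) -> tuple[float, float]:
    """Locate the interior minimum of w along one parameter.

    Profiles w on a ``points``-point linear grid over [lo, hi], then
    refines the bracketing interval around the grid argmin by
    golden-section search.  Returns ``(argmin, w_min)``.
    """
    grid = np.linspace(lo, hi, points)
    w = np.array([
        triggering_rate(params.replace(**{var: float(v)})).w for v in grid
    ])
    k = int(np.argmin(w))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, points - 1)]

    def objective(v: float) -> float:
        return triggering_rate(params.replace(**{var: float(v)})).w

    res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x), float(res.fun)


def mutant_degeneracy_curves(
    base: ScaledParameters,
    ens: EnergyEnsemble,
    omega_grid: np.ndarray | None = None,
    reference: str = "wild-type",
) -> pd.DataFrame:
    """Degeneracy curves for the built-in CD8-affinity variant panel.

    The base parameter set is taken as the reference variant; each mutant
    rescales kappa, x_T and nu via its K_D ratio.  Returns a long-format
    frame (name, K_D, rho, omega, prob).
    """
    frames = []
    for scen in mutant_scenarios(reference=reference):
        p = apply_mutant(base, scen)
        curve = degeneracy_curve(p, ens, omega_grid)
        f = curve.to_frame()
        f.insert(0, "name", scen.name)
        f.insert(1, "K_D", scen.K_D)
        f.insert(2, "rho", scen.rho)
        frames.append(f)
        if omega_grid is None:
            # share one omega grid across the panel so curves are comparable
            omega_grid = curve.omega_grid
    return pd.concat(frames, ignore_index=True)


def params_hash(params: ScaledParameters) -> str:
    """Short stable hash of a parameter set, for provenance headers."""
    blob = json.dumps(params.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    params: ScaledParameters | None = None,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Write a tidy CSV with a ``#``-prefixed provenance header."""
    path = Path(path)
    meta = {"tcrtrigger_version": __version__}
    if params is not None:
        meta["params_hash"] = params_hash(params)
        meta["params"] = json.dumps(params.model_dump(), sort_keys=True)
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra or {})
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (provenance lines skipped)."""
    return pd.read_csv(path, comment="#")
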