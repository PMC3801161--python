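"""Degeneracy statistics of TCR recognition over random ligand ensembles.

A TCR's degeneracy is quantified as the probability that its scaled
functional sensitivity w to a randomly drawn ligand exceeds a threshold
omega.  The ligand ensemble arises from an Arrhenius model of the
TCR/pMHCI dwell time: the dissociation energy barrier is the sum of many
interfacial contributions and is therefore Gaussian, which makes the
scaled off-rate alpha = exp(-u) log-normal, with u ~ N(-mu, sigma^2) and
hence ln(alpha) ~ N(mu, sigma^2).  The mean mu is positive: for the vast
majority of ligands the dwell time falls short of the time needed to
complete the phosphorylation chain.

Because biologically meaningful operating points sit at probabilities as
low as 1e-8, the default method is semi-analytic: w(alpha) is profiled on
a log grid, the super-level set {alpha : w(alpha) > omega} is located by
bracketing and bisection, and its exact Gaussian mass is accumulated.
Monte Carlo sampling is available as an independent cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.optimize import brentq
from scipy.stats import norm

from .equilibrium import solve_equilibrium
from .params import ScaledParameters
from .triggering import w_of_alpha

__all__ = [
    "EnergyEnsemble",
    "DegeneracyCurve",
    "ActivationModel",
    "LigandUniverseSpec",
    "sample_alpha",
    "degeneracy_curve",
    "exceedance_probability",
    "activation_band_scan",
    "ligand_universe_size",
]

#: Points on the log-alpha profiling grid (robustness over speed: w(alpha)
#: is not assumed unimodal, the whole +-8 sigma support is bracketed).
SCAN_POINTS = 400
SCAN_SIGMAS = 8.0


class EnergyEnsemble(BaseModel):
    """Gaussian dissociation-energy model generating log-normal off-rates.

    ``mu`` and ``sigma`` are the mean and standard deviation of ln(alpha),
    in Boltzmann units of dissociation energy.  ``T_0`` (seconds) is the
    Arrhenius frequency factor, only needed to map alpha back to a
    dimensional dwell time; it does not affect the scaled model.
    """

    model_config = ConfigDict(frozen=True)

    mu: float = Field(gt=0.0)
    sigma: float = Field(ge=0.0)
    T_0: float | None = None
    seed: int = 0


def sample_alpha(ens: EnergyEnsemble, count: int) -> np.ndarray:
    """Draw ``count`` scaled off-rates alpha = exp(-u), u ~ N(-mu, sigma^2)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(ens.seed)
    u = rng.normal(loc=-ens.mu, scale=ens.sigma, size=count)
    return np.exp(-u)


@dataclass(frozen=True)
class DegeneracyCurve:
    """Exceedance curve P(w > omega) over a grid of thresholds."""

    omega_grid: np.ndarray
    prob: np.ndarray
    method: Literal["semi_analytic", "monte_carlo"]
    n_samples: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"omega": self.omega_grid, "prob": self.prob, "method": self.method}
        )


def _superlevel_mass(
    t_grid: np.ndarray, w_grid: np.ndarray, omega: float,
    ens: EnergyEnsemble, w_of_t,
) -> float:
    """Gaussian mass (in t = ln alpha) of the set {t : w(exp(t)) > omega}.

    Sign changes of w - omega between grid points are refined by bisection
    to relative 1e-10; a grid endpoint still above omega extends the
    interval into the corresponding Gaussian tail.
    """
    above = w_grid > omega
    if not above.any():
        return 0.0
    cdf = lambda t: norm.cdf(t, loc=ens.mu, scale=ens.sigma)  # noqa: E731
    edges: list[float] = []
    if above[0]:
        edges.append(-np.inf)
    for k in range(len(t_grid) - 1):
        if above[k] != above[k + 1]:
            root = brentq(
                lambda t: w_of_t(t) - omega, t_grid[k], t_grid[k + 1],
                rtol=1e-10, maxiter=200,
            )
            edges.append(root)
    if above[-1]:
        edges.append(np.inf)
    mass = 0.0
    for a, b in zip(edges[::2], edges[1::2]):
        mass += cdf(b) - cdf(a)
    return float(min(max(mass, 0.0), 1.0))


def exceedance_probability(
    params: ScaledParameters,
    ens: EnergyEnsemble,
    omega: float,
    method: Literal["semi_analytic", "monte_carlo"] = "semi_analytic",
    n_samples: int = 100_000,
) -> float:
    """P(w > omega) for a single threshold (see :func:`degeneracy_curve`)."""
    curve = degeneracy_curve(
        params, ens, np.array([omega]), method=method, n_samples=n_samples
    )
    return float(curve.prob[0])


def degeneracy_curve(
    params: ScaledParameters,
    ens: EnergyEnsemble,
    omega_grid: np.ndarray | None = None,
    method: Literal["semi_analytic", "monte_carlo"] = "semi_analytic",
    n_samples: int = 100_000,
) -> DegeneracyCurve:
    """Degeneracy curve P(w > omega) of a parameter set over a ligand ensemble.

    The equilibrium does not depend on alpha and is solved once.  The
    default ``omega_grid`` is 60 log-spaced thresholds spanning
    [1e-4, 10] x max w over the profiled alpha range.

    Parameters
    ----------
    method
        ``semi_analytic`` (default) integrates the exact log-normal mass of
        the super-level sets of w(alpha) and resolves probabilities far
        below any feasible sampling depth; ``monte_carlo`` uses the
        empirical exceedance fraction of ``n_samples`` draws (seeded from
        the ensemble) and serves as an independent cross-check.
    """
    eq = solve_equilibrium(params)
    if ens.sigma == 0.0:
        # Degenerate ensemble: all ligands share alpha = exp(mu).
        w0 = float(w_of_alpha(params, np.array([math.exp(ens.mu)]), eq=eq)[0])
        if omega_grid is None:
            omega_grid = _default_omega_grid(w0 if w0 > 0 else 1.0)
        _validate_grid(omega_grid)
        return DegeneracyCurve(
            omega_grid=np.asarray(omega_grid, dtype=float),
            prob=(w0 > np.asarray(omega_grid)).astype(float),
            method=method,
            n_samples=n_samples if method == "monte_carlo" else None,
        )

    t_grid = np.linspace(
        ens.mu - SCAN_SIGMAS * ens.sigma, ens.mu + SCAN_SIGMAS * ens.sigma,
        SCAN_POINTS,
    )
    w_grid = w_of_alpha(params, np.exp(t_grid), eq=eq)
    if omega_grid is None:
        omega_grid = _default_omega_grid(float(w_grid.max()))
    omega_grid = np.asarray(omega_grid, dtype=float)
    _validate_grid(omega_grid)

    if method == "monte_carlo":
        alphas = sample_alpha(ens, n_samples)
        w_samples = w_of_alpha(params, alphas, eq=eq)
        prob = np.array([(w_samples > om).mean() for om in omega_grid])
        return DegeneracyCurve(omega_grid=omega_grid, prob=prob,
                               method="monte_carlo", n_samples=n_samples)

    def w_of_t(t: float) -> float:
        return float(w_of_alpha(params, np.array([math.exp(t)]), eq=eq)[0])

    prob = np.array([
        1.0 if om <= 0.0 else _superlevel_mass(t_grid, w_grid, om, ens, w_of_t)
        for om in omega_grid
    ])
    return DegeneracyCurve(omega_grid=omega_grid, prob=prob, method="semi_analytic")


def _default_omega_grid(w_max: float) -> np.ndarray:
    return np.geomspace(1e-4 * w_max, 10.0 * w_max, 60)


def _validate_grid(grid: np.ndarray) -> None:
    grid = np.asarray(grid)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("omega_grid must be a nonempty 1-D array")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("omega_grid must be strictly ascending")


class ActivationModel(BaseModel):
    """Cellular activation threshold and operating band.

    A T-cell activates when Z * T_I * w exceeds W_act, where Z is the
    presentation level of the ligand (copies) and T_I the duration of the
    T-cell:APC interaction (s).  The critical scaled sensitivity is
    omega_crit = W_act / (Z * T_I); it may also be supplied directly.
    The operating band [band_lo, band_hi] is the probability range within
    which a repertoire-sized T-cell pool responds to pathogens without
    courting autoimmunity.
    """

    model_config = ConfigDict(frozen=True)

    Z: float | None = Field(default=None, gt=0.0)
    T_I: float | None = Field(default=None, gt=0.0)
    W_act: float | None = Field(default=None, ge=0.0)
    omega_crit: float | None = Field(default=None, ge=0.0)
    band_lo: float = 1e-8
    band_hi: float = 1e-5

    @property
    def critical_omega(self) -> float:
        if self.omega_crit is not None:
            return self.omega_crit
        if self.W_act is None or self.Z is None or self.T_I is None:
            raise ValueError(
                "provide either omega_crit or the triple (Z, T_I, W_act)"
            )
        return self.W_act / (self.Z * self.T_I)

    def model_post_init(self, __context) -> None:
        if self.band_lo >= self.band_hi:
            raise ValueError("band_lo must be below band_hi")


def activation_band_scan(
    act: ActivationModel,
    params: ScaledParameters,
    ens: EnergyEnsemble,
    x_T_grid: np.ndarray,
) -> pd.DataFrame:
    """P(w > omega_crit) across CD8 densities, flagged against the band.

    Recomputes the equilibrium and the semi-analytic exceedance probability
    at each x_T and labels each point ``below``, ``in_band`` or ``above``
    relative to the activation model's operating band.
    """
    x_T_grid = np.asarray(x_T_grid, dtype=float)
    if x_T_grid.size > 1 and np.any(np.diff(x_T_grid) <= 0):
        raise ValueError("x_T_grid must be strictly ascending")
    omega = act.critical_omega
    rows = []
    for x_T in x_T_grid:
        p = exceedance_probability(params.replace(x_T=float(x_T)), ens, omega)
        if p < act.band_lo:
            flag = "below"
        elif p > act.band_hi:
            flag = "above"
        else:
            flag = "in_band"
        rows.append({"x_T": float(x_T), "prob": p, "flag": flag})
    df = pd.DataFrame(rows)
    df.attrs["omega_crit"] = omega
    return df


@dataclass(frozen=True)
class LigandUniverseSpec:
    """Combinatorial description of the effectively distinct ligand universe.

    A peptide of ``n_pep`` residues is anchored to the MHC groove at ``a``
    positions, and the TCR contact region reads ``m`` of the remaining
    residues.
    """

    n_pep: int
    a: int
    m: int

    def __post_init__(self) -> None:
        if self.n_pep < 1 or self.a < 0 or self.m < 0:
            raise ValueError("n_pep >= 1, a >= 0, m >= 0 required")
        if self.m > self.n_pep - self.a:
            raise ValueError(
                f"m = {self.m} exceeds the {self.n_pep - self.a} non-anchor positions"
            )


def ligand_universe_size(spec: LigandUniverseSpec) -> int:
    """Exact count 20^m * C(n_pep - a, m) of effectively distinct ligands.

    Counts the ways to choose which m of the non-anchor positions the TCR
    contacts, times the 20 amino-acid choices at each contacted position.
    """
    if spec.m == 0:
        warnings.warn(
            "m = 0 contacted residues: returning 1 by convention (the model "
            "assumes 0 < m)", UserWarning, stacklevel=2,
        )
    return 20**spec.m * math.comb(spec.n_pep - spec.a, spec.m)
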