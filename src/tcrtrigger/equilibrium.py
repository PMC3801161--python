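"""Equilibrium surface densities of the four-state TCR/pMHCI/CD8 scheme.

A pMHCI molecule in the contact area can be free, bound to TCR only, bound
to CD8 only, or in a ternary TCR/pMHCI/CD8 complex.  With the scaled free
densities x (CD8) and r (TCR), the occupancy fractions of pMHCI share the
common denominator

    D(x, r) = 1 + x + r + x r / gamma_kin,

namely  free: 1/D,  TCR-bound (eps): r/D,  CD8-bound: x/D,  ternary
(zeta): (x r / gamma_kin)/D.  Conservation of CD8 and TCR then yields two
coupled nonlinear equations for (x, r):

    x_T = x + kappa m_T (x + x r/gamma_kin) / D
    r_T = r + m_T (r + x r/gamma_kin) / D

which are solved here by a damped, box-constrained Newton iteration with
analytic Jacobian, falling back to bracketed nested bisection (guaranteed
to converge since each equation is monotone in its own variable).

The equilibrium depends only on (m_T, x_T, r_T, kappa, gamma_kin); the
kinetic parameters alpha, delta, nu, gamma_off, gamma_R and n never enter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ScaledParameters

__all__ = ["EquilibriumState", "solve_equilibrium", "EquilibriumError"]

#: Absolute residual tolerance on both conservation equations.
TOL = 1e-12
MAX_ITER = 200


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


@dataclass(frozen=True)
class EquilibriumState:
    """Scaled free densities and pMHCI occupancy fractions at equilibrium."""

    x: float          # scaled free CD8 density
    r: float          # scaled free TCR density
    eps: float        # fraction of pMHCI in binary TCR/pMHCI complexes (M_R/M_T)
    zeta: float       # fraction of pMHCI in ternary complexes (M_XR/M_T)
    frac_free: float  # fraction of free pMHCI (M/M_T)
    frac_MX: float    # fraction of pMHCI/CD8 binary complexes (M_X/M_T)
    residual: float   # max |residual| of the two conservation equations


def _fractions(x: float, r: float, gamma_kin: float) -> tuple[float, float, float, float]:
    """Occupancy fractions (free, eps, MX, zeta) of pMHCI given free x, r."""
    xr = x * r / gamma_kin
    D = 1.0 + x + r + xr
    return 1.0 / D, r / D, x / D, xr / D


def _residuals(x: float, r: float, p: ScaledParameters) -> tuple[float, float]:
    _, eps, frac_mx, zeta = _fractions(x, r, p.gamma_kin)
    f1 = x + p.kappa * p.m_T * (frac_mx + zeta) - p.x_T
    f2 = r + p.m_T * (eps + zeta) - p.r_T
    return f1, f2


def _jacobian(x: float, r: float, p: ScaledParameters) -> np.ndarray:
    g = p.gamma_kin
    A = x + x * r / g            # numerator of the CD8-bound fractions
    B = r + x * r / g            # numerator of the TCR-bound fractions
    D = 1.0 + x + r + x * r / g
    A_x, A_r = 1.0 + r / g, x / g
    B_x, B_r = r / g, 1.0 + x / g
    D_x, D_r = 1.0 + r / g, 1.0 + x / g
    km, m = p.kappa * p.m_T, p.m_T
    return np.array(
        [
            [1.0 + km * (A_x * D - A * D_x) / D**2, km * (A_r * D - A * D_r) / D**2],
            [m * (B_x * D - B * D_x) / D**2, 1.0 + m * (B_r * D - B * D_r) / D**2],
        ]
    )


def _solve_r_given_x(x: float, p: ScaledParameters) -> float:
    """Solve the TCR conservation equation for r at fixed free CD8 density x."""
    if p.r_T == 0.0:
        return 0.0

    def g(r: float) -> float:
        return _residuals(x, r, p)[1]

    # g(0) = -r_T < 0 and g(r_T) >= 0: the root is bracketed in [0, r_T].
    return brentq(g, 0.0, p.r_T, xtol=1e-15, rtol=8.9e-16, maxiter=300)


def _nested_bisection(p: ScaledParameters) -> tuple[float, float]:
    """Fallback solver: outer root-find on x with inner solve for r."""
    if p.x_T == 0.0:
        return 0.0, _solve_r_given_x(0.0, p)

    def f(x: float) -> float:
        return _residuals(x, _solve_r_given_x(x, p), p)[0]

    x = brentq(f, 0.0, p.x_T, xtol=1e-15, rtol=8.9e-16, maxiter=300)
    return x, _solve_r_given_x(x, p)


def solve_equilibrium(params: ScaledParameters, tol: float = TOL) -> EquilibriumState:
    """Solve the scaled equilibrium system for free CD8 and TCR densities.

    Parameters
    ----------
    params
        Scaled parameter set; only ``m_T``, ``x_T``, ``r_T``, ``kappa`` and
        ``gamma_kin`` are read.
    tol
        Absolute residual tolerance for both conservation equations.

    Returns
    -------
    EquilibriumState
        Free densities, occupancy fractions and the achieved residual.

    Raises
    ------
    EquilibriumError
        If neither Newton iteration nor bracketed bisection reaches the
        requested tolerance.
    """
    p = params

    # Degenerate branches handled exactly.
    if p.m_T == 0.0:
        x, r = p.x_T, p.r_T
    elif p.x_T == 0.0:
        # Single-species binding: r_T = r (1 + m_T/(1 + r)), a quadratic in r.
        b = 1.0 + p.m_T - p.r_T
        r = 0.5 * (-b + math.sqrt(b * b + 4.0 * p.r_T))
        x = 0.0
    elif p.r_T == 0.0:
        # Mirror case: x_T = x (1 + kappa m_T/(1 + x)).
        b = 1.0 + p.kappa * p.m_T - p.x_T
        x = 0.5 * (-b + math.sqrt(b * b + 4.0 * p.x_T))
        r = 0.0
    else:
        x, r = _newton_or_fallback(p, tol)

    frac_free, eps, frac_mx, zeta = _fractions(x, r, p.gamma_kin)
    f1, f2 = _residuals(x, r, p)
    residual = max(abs(f1), abs(f2))
    if residual > tol:
        raise EquilibriumError(
            f"equilibrium residual {residual:.3e} exceeds tol {tol:.1e} for {p!r}"
        )
    return EquilibriumState(
        x=x, r=r, eps=eps, zeta=zeta, frac_free=frac_free, frac_MX=frac_mx,
        residual=residual,
    )


def _newton_or_fallback(p: ScaledParameters, tol: float) -> tuple[float, float]:
    x = min(p.x_T, p.x_T / (1.0 + p.kappa * p.m_T) + 1e-12)
    r = min(p.r_T, p.r_T / (1.0 + p.m_T) + 1e-12)
    f = np.array(_residuals(x, r, p))
    for _ in range(MAX_ITER):
        if max(abs(f[0]), abs(f[1])) < tol:
            return x, r
        try:
            step = np.linalg.solve(_jacobian(x, r, p), -f)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        norm0 = float(np.abs(f).max())
        while lam > 1e-8:
            xn = min(max(x + lam * step[0], 0.0), p.x_T)
            rn = min(max(r + lam * step[1], 0.0), p.r_T)
            fn = np.array(_residuals(xn, rn, p))
            if float(np.abs(fn).max()) < norm0:
                x, r, f = xn, rn, fn
                break
            lam *= 0.5
        else:
            break  # damping exhausted: fall back to bisection
    if max(abs(f[0]), abs(f[1])) < tol:
        return x, r
    return _nested_bisection(p)
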