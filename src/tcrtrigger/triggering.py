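"""Two-lane kinetic proofreading: triggering probabilities and the scaled rate w.

An engaged TCR/CD3 complex progresses through n phosphorylation steps along
one of two lanes — CD8 unbound or CD8 bound — switching lanes as CD8
associates with or dissociates from the pMHCI, and failing when the
TCR/pMHCI bond dissociates.  In units of the basal triggering rate lambda,
the competing rates are

    unbound lane:  forward n,        dissociation alpha,            switch nu*x
    bound lane:    forward n/gamma_R, dissociation gamma_off*alpha, switch delta

The per-state success probabilities P_i^0 (unbound) and P_i^* (bound)
satisfy a coupled backward recursion with boundary P_n^0 = P_n^* = 1; the
scaled triggering rate for a single ligand is

    w = alpha (eps P_0^0 + zeta gamma_off P_0^*),

with eps, zeta the equilibrium fractions of binary and ternary complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import EquilibriumState, solve_equilibrium
from .params import ScaledParameters

__all__ = [
    "ChainStepProbabilities",
    "TriggeringResult",
    "step_probabilities",
    "triggering_probabilities",
    "triggering_rate",
    "w_of_alpha",
]


@dataclass(frozen=True)
class ChainStepProbabilities:
    """Single-step outcome probabilities of the two proofreading lanes.

    In each lane the complement 1 - Pa - Pb is the probability that the
    TCR/pMHCI bond dissociates before anything else happens.
    """

    Pa0: float      # another phosphorylation, CD8 unbound
    Pa_star: float  # another phosphorylation, CD8 bound
    Pb0: float      # lane switch unbound -> bound (CD8 association)
    Pb_star: float  # lane switch bound -> unbound (CD8 dissociation)


@dataclass(frozen=True)
class TriggeringResult:
    """Triggering probabilities and scaled functional sensitivity of a ligand."""

    P00: float                  # triggering probability, docking starts CD8-unbound
    P0_star: float              # triggering probability, docking starts CD8-bound
    w: float                    # scaled TCR triggering rate (functional sensitivity)
    P_chain0: np.ndarray        # P_i^0 for i = 0..n
    P_chain_star: np.ndarray    # P_i^* for i = 0..n
    equilibrium: EquilibriumState


def step_probabilities(params: ScaledParameters, x: float) -> ChainStepProbabilities:
    """Per-step probabilities given the scaled free CD8 density x.

    Each probability is a rate divided by the total rate out of the state:
    in the unbound lane the competing rates (in units of lambda) are the
    forward rate n, the dissociation rate alpha and the CD8-association
    rate nu*x; in the bound lane they are n/gamma_R, gamma_off*alpha and
    the CD8-dissociation rate delta.
    """
    if x < 0:
        raise ValueError(f"free CD8 density must be nonnegative, got {x}")
    p = params
    tot0 = p.alpha + p.n + p.nu * x
    tot_star = p.gamma_off * p.alpha + p.n / p.gamma_R + p.delta
    return ChainStepProbabilities(
        Pa0=p.n / tot0,
        Pb0=p.nu * x / tot0,
        Pa_star=(p.n / p.gamma_R) / tot_star,
        Pb_star=p.delta / tot_star,
    )


def triggering_probabilities(
    steps: ChainStepProbabilities, n: int
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Success probabilities of the two-lane chain by backward recursion.

    Starting from the boundary condition P_n^0 = P_n^* = 1, each backward
    step applies

        (P_{i-1}^0, P_{i-1}^*) =
            [[Pa0, Pb0 Pa*], [Pb* Pa0, Pa*]] (P_i^0, P_i^*) / (1 - Pb0 Pb*)

    (n matrix-vector products; all quantities stay in [0, 1], so the
    iteration is numerically stable and O(n)).

    Returns ``(P00, P0_star, P_chain0, P_chain_star)`` where the chains
    hold P_i for i = 0..n.
    """
    if n < 1:
        raise ValueError(f"chain length n must be >= 1, got {n}")
    s = steps
    denom = 1.0 - s.Pb0 * s.Pb_star
    if denom <= 0.0:
        raise ValueError(
            "degenerate chain: Pb0 * Pb_star >= 1, the complex only switches "
            "lanes and can never progress"
        )
    chain0 = np.empty(n + 1)
    chain_star = np.empty(n + 1)
    chain0[n] = chain_star[n] = 1.0
    if s.Pb0 == 0.0:
        # Single-lane limit (no CD8 association): the unbound lane decouples
        # and P_i^0 = Pa0^(n-i), computed in log space to avoid underflow
        # for large n or large off-rates.
        if s.Pa0 > 0.0:
            exponents = np.arange(n, -1, -1, dtype=float)
            chain0[:] = np.exp(exponents * np.log(s.Pa0))
        else:
            chain0[:n] = 0.0
        ps = 1.0
        for i in range(n - 1, -1, -1):
            ps = s.Pb_star * s.Pa0 * chain0[i + 1] + s.Pa_star * ps
            chain_star[i] = ps
        return float(chain0[0]), ps, chain0, chain_star
    p0, ps = 1.0, 1.0
    for i in range(n - 1, -1, -1):
        p0, ps = (
            (s.Pa0 * p0 + s.Pb0 * s.Pa_star * ps) / denom,
            (s.Pb_star * s.Pa0 * p0 + s.Pa_star * ps) / denom,
        )
        chain0[i], chain_star[i] = p0, ps
    return p0, ps, chain0, chain_star


def triggering_rate(params: ScaledParameters) -> TriggeringResult:
    """Scaled TCR triggering rate w for a single ligand.

    Composes the equilibrium solve (for the free CD8 density and the
    occupancy fractions eps, zeta) with the two-lane proofreading chain.
    """
    eq = solve_equilibrium(params)
    steps = step_probabilities(params, eq.x)
    P00, P0s, chain0, chain_star = triggering_probabilities(steps, params.n)
    w = params.alpha * (eq.eps * P00 + eq.zeta * params.gamma_off * P0s)
    return TriggeringResult(
        P00=P00, P0_star=P0s, w=w, P_chain0=chain0, P_chain_star=chain_star,
        equilibrium=eq,
    )


def w_of_alpha(
    params: ScaledParameters,
    alphas: np.ndarray,
    eq: EquilibriumState | None = None,
) -> np.ndarray:
    """Vectorised w over an array of scaled off-rates alpha.

    The equilibrium is independent of alpha, so it is solved once and the
    backward recursion is evaluated for all alphas simultaneously.  Used by
    the degeneracy layer, where alpha is the random variable of the ligand
    ensemble.
    """
    p = params
    alphas = np.asarray(alphas, dtype=float)
    if eq is None:
        eq = solve_equilibrium(p)
    tot0 = alphas + p.n + p.nu * eq.x
    tot_star = p.gamma_off * alphas + p.n / p.gamma_R + p.delta
    Pa0 = p.n / tot0
    Pb0 = (p.nu * eq.x) / tot0
    Pa_star = (p.n / p.gamma_R) / tot_star
    Pb_star = p.delta / tot_star
    denom = 1.0 - Pb0 * Pb_star
    p0 = np.ones_like(alphas)
    ps = np.ones_like(alphas)
    for _ in range(p.n):
        p0, ps = (
            (Pa0 * p0 + Pb0 * Pa_star * ps) / denom,
            (Pb_star * Pa0 * p0 + Pa_star * ps) / denom,
        )
    return alphas * (eq.eps * p0 + eq.zeta * p.gamma_off * ps)
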