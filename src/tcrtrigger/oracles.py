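"""Independent reference implementations of the two-lane proofreading chain.

These routines recompute the triggering probabilities without the backward
recursion used by :mod:`tcrtrigger.triggering`: once by a direct linear
solve of the first-step equations over the explicit state space, and once
by stochastic simulation of the embedded jump chain.  They exist to
cross-validate the production code path and are exercised heavily by the
test suite, but are part of the public API for anyone who wants an
independent check on a parameter regime of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .params import ScaledParameters

__all__ = ["ChainSpec", "SimulationResult", "absorption_solve", "simulate_chain"]


@dataclass(frozen=True)
class ChainSpec:
    """Transition rates of the two-lane chain, in units of the basal rate lambda.

    States are (lane, i) with lane 0 = CD8 unbound, lane 1 = CD8 bound and
    i = 0..n completed phosphorylations; i = n is the absorbing triggered
    state and TCR/pMHCI dissociation is the absorbing failure state.
    """

    n: int
    forward0: float      # phosphorylation rate, CD8 unbound (= n in scaled units)
    forward_star: float  # phosphorylation rate, CD8 bound (= n / gamma_R)
    off0: float          # TCR/pMHCI dissociation, CD8 unbound (= alpha)
    off_star: float      # TCR/pMHCI dissociation, CD8 bound (= gamma_off * alpha)
    switch_on: float     # CD8 association (= nu * x)
    switch_off: float    # CD8 dissociation (= delta)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("forward0", "forward_star", "off0", "off_star",
                     "switch_on", "switch_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")

    @classmethod
    def from_params(cls, params: ScaledParameters, x: float) -> "ChainSpec":
        """Chain rates implied by a scaled parameter set and free CD8 density x."""
        p = params
        return cls(
            n=p.n,
            forward0=float(p.n),
            forward_star=p.n / p.gamma_R,
            off0=p.alpha,
            off_star=p.gamma_off * p.alpha,
            switch_on=p.nu * x,
            switch_off=p.delta,
        )


@dataclass(frozen=True)
class SimulationResult:
    """Empirical triggering probabilities with binomial standard errors."""

    P00: float
    P0_star: float
    se00: float
    se0_star: float
    trials: int


def absorption_solve(spec: ChainSpec) -> tuple[float, float]:
    """Triggering probabilities by direct linear solve (first-step analysis).

    Builds the sparse linear system satisfied by the success probabilities
    of all 2(n+1) states — for a transient state, the probability is the
    rate-weighted average of the probabilities of its successors — and
    solves it by sparse direct elimination.  Exact up to linear-solver
    round-off; O(n) memory and near-O(n) time for this banded structure.
    """
    n = spec.n
    # State indexing: k = i for (lane 0, i), k = (n+1) + i for (lane 1, i).
    size = 2 * (n + 1)
    A = sp.lil_matrix((size, size))
    b = np.zeros(size)

    def idx(lane: int, i: int) -> int:
        return lane * (n + 1) + i

    for lane, fwd, off, sw in (
        (0, spec.forward0, spec.off0, spec.switch_on),
        (1, spec.forward_star, spec.off_star, spec.switch_off),
    ):
        # Absorbing boundary: success certain once all n steps are done.
        A[idx(lane, n), idx(lane, n)] = 1.0
        b[idx(lane, n)] = 1.0
        for i in range(n):
            total = fwd + off + sw
            if total == 0.0:
                raise ValueError(
                    f"state (lane={lane}, i={i}) has no outgoing rate; "
                    "the system is singular"
                )
            k = idx(lane, i)
            A[k, k] = total
            A[k, idx(lane, i + 1)] = -fwd
            A[k, idx(1 - lane, i)] = -sw
            # dissociation contributes 0 to the right-hand side

    sol = spsolve(A.tocsr(), b)
    return float(sol[idx(0, 0)]), float(sol[idx(1, 0)])


def simulate_chain(spec: ChainSpec, trials: int, seed: int) -> SimulationResult:
    """Monte Carlo estimate of the triggering probabilities.

    Simulates the embedded jump chain (categorical draws with probabilities
    proportional to the competing rates), which has the same absorption
    probabilities as the continuous-time chain with exponential clocks.
    Runs ``trials`` independent trajectories from each of the two starting
    lanes at zero phosphorylations.

    Returns empirical success fractions and their binomial standard errors;
    fully reproducible for a fixed seed.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = []
    for start_lane in (0, 1):
        successes = _run_batch(spec, trials, start_lane, rng)
        p = successes / trials
        estimates.append((p, np.sqrt(p * (1.0 - p) / trials)))
    (p00, se00), (p0s, se0s) = estimates
    return SimulationResult(P00=p00, P0_star=p0s, se00=se00, se0_star=se0s,
                            trials=trials)


def _run_batch(spec: ChainSpec, trials: int, start_lane: int,
               rng: np.random.Generator) -> int:
    n = spec.n
    rates = np.array([
        [spec.forward0, spec.off0, spec.switch_on],
        [spec.forward_star, spec.off_star, spec.switch_off],
    ])
    totals = rates.sum(axis=1)
    # A lane with no outgoing rate traps the trajectory forever.
    if totals[start_lane] == 0.0 or (
        totals[1 - start_lane] == 0.0 and rates[start_lane, 2] > 0.0
    ):
        raise ValueError("every reachable lane needs at least one positive rate")
    # Cumulative event thresholds per lane: [forward, forward+off] of total.
    with np.errstate(invalid="ignore"):
        thresh = np.cumsum(rates, axis=1) / np.where(totals > 0, totals, 1.0)[:, None]

    lane = np.full(trials, start_lane, dtype=np.int8)
    steps = np.zeros(trials, dtype=np.int32)
    active = np.ones(trials, dtype=bool)
    successes = 0
    while active.any():
        k = np.flatnonzero(active)
        u = rng.random(k.size)
        t1 = thresh[lane[k], 0]
        t2 = thresh[lane[k], 1]
        fwd = u < t1
        fail = (~fwd) & (u < t2)
        switch = ~fwd & ~fail

        ki = k[fwd]
        steps[ki] += 1
        done = steps[ki] >= n
        successes += int(done.sum())
        active[ki[done]] = False
        active[k[fail]] = False
        lane[k[switch]] ^= 1
    return successes
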