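"""Dimensional kinetic scheme and the bridge to scaled parameters.

The four binding states of a pMHCI molecule (free; TCR-bound; CD8-bound;
ternary TCR/pMHCI/CD8) are connected by pseudo-unimolecular association
rates lambda_i = Lambda_i * (partner density) and dissociation rates
lambda_-i.  Two-dimensional dissociation constants are K_i = lambda_-i /
Lambda_i; detailed balance of the cycle requires K1 K2 = K3 K4.

This module converts dimensional rates and surface densities into the
scaled parameter set, computes dimensional bound densities and the
dimensional triggering rate W, and generates pMHCI-mutant scenarios in
which the pMHCI/CD8 dissociation constant K3 is rescaled in proportion to
the mutant's solution-phase K_D (the confinement length relating 3D and 2D
affinities is assumed common to all mutants, so only K_D ratios enter).
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .equilibrium import solve_equilibrium
from .params import ScaledParameters
from .triggering import step_probabilities, triggering_probabilities

__all__ = [
    "DimensionalKinetics",
    "BoundDensities",
    "MutantScenario",
    "HLA_A2_MUTANTS",
    "to_scaled",
    "bound_densities",
    "triggering_rate_forms",
    "densities_affinity_form",
    "densities_gamma_form",
    "apply_mutant",
    "mutant_scenarios",
]

#: Solution-phase pMHCI/CD8 dissociation constants (micromolar) of the HLA
#: A*0201 alpha3-domain variants measured by surface plasmon resonance:
#: A245V weakens CD8 binding, Q115E slightly enhances it and the A2/a3kb
#: chimera enhances it strongly.
HLA_A2_MUTANTS: dict[str, float] = {
    "A245V": 498.0,
    "wild-type": 137.1,
    "Q115E": 97.94,
    "A2/a3kb": 10.87,
}


class DimensionalKinetics(BaseModel):
    """Dimensional rates and densities of the TCR/pMHCI/CD8 scheme.

    Association rates ``Lambda1..Lambda4`` are two-dimensional (cm^2 s^-1):
    1 = TCR/pMHCI without CD8, 2 = CD8 joining a TCR/pMHCI complex,
    3 = CD8/pMHCI without TCR, 4 = TCR joining a pMHCI/CD8 complex.
    Dissociation rates ``lambda_m1..lambda_m4`` (s^-1) are the reverse
    steps.  ``T_R`` and ``T_R_star`` are the TCR triggering thresholds
    (seconds) without and with CD8 bound; the preset default of 7.5 s sits
    in the physiologic 5-15 s band.
    """

    model_config = ConfigDict(frozen=True)

    Lambda1: float = Field(gt=0.0)
    Lambda2: float = Field(gt=0.0)
    Lambda3: float = Field(gt=0.0)
    Lambda4: float = Field(gt=0.0)
    lambda_m1: float = Field(gt=0.0)
    lambda_m2: float = Field(gt=0.0)
    lambda_m3: float = Field(gt=0.0)
    lambda_m4: float = Field(gt=0.0)
    M_T: float = Field(ge=0.0)
    X_T: float = Field(ge=0.0)
    R_T: float = Field(ge=0.0)
    T_R: float = Field(gt=0.0, default=7.5)
    T_R_star: float = Field(gt=0.0, default=7.5)

    # -- derived dissociation constants (cm^-2) ---------------------------

    @property
    def K1(self) -> float:
        return self.lambda_m1 / self.Lambda1

    @property
    def K2(self) -> float:
        return self.lambda_m2 / self.Lambda2

    @property
    def K3(self) -> float:
        return self.lambda_m3 / self.Lambda3

    @property
    def K4(self) -> float:
        return self.lambda_m4 / self.Lambda4

    @property
    def gamma_on(self) -> float:
        return self.Lambda4 / self.Lambda1

    @property
    def gamma_off(self) -> float:
        return self.lambda_m4 / self.lambda_m1

    @model_validator(mode="after")
    def _validate(self) -> "DimensionalKinetics":
        if abs(self.K1 * self.K2 - self.K3 * self.K4) > 1e-10 * self.K1 * self.K2:
            raise ValueError(
                f"detailed balance violated: K1*K2 = {self.K1 * self.K2:g} but "
                f"K3*K4 = {self.K3 * self.K4:g}; construct with "
                "DimensionalKinetics.consistent() to derive lambda_m2"
            )
        if self.T_R_star > self.T_R:
            raise ValueError(
                "T_R_star > T_R: CD8 engagement may not slow ITAM phosphorylation"
            )
        return self

    @classmethod
    def consistent(cls, **kwargs: float) -> "DimensionalKinetics":
        """Construct with ``lambda_m2`` derived from the detailed-balance cycle.

        Accepts all fields except ``lambda_m2``, which is set to
        ``Lambda2 * K3 * K4 / K1`` so that K1 K2 = K3 K4 holds exactly.
        """
        if "lambda_m2" in kwargs:
            raise TypeError("lambda_m2 is derived; do not pass it to consistent()")
        K1 = kwargs["lambda_m1"] / kwargs["Lambda1"]
        K3 = kwargs["lambda_m3"] / kwargs["Lambda3"]
        K4 = kwargs["lambda_m4"] / kwargs["Lambda4"]
        return cls(lambda_m2=kwargs["Lambda2"] * K3 * K4 / K1, **kwargs)


@dataclass(frozen=True)
class BoundDensities:
    """Dimensional surface densities (cm^-2) at binding equilibrium."""

    M: float      # free pMHCI
    M_R: float    # TCR/pMHCI without CD8
    M_X: float    # pMHCI/CD8 without TCR
    M_XR: float   # ternary TCR/pMHCI/CD8
    X: float      # free CD8
    R: float      # free TCR
    C: float      # normalisation factor of the occupancy fractions
    W: float      # dimensional TCR triggering rate (s^-1 cm^-2)


def to_scaled(kin: DimensionalKinetics, n: int = 100) -> ScaledParameters:
    """Non-dimensionalise a kinetic scheme into the scaled parameter set.

    Densities scale by the dissociation constants (x = X/K3, r = R/K1,
    m_T = M_T/K1) and rates by the basal triggering rate lambda = 1/T_R.
    """
    lam = 1.0 / kin.T_R
    return ScaledParameters(
        m_T=kin.M_T / kin.K1,
        x_T=kin.X_T / kin.K3,
        r_T=kin.R_T / kin.K1,
        alpha=kin.lambda_m1 / lam,
        delta=kin.lambda_m2 / lam,
        nu=kin.Lambda2 * kin.K3 / lam,
        kappa=kin.K1 / kin.K3,
        gamma_off=kin.gamma_off,
        gamma_kin=kin.gamma_off / kin.gamma_on,
        gamma_R=kin.T_R_star / kin.T_R,
        n=n,
    )


def densities_affinity_form(
    kin: DimensionalKinetics, X: float, R: float
) -> tuple[float, float, float]:
    """Bound pMHCI densities (M_R, M_X, M_XR) in the affinity-constant form."""
    K1, K2, K3, K4, MT = kin.K1, kin.K2, kin.K3, kin.K4, kin.M_T
    M_R = MT * R / (K1 + R + X * K1 / K3 + R * X / K2)
    M_X = MT * X / (K3 + X + R * K3 / K1 + R * X / K4)
    M_XR = MT * X * R / (K1 * K2 + R * K2 + X * K4 + R * X)
    return M_R, M_X, M_XR


def densities_gamma_form(
    kin: DimensionalKinetics, X: float, R: float
) -> tuple[float, float, float]:
    """Bound pMHCI densities in the gamma_kin parameterisation.

    Algebraically identical to :func:`densities_affinity_form` once
    gamma_kin = K4/K1 = K2/K3 is substituted; kept as an independent form
    for consistency checks.
    """
    gamma_kin = kin.K4 / kin.K1
    r, x = R / kin.K1, X / kin.K3
    D = 1.0 + r + x + x * r / gamma_kin
    M_R = kin.M_T * r / D
    M_X = kin.M_T * x / D
    M_XR = kin.M_T * x * r / (gamma_kin * (1.0 + x + r) + x * r)
    return M_R, M_X, M_XR


def bound_densities(kin: DimensionalKinetics, n: int = 100) -> BoundDensities:
    """Equilibrium surface densities and dimensional triggering rate W.

    The free densities are obtained from the scaled equilibrium solver and
    mapped back to cm^-2; W is evaluated in the dissociation-rate form
    ``W = M_R lambda_-1 P00 + M_XR lambda_-4 P0*``.
    """
    scaled = to_scaled(kin, n=n)
    eq = solve_equilibrium(scaled)
    X, R = eq.x * kin.K3, eq.r * kin.K1
    lam1 = kin.Lambda1 * R
    lam2 = kin.Lambda2 * X
    lam3 = kin.Lambda3 * X
    C = (1.0 + lam1 / kin.lambda_m1 + lam3 / kin.lambda_m3
         + lam1 * lam2 / (kin.lambda_m1 * kin.lambda_m2))
    steps = step_probabilities(scaled, eq.x)
    P00, P0s, _, _ = triggering_probabilities(steps, scaled.n)
    M_R = kin.M_T * eq.eps
    M_XR = kin.M_T * eq.zeta
    W = M_R * kin.lambda_m1 * P00 + M_XR * kin.lambda_m4 * P0s
    return BoundDensities(
        M=kin.M_T * eq.frac_free, M_R=M_R, M_X=kin.M_T * eq.frac_MX,
        M_XR=M_XR, X=X, R=R, C=C, W=W,
    )


def triggering_rate_forms(kin: DimensionalKinetics, n: int = 100) -> tuple[float, float]:
    """Dimensional W in its two equivalent forms.

    Association form ``W = M lambda_1 P00 + M_X lambda_4 P0*`` and
    dissociation form ``W = M_R lambda_-1 P00 + M_XR lambda_-4 P0*``;
    detailed balance (M lambda_1 = M_R lambda_-1 and M_X lambda_4 =
    M_XR lambda_-4) makes them equal at equilibrium.
    """
    scaled = to_scaled(kin, n=n)
    eq = solve_equilibrium(scaled)
    X, R = eq.x * kin.K3, eq.r * kin.K1
    steps = step_probabilities(scaled, eq.x)
    P00, P0s, _, _ = triggering_probabilities(steps, scaled.n)
    M = kin.M_T * eq.frac_free
    M_X = kin.M_T * eq.frac_MX
    M_R = kin.M_T * eq.eps
    M_XR = kin.M_T * eq.zeta
    W_assoc = M * kin.Lambda1 * R * P00 + M_X * kin.Lambda4 * R * P0s
    W_dissoc = M_R * kin.lambda_m1 * P00 + M_XR * kin.lambda_m4 * P0s
    return W_assoc, W_dissoc


@dataclass(frozen=True)
class MutantScenario:
    """A pMHCI variant with altered CD8-binding affinity.

    ``rho`` is the ratio K_D(variant) / K_D(reference); the two-dimensional
    constant K3 is assumed proportional to the solution K_D.
    """

    name: str
    K_D: float  # micromolar
    rho: float

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def mutant_scenarios(
    reference: str = "wild-type",
    table: dict[str, float] | None = None,
) -> list[MutantScenario]:
    """Built-in mutant scenarios with rho relative to the reference variant."""
    table = dict(table) if table is not None else dict(HLA_A2_MUTANTS)
    if reference not in table:
        raise KeyError(f"unknown reference variant {reference!r}")
    ref = table[reference]
    return [MutantScenario(name=k, K_D=v, rho=v / ref) for k, v in table.items()]


def apply_mutant(base: ScaledParameters, scenario: MutantScenario) -> ScaledParameters:
    """Rescale a reference parameter set for a CD8-affinity variant.

    K3 -> rho * K3 propagates to the three scaled parameters containing K3:
    kappa -> kappa/rho, x_T -> x_T/rho, nu -> nu*rho.  All other parameters
    are unchanged.
    """
    return base.replace(
        kappa=base.kappa / scenario.rho,
        x_T=base.x_T / scenario.rho,
        nu=base.nu * scenario.rho,
    )
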