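"""Scaled (dimensionless) model parameters and their validation.

The model of TCR triggering with CD8 co-receptor modulation is governed by
ten dimensionless parameters plus the proofreading chain length ``n``.  All
densities are scaled by two-dimensional dissociation constants (TCR and CD8
densities by the TCR/pMHCI constant K1 and the pMHCI/CD8 constant K3,
respectively) and all rates by the basal triggering rate lambda = 1/T_R,
the reciprocal of the time the TCR/CD3 complex needs to complete its
phosphorylation sequence in the absence of CD8.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ScaledParameters", "ConsistencyWarning", "check_consistency"]


class ConsistencyWarning(UserWarning):
    """Raised (as a warning) when a parameter set is thermodynamically suspect."""


class ScaledParameters(BaseModel):
    """Dimensionless parameters that govern functional sensitivity.

    Attributes
    ----------
    m_T : scaled total pMHCI density (M_T / K1).
    x_T : scaled total CD8 density (X_T / K3).
    r_T : scaled total TCR density (R_T / K1).
    alpha : scaled TCR/pMHCI off-rate without CD8 bound (lambda_-1 / lambda).
    delta : scaled pMHCI/CD8 off-rate with TCR bound (lambda_-2 / lambda).
    nu : scaled kinetic effect of pMHCI/CD8 association (Lambda_2 K3 / lambda).
    kappa : ratio of dissociation constants K1 / K3.
    gamma_off : factor by which CD8 reduces the TCR/pMHCI off-rate.
    gamma_kin : factor by which CD8 modulates the TCR/pMHCI affinity
        (gamma_off / gamma_on).
    gamma_R : factor by which CD8 shortens the TCR triggering threshold.
    n : number of phosphorylation (proofreading) steps.
    """

    model_config = ConfigDict(frozen=True)

    m_T: float = Field(ge=0.0)
    x_T: float = Field(ge=0.0)
    r_T: float = Field(ge=0.0)
    alpha: float = Field(gt=0.0)
    delta: float = Field(ge=0.0)
    nu: float = Field(ge=0.0)
    kappa: float = Field(gt=0.0)
    gamma_off: float = Field(gt=0.0, le=1.0)
    gamma_kin: float = Field(gt=0.0, le=1.0)
    gamma_R: float = Field(gt=0.0, le=1.0)
    n: int = Field(ge=1)

    @model_validator(mode="after")
    def _warn_on_gamma_order(self) -> "ScaledParameters":
        # gamma_kin = gamma_off / gamma_on with gamma_on >= 1 implies
        # gamma_kin <= gamma_off; the converse merely means gamma_on < 1,
        # so it is accepted with a warning rather than rejected.
        if self.gamma_kin > self.gamma_off + 1e-12:
            warnings.warn(
                f"gamma_kin={self.gamma_kin} > gamma_off={self.gamma_off} "
                "implies a CD8-mediated *reduction* of the TCR/pMHCI on-rate "
                "(gamma_on < 1)",
                ConsistencyWarning,
                stacklevel=2,
            )
        return self

    # -- serialisation -----------------------------------------------------

    def replace(self, **updates: Any) -> "ScaledParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        data = self.model_dump()
        data.update(updates)
        return ScaledParameters(**data)

    def to_file(self, path: str | Path) -> None:
        """Write the parameter set as YAML (``.yaml``/``.yml``) or JSON."""
        path = Path(path)
        data = self.model_dump()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScaledParameters":
        """Load a parameter set from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def check_consistency(params: ScaledParameters, rtol: float = 1e-6) -> float:
    """Check the detailed-balance identity delta/nu == gamma_kin.

    The scalings imply delta/nu = K2/K3, and detailed balance of the
    four-state binding scheme gives K2/K3 = gamma_kin.  Parameter sets used
    for scenario exploration frequently treat delta, nu and gamma_kin as
    independent dials and violate this identity; a warning (not an error)
    is emitted so that the user is aware the set does not correspond to a
    single thermodynamically consistent dimensional scheme.

    Returns the ratio (delta/nu) / gamma_kin (1.0 when consistent).
    """
    if params.nu == 0:
        warnings.warn(
            "nu = 0: delta/nu undefined, consistency with gamma_kin not checkable",
            ConsistencyWarning,
            stacklevel=2,
        )
        return float("nan")
    ratio = (params.delta / params.nu) / params.gamma_kin
    if abs(ratio - 1.0) > rtol:
        warnings.warn(
            f"delta/nu = {params.delta / params.nu:g} differs from "
            f"gamma_kin = {params.gamma_kin:g} (ratio {ratio:g}); the set is "
            "not derivable from a single detailed-balanced kinetic scheme",
            ConsistencyWarning,
            stacklevel=2,
        )
    return ratio
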