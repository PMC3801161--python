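"""Named parameter presets for the published simulation scenarios.

Each preset bundles a scaled parameter set, an optional ligand ensemble
and a default sweep.  ``cd8_dip`` is the reference scenario exhibiting the
functional-sensitivity minimum at intermediate CD8 density; ``weak_kinetic``
and ``strong_kinetic`` probe weak (nu = 0.05) and strong (nu = 300)
kinetic coupling of the pMHCI/CD8 interaction; ``mutant_panel`` is the
wild-type reference regime for the HLA A*0201 CD8-affinity variants and
``mutant_panel_highnu`` its high-nu counterpart.  The figure-style aliases
fig2..fig5c map onto these.
"""

from __future__ import annotations

from dataclasses import dataclass

from .degeneracy import EnergyEnsemble
from .params import ScaledParameters

__all__ = ["FigurePreset", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class FigurePreset:
    """A named scenario: parameters, optional ensemble, default sweep."""

    name: str
    params: ScaledParameters
    ensemble: EnergyEnsemble | None = None
    sweep_var: str = "x_T"
    sweep_grid: str = "1:200:400"
    sweep_log: bool = False
    omega_crit: float | None = None


def _p(**kw: float) -> ScaledParameters:
    return ScaledParameters(**kw)


PRESETS: dict[str, FigurePreset] = {
    "fig2": FigurePreset(
        name="fig2",
        params=_p(m_T=10, x_T=100, r_T=10, alpha=2.5, delta=300, nu=0.5,
                  kappa=5, gamma_off=0.5, gamma_kin=0.5, gamma_R=0.3, n=100),
        ensemble=EnergyEnsemble(mu=2.0, sigma=0.2),
        sweep_var="x_T",
        sweep_grid="1:200:400",
        omega_crit=0.12,
    ),
    "fig3": FigurePreset(
        name="fig3",
        params=_p(m_T=10, x_T=10, r_T=10, alpha=1.0, delta=2.5, nu=0.05,
                  kappa=1, gamma_off=0.5, gamma_kin=0.5, gamma_R=0.5, n=100),
        sweep_var="x_T",
        sweep_grid="1:200:400",
    ),
    "fig4": FigurePreset(
        name="fig4",
        params=_p(m_T=10, x_T=10, r_T=10, alpha=2.0, delta=3.0, nu=300,
                  kappa=2, gamma_off=0.2, gamma_kin=0.05, gamma_R=0.5, n=100),
        sweep_var="x_T",
        sweep_grid="1:200:400",
    ),
    "fig5": FigurePreset(
        name="fig5",
        params=_p(m_T=10, x_T=10, r_T=10, alpha=1.0, delta=0.2, nu=0.05,
                  kappa=1, gamma_off=0.5, gamma_kin=0.5, gamma_R=0.2, n=100),
        ensemble=EnergyEnsemble(mu=5.0, sigma=0.5),
        sweep_var="alpha",
        sweep_grid="0.1:100:200",
        sweep_log=True,
    ),
}
PRESETS["fig5c"] = FigurePreset(
    name="fig5c",
    params=PRESETS["fig5"].params.replace(nu=10.0),
    ensemble=PRESETS["fig5"].ensemble,
    sweep_var="alpha",
    sweep_grid="0.1:100:200",
    sweep_log=True,
)

_ALIASES = {
    "cd8_dip": "fig2",
    "weak_kinetic": "fig3",
    "strong_kinetic": "fig4",
    "mutant_panel": "fig5",
    "mutant_panel_highnu": "fig5c",
}


def preset_names() -> list[str]:
    return sorted(PRESETS) + sorted(_ALIASES)


def get_preset(name: str) -> FigurePreset:
    """Look up a preset by canonical name or alias."""
    key = _ALIASES.get(name, name)
    try:
        return PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
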