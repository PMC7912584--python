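"""Diffusion-limited corrections to bimolecular rate constants.

Fast electron transfers run into the encounter limit of the solvent.
Reactant diffusion coefficients come from the Stokes-Einstein relation,
the encounter rate from the steady-state Smoluchowski expression, and
the apparent rate constant from Collins-Kimball interpolation:

    D      = kB T / (6 pi eta a)
    k_D    = 4 pi R_AB (D_A + D_B) N_A * 1000        [M^-1 s^-1]
    k_app  = k_act k_D / (k_act + k_D)

The correction is applied only when the activation-controlled constant
exceeds a threshold (default 1e8 M^-1 s^-1, strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    DIFFUSION_THRESHOLD,
    K_BOLTZMANN,
    N_AVOGADRO,
    T_DEFAULT,
    WATER_VISCOSITY_298,
)
from .errors import ConfigError
from .et_kinetics import RateResult, eyring_rate

ANGSTROM = 1.0e-10  # m


@dataclass(frozen=True)
class DiffusionParams:
    """Hydrodynamic description of an encounter pair."""

    radius_a: float  # Angstrom
    radius_b: float  # Angstrom
    viscosity: float = WATER_VISCOSITY_298  # Pa s
    reaction_distance: float | None = None  # Angstrom; default ra + rb
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.radius_a <= 0 or self.radius_b <= 0:
            raise ValueError("reactant radii must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.reaction_distance is not None and self.reaction_distance <= 0:
            raise ValueError("reaction_distance must be positive")

    def r_ab(self) -> float:
        return (
            self.reaction_distance
            if self.reaction_distance is not None
            else self.radius_a + self.radius_b
        )


def stokes_einstein_diffusion(radius: float, viscosity: float, T: float = T_DEFAULT) -> float:
    """Diffusion coefficient (m^2/s) of a sphere of the given Stokes
    radius (Angstrom) in a solvent of the given viscosity (Pa s)."""
    if radius <= 0 or viscosity <= 0 or T <= 0:
        raise ValueError("radius, viscosity and T must be positive")
    return K_BOLTZMANN * T / (6.0 * math.pi * viscosity * radius * ANGSTROM)


def smoluchowski_rate(reaction_distance: float, d_ab: float) -> float:
    """Steady-state encounter rate constant (M^-1 s^-1) for an
    irreversible diffusion-controlled bimolecular reaction.

    ``reaction_distance`` in Angstrom, ``d_ab`` the mutual diffusion
    coefficient D_A + D_B in m^2/s.
    """
    if reaction_distance <= 0 or d_ab <= 0:
        raise ValueError("reaction_distance and d_ab must be positive")
    return 4.0 * math.pi * reaction_distance * ANGSTROM * d_ab * N_AVOGADRO * 1.0e3


def collins_kimball(k_act: float, k_d: float) -> float:
    """Apparent rate constant interpolating the activation- and
    diffusion-limited regimes; always <= min(k_act, k_d)."""
    if k_act <= 0 or k_d <= 0:
        raise ValueError("rate constants must be positive")
    return k_act * k_d / (k_act + k_d)


def diffusion_rate(params: DiffusionParams) -> float:
    """Encounter rate constant (M^-1 s^-1) for a reactant pair."""
    d_a = stokes_einstein_diffusion(params.radius_a, params.viscosity, params.T)
    d_b = stokes_einstein_diffusion(params.radius_b, params.viscosity, params.T)
    return smoluchowski_rate(params.r_ab(), d_a + d_b)


def apparent_rate(
    delta_g_act: float,
    T: float = T_DEFAULT,
    params: DiffusionParams | None = None,
    threshold: float = DIFFUSION_THRESHOLD,
    label: str | None = None,
) -> RateResult:
    """TST rate with the diffusion correction gated at the threshold.

    k_act strictly above the threshold triggers the Collins-Kimball
    combination with the Smoluchowski encounter rate; at or below it the
    apparent constant is k_act itself.
    """
    k_act = eyring_rate(delta_g_act, T=T)
    if k_act > threshold:
        if params is None:
            raise ConfigError(
                f"k_act = {k_act:.3g} exceeds the diffusion threshold "
                f"{threshold:.3g} but no DiffusionParams were supplied"
            )
        k_d = diffusion_rate(params)
        return RateResult(
            delta_g_act=delta_g_act,
            k_act=k_act,
            k_app=collins_kimball(k_act, k_d),
            k_diff=k_d,
            diffusion_applied=True,
            label=label,
        )
    return RateResult(
        delta_g_act=delta_g_act,
        k_act=k_act,
        k_app=k_act,
        k_diff=None,
        diffusion_applied=False,
        label=label,
    )
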