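"""Marcus-theory activation energies and transition-state-theory rate
constants for outer-sphere electron transfer.

The reduction of the chelated (or hydrated) metal centre by superoxide
or ascorbate,

    M(III/II)Lx + Ox-  ->  M(II/I)Lx + Ox,

is treated with the classical Marcus quadratic relation

    dG_act = (lambda / 4) * (1 + dG_ET / lambda)^2

and the Eyring equation

    k = (kB T / h) * exp(-dG_act / R T).

The reorganization energy lambda is either supplied directly or derived
from a single-point vertical energy gap, lambda = dE_vertical - dG_ET.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import H_PLANCK, K_BOLTZMANN, T_DEFAULT, rt_kcal


@dataclass(frozen=True)
class ETReaction:
    """One electron-transfer step with its driving force and lambda."""

    label: str
    oxidant_complex: str
    reduced_complex: str
    reductant: str  # "superoxide" or "ascorbate"
    delta_g_et: float  # kcal/mol
    lambda_reorg: float | None = None  # kcal/mol
    delta_e_vertical: float | None = None  # kcal/mol
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.reductant not in ("superoxide", "ascorbate"):
            raise ValueError(f"unknown reductant {self.reductant!r}")
        if (self.lambda_reorg is None) == (self.delta_e_vertical is None):
            raise ValueError(
                "exactly one of lambda_reorg / delta_e_vertical must be given"
            )
        if self.lambda_reorg is not None and self.lambda_reorg <= 0:
            raise ValueError(f"lambda_reorg must be > 0, got {self.lambda_reorg}")

    def resolved_lambda(self) -> float:
        if self.lambda_reorg is not None:
            return self.lambda_reorg
        return reorganization_energy(self.delta_e_vertical, self.delta_g_et)


@dataclass(frozen=True)
class RateResult:
    """Activation energy and rate constants for one reduction step."""

    delta_g_act: float  # kcal/mol, >= 0
    k_act: float  # M^-1 s^-1
    k_app: float  # M^-1 s^-1
    k_diff: float | None = None  # M^-1 s^-1
    diffusion_applied: bool = False
    ratio_vs_reference: float | None = None
    label: str | None = None


def marcus_activation(delta_g_et: float, lambda_reorg: float) -> float:
    """Marcus activation free energy (kcal/mol), non-negative by
    construction; re-enters the inverted region for dG_ET < -lambda."""
    if lambda_reorg <= 0:
        raise ValueError(f"lambda_reorg must be > 0, got {lambda_reorg}")
    return (lambda_reorg / 4.0) * (1.0 + delta_g_et / lambda_reorg) ** 2


def reorganization_energy(delta_e_vertical: float, delta_g_et: float) -> float:
    """Single-point lambda = dE_vertical - dG_ET (kcal/mol)."""
    lam = delta_e_vertical - delta_g_et
    if lam <= 0:
        raise ValueError(
            f"unphysical reorganization energy {lam} <= 0 "
            f"(dE = {delta_e_vertical}, dG_ET = {delta_g_et})"
        )
    return lam


def eyring_rate(delta_g_act: float, T: float = T_DEFAULT) -> float:
    """TST rate constant, (kB T / h) exp(-dG_act / RT).

    The universal frequency prefactor is applied against the 1 M
    bimolecular standard state, so the result carries M^-1 s^-1.
    """
    if delta_g_act < 0:
        raise ValueError(f"delta_g_act must be >= 0, got {delta_g_act}")
    prefactor = K_BOLTZMANN * T / H_PLANCK
    return prefactor * math.exp(-delta_g_act / rt_kcal(T))


def activation_rate(et: ETReaction) -> tuple[float, float]:
    """(dG_act, k_act) for one electron-transfer reaction."""
    lam = et.resolved_lambda()
    dga = marcus_activation(et.delta_g_et, lam)
    return dga, eyring_rate(dga, T=et.T)
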