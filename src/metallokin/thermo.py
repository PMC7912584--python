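"""Complexation thermodynamics: reaction Gibbs energies, standard-state
and deprotonation corrections, formation constants, stability rankings.

The pipeline for one chelation equilibrium is

    dG_raw   = sum(coeff * G0)_products - sum(coeff * G0)_reactants
    dGf      = dG_raw + dG_standard_state + x * dG_dep
    logKf    = -dGf / (R T ln 10),   Kf = 10^logKf

The deprotonation penalty is *added* to the raw reaction energy: bringing
the ligand into its chelating anionic form costs free energy and makes
the complex less stable (a smaller |dGf|). logKf is computed in log
space first so that very stable complexes (|dGf| > 60 kcal/mol) never
overflow the exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .constants import (
    LN10,
    MOLAR_VOLUME_298,
    T_DEFAULT,
    WATER_MOLARITY,
    rt_kcal,
)
from .errors import ConfigError, SpeciesLookupError
from .species_io import Reaction, SpeciesMap, SpeciesRecord, _species_map


@dataclass(frozen=True)
class FormationResult:
    """Formation free energy and constant for one complex, with its
    correction ledger."""

    reaction: Reaction
    delta_g_raw: float  # kcal/mol, plain species-energy balance
    ss_correction: float  # kcal/mol, standard-state shift
    dep_penalty_total: float  # kcal/mol, x * per-ligand penalty
    delta_g_formation: float  # kcal/mol, final
    Kf: float
    logKf: float
    T: float = T_DEFAULT
    label: str | None = None


def reaction_gibbs(
    reaction: Reaction,
    energies: Mapping[str, float] | SpeciesMap,
) -> float:
    """Reaction Gibbs energy (kcal/mol) from per-species standard G0."""

    def g(label: str) -> float:
        try:
            val = energies[label]
        except KeyError:
            raise SpeciesLookupError(f"no energy for label {label!r}") from None
        if isinstance(val, SpeciesRecord):
            return val.g_standard
        return float(val)

    prod = sum(coeff * g(l) for l, coeff in reaction.products)
    reac = sum(coeff * g(l) for l, coeff in reaction.reactants)
    return prod - reac


def standard_state_correction(
    reaction: Reaction,
    convention: str = "one_molar_all",
    species: Union[SpeciesMap, Iterable[SpeciesRecord], None] = None,
    T: float = T_DEFAULT,
) -> float:
    """Standard-state shift (kcal/mol) for moving every solute from the
    1 atm gas convention to 1 M.

    ``one_molar_all``: dn * RT ln(24.46) where dn counts all product
    minus reactant coefficients except protons (protons are handled via
    pK, never via an explicit concentration term).
    ``one_molar_solutes_55M_water``: as above, but released/consumed
    water additionally carries RT ln(55.34) per molecule, treating the
    solvent at its own liquid-state concentration.
    ``none``: 0.
    """
    if convention == "none":
        return 0.0
    if convention not in ("one_molar_all", "one_molar_solutes_55M_water"):
        raise ConfigError(f"unknown standard-state convention {convention!r}")

    smap = _species_map(species) if species is not None else {}

    def role(label: str) -> str:
        rec = smap.get(label)
        return rec.role if rec is not None else "unknown"

    dn = 0
    dn_water = 0
    for label, coeff in reaction.products:
        if role(label) == "proton":
            continue
        dn += coeff
        if role(label) == "water":
            dn_water += coeff
    for label, coeff in reaction.reactants:
        if role(label) == "proton":
            continue
        dn -= coeff
        if role(label) == "water":
            dn_water -= coeff

    rt = rt_kcal(T)
    corr = dn * rt * math.log(MOLAR_VOLUME_298)
    if convention == "one_molar_solutes_55M_water":
        corr += dn_water * rt * math.log(WATER_MOLARITY)
    return corr


def delta_n_correction(delta_n: int, T: float = T_DEFAULT) -> float:
    """dn * RT ln(24.46) for a bare species-count change."""
    return delta_n * rt_kcal(T) * math.log(MOLAR_VOLUME_298)


def ph_corrected_formation(
    delta_g_raw: float,
    x: int,
    dep_penalty_per_ligand: float,
) -> float:
    """Apply the per-ligand deprotonation penalty: dG + x * penalty.

    The penalty destabilizes the complex (dGf becomes less negative);
    x is the number of ligands in the coordination compound.
    """
    if x < 0:
        raise ValueError(f"ligand count x must be >= 0, got {x}")
    return delta_g_raw + x * dep_penalty_per_ligand


def formation_constant(delta_g_formation: float, T: float = T_DEFAULT) -> tuple[float, float]:
    """(Kf, logKf) from the formation Gibbs energy.

    logKf = -dGf/(RT ln10) is evaluated first; Kf = 10^logKf may
    overflow to inf only for logKf beyond float range (~1e308).
    """
    rt = rt_kcal(T)
    log_kf = -delta_g_formation / (rt * LN10)
    try:
        kf = 10.0 ** log_kf
    except OverflowError:
        kf = math.inf
    return kf, log_kf


def rank_stability(best_delta_g_per_ligand: Mapping[str, float]) -> list[str]:
    """Order ligands from least to most stable best complex.

    Sorting is by ascending |dGf| (descending dGf for the usual negative
    values); ties break lexicographically by ligand label.
    """
    if not best_delta_g_per_ligand:
        raise ValueError("empty stability map")
    return sorted(best_delta_g_per_ligand, key=lambda k: (-best_delta_g_per_ligand[k], k))


def compute_formation(
    reaction: Reaction,
    species: Union[SpeciesMap, Iterable[SpeciesRecord]],
    dep_penalty_per_ligand: float = 0.0,
    convention: str = "one_molar_all",
    T: float = T_DEFAULT,
    label: str | None = None,
) -> FormationResult:
    """Full pipeline for one equilibrium; x is taken from the reaction."""
    smap = _species_map(species)
    raw = reaction_gibbs(reaction, smap)
    ss = standard_state_correction(reaction, convention=convention, species=smap, T=T)
    x = reaction.x if reaction.x is not None else 0
    dep_total = x * dep_penalty_per_ligand
    dgf = raw + ss + dep_total
    kf, log_kf = formation_constant(dgf, T=T)
    return FormationResult(
        reaction=reaction,
        delta_g_raw=raw,
        ss_correction=ss,
        dep_penalty_total=dep_total,
        delta_g_formation=dgf,
        Kf=kf,
        logKf=log_kf,
        T=T,
        label=label,
    )
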