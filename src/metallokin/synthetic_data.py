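"""Synthetic thermochemistry generator with known ground truth.

Solution-phase G0 tables of the kind produced by a DFT/SMD workflow are
emulated with an additive per-ligand binding structure: the raw
complexation energy of the 1:x complex of ligand L is

    dG_raw(L, x) = x * mu_L + eps,    eps ~ Normal(0, noise_sd^2),

realized by constructing mutually consistent absolute G0 values for the
hydrated metal ion, free ligand, released water and complex. This is
the pattern seen across real chelation series, where 1:2 complexes are
roughly twice as stable as 1:1. The generator also draws Marcus
electron-transfer inputs (dG_ET, lambda) and post-annihilation <S^2>
values with optional Gaussian contamination, and records every draw so
parameter-recovery tests can score the pipeline against truth.

All output is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import H_PLANCK, K_BOLTZMANN, PH_DEFAULT, R_KCAL, T_DEFAULT
from .errors import ConfigError, IdentifiabilityError
from .et_kinetics import ETReaction
from .species_io import (
    COORDINATION,
    METAL_CHARGE,
    Reaction,
    SpeciesMap,
    SpeciesRecord,
    build_scheme_reaction,
)

#: anionic-ligand chelation scheme tag per metal
_ANIONIC_SCHEME = {"Cu": "7", "Fe": "10"}
#: unpaired electrons of the oxidized metal centre
_METAL_UNPAIRED = {"Cu": 1, "Fe": 5}


@dataclass(frozen=True)
class LigandSpec:
    """Ground-truth description of one synthetic ligand."""

    name: str
    binding_increment_mu: float  # kcal/mol per ligand, negative
    m: int = 0  # protons shed to reach the chelating anion
    pK_cumulative: float = 0.0

    def __post_init__(self) -> None:
        if self.binding_increment_mu >= 0:
            raise ConfigError(
                f"binding increment for {self.name!r} must be negative"
            )
        if self.m < 0:
            raise ConfigError("m must be >= 0")


def default_ligands() -> tuple[LigandSpec, ...]:
    """Three ligands spanning the chelation regimes of interest: a
    strong doubly-protonated chelator (PM-like), a mid-range
    singly-protonated one (Amadori-like) and a weaker already-anionic
    one (ascorbate-like)."""
    return (
        LigandSpec("PM", -18.0, m=2, pK_cumulative=20.08),
        LigandSpec("AMD", -15.0, m=1, pK_cumulative=9.01),
        LigandSpec("ASC", -12.0, m=0, pK_cumulative=0.0),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    metal: str = "Cu"
    ligands: tuple[LigandSpec, ...] = field(default_factory=default_ligands)
    max_stoichiometry: int = 3
    noise_sd: float = 0.5  # kcal/mol on each reaction dG
    T: float = T_DEFAULT
    pH: float = PH_DEFAULT
    lambda_range: tuple[float, float] = (20.0, 60.0)  # kcal/mol
    delta_g_range: tuple[float, float] = (-40.0, 10.0)  # kcal/mol
    spin_contamination_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.metal not in COORDINATION:
            raise ConfigError(f"unknown metal {self.metal!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.max_stoichiometry < 1:
            raise ConfigError("max_stoichiometry must be >= 1")
        if self.lambda_range[0] <= 0 or self.lambda_range[0] > self.lambda_range[1]:
            raise ConfigError("lambda_range must be positive and ordered")
        if self.delta_g_range[0] > self.delta_g_range[1]:
            raise ConfigError("delta_g_range must be ordered")
        if not self.ligands:
            raise ConfigError("at least one ligand required")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the generator."""

    seed: int
    mu: dict[str, float]
    eps: dict[str, float]  # keyed "ligand:x"
    raw_delta_g: dict[str, float]  # keyed by complex label
    pK_cumulative: dict[str, float]
    m: dict[str, int]
    s2_true: dict[str, float]


def _complex_label(metal: str, ligand: str, x: int) -> str:
    return f"[{metal}({ligand}){x}]"


def generate_species_set(
    config: SyntheticConfig,
) -> tuple[SpeciesMap, list[Reaction], GroundTruth]:
    """Emit a species table, the matching chelation equilibria, and the
    ground truth behind them.

    For each ligand and each stoichiometry x <= max, the complex G0 is
    back-constructed so the anionic-scheme reaction energy equals
    x * mu + eps. Bidentate binding is assumed: the 1:x complex retains
    max(coord - 2x, 0) waters.
    """
    rng = np.random.default_rng(config.seed)
    metal = config.metal
    coord = COORDINATION[metal]
    q = METAL_CHARGE[metal]
    scheme = _ANIONIC_SCHEME[metal]

    g_water = -47857.3  # kcal/mol, plausible SMD-scale absolute G0
    g_metal_aqua = float(rng.uniform(-1.5e6, -0.5e6))
    aqua_label = f"[{metal}(H2O){coord}]{q}+"
    n_unpaired = _METAL_UNPAIRED[metal]

    species: SpeciesMap = {
        "H2O": SpeciesRecord("H2O", "water", 0, 0, g_water),
        "H+": SpeciesRecord("H+", "proton", 1, 0, 0.0),
        aqua_label: SpeciesRecord(
            aqua_label,
            "metal_aqua",
            q,
            n_unpaired,
            g_metal_aqua,
            metal=metal,
            s2_after=float(
                n_unpaired / 2 * (n_unpaired / 2 + 1)
                + rng.normal(0.0, config.spin_contamination_sd)
            ),
            stokes_radius=3.0,
        ),
    }

    truth = GroundTruth(
        seed=config.seed,
        mu={},
        eps={},
        raw_delta_g={},
        pK_cumulative={},
        m={},
        s2_true={},
    )
    truth.s2_true[aqua_label] = n_unpaired / 2 * (n_unpaired / 2 + 1)

    reactions: list[Reaction] = []
    for lig in config.ligands:
        g_ligand = float(rng.uniform(-6e5, -2e5))
        species[lig.name] = SpeciesRecord(
            lig.name, "ligand", -1, 0, g_ligand, stokes_radius=3.5
        )
        truth.mu[lig.name] = lig.binding_increment_mu
        truth.pK_cumulative[lig.name] = lig.pK_cumulative
        truth.m[lig.name] = lig.m
        for x in range(1, config.max_stoichiometry + 1):
            eps = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd > 0 else 0.0
            target = x * lig.binding_increment_mu + eps
            n_retained = max(coord - 2 * x, 0)
            released = coord - n_retained
            label = _complex_label(metal, lig.name, x)
            # G0(complex) chosen so the scheme reaction energy equals target
            g_complex = (
                target + g_metal_aqua + x * g_ligand - released * g_water
            )
            s2_exp = n_unpaired / 2 * (n_unpaired / 2 + 1)
            species[label] = SpeciesRecord(
                label,
                "complex",
                q - x,
                n_unpaired,
                g_complex,
                metal=metal,
                n_ligands=x,
                s2_after=float(s2_exp + rng.normal(0.0, config.spin_contamination_sd)),
                stokes_radius=3.0 + 0.8 * x,
            )
            truth.eps[f"{lig.name}:{x}"] = eps
            truth.raw_delta_g[label] = target
            truth.s2_true[label] = s2_exp
            reactions.append(
                build_scheme_reaction(
                    scheme, x, n_retained, lig.name, label, metal_aqua_label=aqua_label
                )
            )
    return species, reactions, truth


def generate_et_inputs(
    config: SyntheticConfig,
    n_samples: int = 50,
) -> tuple[list[ETReaction], list[dict[str, float]]]:
    """Sample (dG_ET, lambda) pairs uniformly from the configured ranges
    with the ground-truth activation energy and TST rate attached."""
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    lam_lo, lam_hi = config.lambda_range
    dg_lo, dg_hi = config.delta_g_range
    reactions, truths = [], []
    for i in range(n_samples):
        dg = float(rng.uniform(dg_lo, dg_hi))
        lam = float(rng.uniform(lam_lo, lam_hi))
        reactions.append(
            ETReaction(
                label=f"et{i}",
                oxidant_complex=f"ox{i}",
                reduced_complex=f"red{i}",
                reductant="superoxide" if i % 2 == 0 else "ascorbate",
                delta_g_et=dg,
                lambda_reorg=lam,
                T=config.T,
            )
        )
        dga = 0.25 * lam * (1.0 + dg / lam) ** 2
        k = (K_BOLTZMANN * config.T / H_PLANCK) * np.exp(-dga / (R_KCAL * config.T))
        truths.append({"delta_g_act": dga, "k": float(k)})
    return reactions, truths


def recover_increments(
    species: SpeciesMap,
    reactions: list[Reaction],
) -> dict[str, tuple[float, float]]:
    """Least-squares per-ligand binding increment from raw reaction
    energies: fit dG_raw = mu * x through the origin.

    Returns ligand -> (mu_hat, standard error). The analytic SE is
    sqrt(RSS / (k - 1) / sum(x^2)) over the k observed stoichiometries;
    for a saturated fit (k = 1 would be unidentifiable and raises) with
    zero residuals the SE is 0.
    """
    from .thermo import reaction_gibbs

    per_ligand: dict[str, list[tuple[int, float]]] = {}
    for rxn in reactions:
        lig = next(
            (l for l, _ in rxn.reactants if species[l].role == "ligand"), None
        )
        if lig is None or rxn.x is None:
            continue
        per_ligand.setdefault(lig, []).append((rxn.x, reaction_gibbs(rxn, species)))

    out: dict[str, tuple[float, float]] = {}
    for lig, points in per_ligand.items():
        xs = np.array([p[0] for p in points], dtype=float)
        ys = np.array([p[1] for p in points], dtype=float)
        if len(np.unique(xs)) < 2:
            raise IdentifiabilityError(
                f"ligand {lig!r}: need >= 2 distinct stoichiometries, "
                f"got {sorted(set(xs.tolist()))}"
            )
        sxx = float(np.sum(xs * xs))
        mu_hat = float(np.sum(xs * ys) / sxx)
        resid = ys - mu_hat * xs
        dof = len(xs) - 1
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else 0.0
        out[lig] = (mu_hat, se)
    return out


def write_fixture_dir(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write species.csv, reactions.json, et.json and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species, reactions, truth = generate_species_set(config)
    et_reactions, et_truth = generate_et_inputs(config)

    header = (
        "label,role,charge,unpaired_electrons,g_standard,h_standard,"
        "s2_before,s2_after,metal,n_ligands,stokes_radius"
    )
    lines = [header]
    for rec in species.values():
        lines.append(
            ",".join(
                [
                    rec.label,
                    rec.role,
                    str(rec.charge),
                    str(rec.unpaired_electrons),
                    repr(rec.g_standard),
                    "" if rec.h_standard is None else repr(rec.h_standard),
                    "" if rec.s2_before is None else repr(rec.s2_before),
                    "" if rec.s2_after is None else repr(rec.s2_after),
                    rec.metal,
                    str(rec.n_ligands),
                    "" if rec.stokes_radius is None else repr(rec.stokes_radius),
                ]
            )
        )
    paths = {
        "species": out / "species.csv",
        "reactions": out / "reactions.json",
        "et": out / "et.json",
        "ground_truth": out / "ground_truth.json",
    }
    paths["species"].write_text("\n".join(lines) + "\n")
    paths["reactions"].write_text(
        json.dumps(
            [
                {
                    "reactants": [list(t) for t in r.reactants],
                    "products": [list(t) for t in r.products],
                    "scheme_id": r.scheme_id,
                    "x": r.x,
                    "n": r.n,
                }
                for r in reactions
            ],
            indent=2,
        )
    )
    paths["et"].write_text(
        json.dumps(
            [
                {
                    "label": e.label,
                    "oxidant_complex": e.oxidant_complex,
                    "reduced_complex": e.reduced_complex,
                    "reductant": e.reductant,
                    "delta_g_et": e.delta_g_et,
                    "lambda_reorg": e.lambda_reorg,
                    "T": e.T,
                }
                for e in et_reactions
            ],
            indent=2,
        )
    )
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "seed": truth.seed,
                "mu": truth.mu,
                "eps": truth.eps,
                "raw_delta_g": truth.raw_delta_g,
                "pK_cumulative": truth.pK_cumulative,
                "m": truth.m,
                "s2_true": truth.s2_true,
                "et": et_truth,
            },
            indent=2,
        )
    )
    return paths
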