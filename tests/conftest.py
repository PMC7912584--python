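import pytest

from metallokin import SyntheticConfig, generate_species_set
from metallokin.species_io import scheme_species_charges, SpeciesRecord


@pytest.fixture()
def noiseless_set():
    """Deterministic noise-free synthetic species/reactions/truth."""
    config = SyntheticConfig(seed=7, noise_sd=0.0)
    return generate_species_set(config)


@pytest.fixture()
def noisy_set():
    config = SyntheticConfig(seed=11, noise_sd=0.5)
    return generate_species_set(config)


def scheme_species(scheme_id: str, x: int) -> dict[str, SpeciesRecord]:
    """Minimal species records carrying the formal charges of one
    chelation scheme, for balance-checking template reactions."""
    from metallokin.species_io import COORDINATION, METAL_CHARGE, SCHEME_METAL

    charges = scheme_species_charges(scheme_id, x)
    metal = SCHEME_METAL[str(scheme_id)]
    coord = COORDINATION[metal]
    aqua = f"[{metal}(H2O){coord}]{METAL_CHARGE[metal]}+"
    return {
        "L": SpeciesRecord("L", "ligand", charges["ligand"], 0, -100.0),
        aqua: SpeciesRecord(aqua, "metal_aqua", charges["metal_aqua"], 1, -500.0, metal=metal),
        "MLx": SpeciesRecord("MLx", "complex", charges["complex"], 1, -700.0,
                             metal=metal, n_ligands=x),
        "H2O": SpeciesRecord("H2O", "water", 0, 0, -47.0),
        "H+": SpeciesRecord("H+", "proton", 1, 0, 0.0),
    }
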