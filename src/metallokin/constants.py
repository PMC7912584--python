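"""Physical constants and solution-phase defaults.

All energies in this package are kcal/mol; temperatures in kelvin;
concentrations in mol/L; rate constants in M^-1 s^-1 unless stated
otherwise.
"""

import math

#: Gas constant, kcal mol^-1 K^-1 (CODATA 2018, exact SI value converted).
R_KCAL = 1.9872042586e-3

#: Hartree -> kcal/mol (CODATA 2018).
HARTREE_TO_KCAL = 627.5094740631

#: Boltzmann constant, J K^-1 (exact).
K_BOLTZMANN = 1.380649e-23

#: Planck constant, J s (exact).
H_PLANCK = 6.62607015e-34

#: Avogadro constant, mol^-1 (exact).
N_AVOGADRO = 6.02214076e23

LN10 = math.log(10.0)

#: Default working temperature, K.
T_DEFAULT = 298.15

#: Default (physiological) pH.
PH_DEFAULT = 7.4

#: Molar volume of an ideal gas at 298.15 K and 1 atm, L/mol. The
#: gas-phase (1 atm) -> solution (1 M) standard-state shift per species is
#: RT ln(24.46).
MOLAR_VOLUME_298 = 24.46

#: Molarity of pure liquid water at 298.15 K, mol/L.
WATER_MOLARITY = 55.34

#: Dynamic viscosity of water at 298.15 K, Pa s (standard tabulated value).
WATER_VISCOSITY_298 = 8.91e-4

#: Above this activation-controlled rate constant (M^-1 s^-1) a
#: diffusion correction is applied (strict inequality).
DIFFUSION_THRESHOLD = 1.0e8


def rt_kcal(temperature: float) -> float:
    """R*T in kcal/mol; raises for non-physical temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature
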