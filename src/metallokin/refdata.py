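"""Published benchmark values for Cu(II)/Fe(III) chelation by
pyridoxamine (PM), ascorbate (ASC), a model Amadori compound (AMD) and
aminoguanidine (AG) at 298.15 K and pH 7.4.

These literature numbers are *inputs* used for regression checks: the
formation energies come from DFT-level solution thermochemistry that
this package does not recompute, so consistency is verified on the
derived quantities (logKf from dGf, rate-constant ratios from the
printed rate constants) instead.

Each complex entry: label -> (metal, ligand, x, dGf in kcal/mol,
printed Kf, printed logKf).
"""

from __future__ import annotations

# ΔGf° (kcal/mol), Kf, logKf — Cu(II) square-planar complexes
CU_COMPLEXES = {
    "{A1}": ("Cu", "AMD", 1, -1.8, 20.2, 1.31),
    "{A2}": ("Cu", "AMD", 1, -9.0, 3.91e6, 6.59),
    "{A3}": ("Cu", "AMD", 1, -19.7, 2.54e14, 14.41),
    "{A4}": ("Cu", "AMD", 1, -20.7, 1.48e15, 15.17),
    "{A5}": ("Cu", "AMD", 2, -33.6, 3.93e24, 24.59),
    "{A6}": ("Cu", "AMD", 2, -35.3, 7.28e25, 25.86),
    "{A7}": ("Cu", "ASC", 1, -6.9, 1.11e5, 5.05),
    "{A8}": ("Cu", "ASC", 2, -13.7, 1.08e10, 10.03),
    "{A9}": ("Cu", "PM", 1, -19.4, 1.67e14, 14.22),
    "{A10}": ("Cu", "PM", 2, -33.8, 5.49e24, 24.74),
    "{A11}": ("Cu", "PM", 2, -35.8, 1.69e26, 26.23),
    "{G1}": ("Cu", "AG", 1, -16.3, 8.75e11, 11.94),
    "{G2}": ("Cu", "AG", 2, -29.7, 6.25e21, 21.80),
}

# Octahedral Fe(III) complexes
FE_OCTAHEDRAL = {
    "{B1}": ("Fe", "AMD", 1, -20.1, 5.07e14, 14.71),
    "{B2}": ("Fe", "AMD", 1, -23.4, 1.39e17, 17.14),
    "{B3}": ("Fe", "AMD", 2, -37.4, 2.60e27, 27.41),
    "{B4}": ("Fe", "AMD", 2, -42.8, 2.24e31, 31.35),
    "{B5}": ("Fe", "AMD", 3, -48.9, 6.72e35, 35.83),
    "{B6}": ("Fe", "ASC", 1, -19.3, 1.30e14, 14.11),
    "{B7}": ("Fe", "ASC", 2, -28.3, 5.83e20, 20.77),
    "{B8}": ("Fe", "ASC", 3, -46.9, 2.20e34, 34.34),
    "{B9}": ("Fe", "PM", 1, -28.4, 6.90e20, 20.84),
    "{B10}": ("Fe", "PM", 2, -42.1, 7.83e30, 30.89),
    "{B11}": ("Fe", "PM", 2, -45.8, 3.48e33, 33.54),
    "{B12}": ("Fe", "PM", 3, -58.9, 1.56e43, 43.19),
    "{G3}": ("Fe", "AG", 1, -10.3, 3.48e7, 7.54),
    "{G4}": ("Fe", "AG", 2, -23.5, 1.78e17, 17.25),
    "{G5}": ("Fe", "AG", 3, -37.9, 5.65e27, 27.75),
}

# Fe(III) complexes with coordination number below six
FE_NON_OCTAHEDRAL = {
    "{C1}": ("Fe", "AMD", 1, -18.4, 3.34e13, 13.52),
    "{C2}": ("Fe", "AMD", 1, -22.1, 1.59e16, 16.20),
    "{C3}": ("Fe", "AMD", 1, -22.5, 3.17e16, 16.50),
    "{C4}": ("Fe", "AMD", 1, -27.3, 9.55e19, 19.98),
    "{C5}": ("Fe", "AMD", 2, -41.7, 3.40e30, 30.53),
    "{C6}": ("Fe", "AMD", 2, -41.7, 3.77e30, 30.58),
    "{C7}": ("Fe", "ASC", 1, -22.6, 3.78e16, 16.58),
    "{C8}": ("Fe", "ASC", 1, -25.7, 6.55e18, 18.82),
    "{C9}": ("Fe", "ASC", 2, -28.3, 5.15e20, 20.71),
    "{C10}": ("Fe", "PM", 1, -24.9, 1.88e18, 18.27),
    "{C11}": ("Fe", "PM", 1, -26.5, 2.80e19, 19.45),
    "{C12}": ("Fe", "PM", 2, -46.3, 8.29e33, 33.92),
    "{C13}": ("Fe", "PM", 2, -48.0, 1.46e35, 35.16),
    "{C14}": ("Fe", "PM", 2, -51.1, 2.84e37, 37.45),
}

ALL_COMPLEXES = {**CU_COMPLEXES, **FE_OCTAHEDRAL, **FE_NON_OCTAHEDRAL}

# Rate constants (M^-1 s^-1) for reduction by superoxide / ascorbate,
# with the published fold-reduction vs the hydrated-ion reference.
# label -> {reductant: (k_app, printed ratio or None for the reference,
#                       significant figures of the printed ratio)}
REDUCTION_RATES = {
    "Cu_aqua": {"superoxide": (7.71e9, None, 0), "ascorbate": (2.10e9, None, 0)},
    "{A9}": {"superoxide": (5.53e9, 1.39, 3), "ascorbate": (2.47e3, 8.50e5, 3)},
    "{A11}": {"superoxide": (7.95e5, 9.70e3, 3), "ascorbate": (5.13e-5, 4.09e13, 3)},
    "Fe_aqua": {"superoxide": (7.28e9, None, 0), "ascorbate": (7.43e9, None, 0)},
    "{B9}": {"superoxide": (8.21e9, 0.89, 2), "ascorbate": (3.99e6, 1.86e3, 3)},
    "{B11}": {"superoxide": (7.10e9, 1.02, 3), "ascorbate": (3.91e2, 1.90e7, 3)},
    "{B12}": {"superoxide": (4.08e6, 1.78e3, 3), "ascorbate": (1.67e-6, 4.45e15, 3)},
}

#: reference reduction per metal
RATE_REFERENCE = {"Cu": "Cu_aqua", "Fe": "Fe_aqua"}

#: metal of each kinetic complex
RATE_METAL = {"{A9}": "Cu", "{A11}": "Cu", "{B9}": "Fe", "{B11}": "Fe", "{B12}": "Fe"}

#: experimental reduction of hydrated Cu(II) by superoxide, M^-1 s^-1
CU_SUPEROXIDE_EXPERIMENTAL = 8.1e9

#: published pH-7.4 deprotonation penalties (kcal/mol): one proton off
#: the neutral Amadori zwitterion, two protons off protonated PM.
DEPROTONATION_PENALTY = {"AMD": 2.2, "PM": 7.2}
DEPROTONATION_PROTONS = {"AMD": 1, "PM": 2, "ASC": 0}

#: ascorbic acid pKa (already anionic at pH 7.4)
ASC_PKA = 4.1
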