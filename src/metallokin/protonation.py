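"""pH-dependent deprotonation free-energy penalty.

A ligand whose dominant protonation state at the working pH is not the
chelating (deprotonated) anion must pay a Gibbs-energy cost before it
can bind the metal. For ``m`` protons removed per ligand with cumulative
pK (the sum of the relevant stepwise pK values),

    dG_dep = (pK_cumulative - m * pH) * R * T * ln(10)

which is the log-space form of the equilibrium expression
K' = K * [H+]^m. A ligand already anionic at the working pH (e.g.
ascorbate at pH 7.4, pKa 4.1) is configured with m = 0 and pays
nothing; a clamped negative penalty would artificially stabilize its
complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import LN10, PH_DEFAULT, T_DEFAULT, rt_kcal


@dataclass(frozen=True)
class DeprotonationSpec:
    """Deprotonation requirement for one ligand at a stated pH and T."""

    ligand_label: str
    m: int  # protons removed per ligand
    pK_cumulative: float = 0.0
    pH: float = PH_DEFAULT
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if not math.isfinite(self.pK_cumulative):
            raise ValueError("pK_cumulative must be finite")


def deprotonation_penalty(spec: DeprotonationSpec) -> float:
    """Gibbs penalty (kcal/mol) to deprotonate one ligand at the given pH.

    Returns exactly 0 for m = 0; may be negative when the cumulative pK
    lies below m * pH (the anion already dominates).
    """
    if spec.m == 0:
        return 0.0
    return (spec.pK_cumulative - spec.m * spec.pH) * rt_kcal(spec.T) * LN10


def penalty(pK_cumulative: float, m: int, pH: float = PH_DEFAULT, T: float = T_DEFAULT) -> float:
    """Convenience wrapper around :func:`deprotonation_penalty`."""
    return deprotonation_penalty(
        DeprotonationSpec(ligand_label="", m=m, pK_cumulative=pK_cumulative, pH=pH, T=T)
    )
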