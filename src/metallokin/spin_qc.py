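"""Spin-contamination quality control for open-shell species.

An uncontaminated wavefunction with n unpaired electrons has
<S^2> = S(S+1) with S = n/2: 0.75 for a doublet (1 unpaired electron),
6.00 for a quintet (4) and 8.75 for a sextet (5). Species whose
annihilated <S^2> deviates beyond tolerance are flagged so their
energies can be treated with suspicion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .species_io import SpeciesRecord

TOL_ABS_DEFAULT = 0.05
TOL_REL_DEFAULT = 0.10


@dataclass(frozen=True)
class SpinCheck:
    label: str
    n_unpaired: int
    expected_s2: float
    observed_s2: float
    deviation: float
    contaminated: bool


def expected_s2(n_unpaired: int) -> float:
    """S(S+1) with S = n/2 for n unpaired electrons."""
    if n_unpaired < 0:
        raise ValueError(f"n_unpaired must be >= 0, got {n_unpaired}")
    s = n_unpaired / 2.0
    return s * (s + 1.0)


def contamination_flag(
    observed_s2: float,
    n_unpaired: int,
    tol_abs: float = TOL_ABS_DEFAULT,
    tol_rel: float = TOL_REL_DEFAULT,
    label: str = "",
) -> SpinCheck:
    """Flag a species whose |<S^2> - S(S+1)| exceeds
    max(tol_abs, tol_rel * expected)."""
    if observed_s2 < 0:
        raise ValueError(f"observed_s2 must be >= 0, got {observed_s2}")
    exp = expected_s2(n_unpaired)
    dev = observed_s2 - exp
    threshold = max(tol_abs, tol_rel * exp)
    return SpinCheck(
        label=label,
        n_unpaired=n_unpaired,
        expected_s2=exp,
        observed_s2=observed_s2,
        deviation=dev,
        contaminated=abs(dev) > threshold,
    )


def qc_species(
    species: Iterable[SpeciesRecord],
    tol_abs: float = TOL_ABS_DEFAULT,
    tol_rel: float = TOL_REL_DEFAULT,
) -> list[SpinCheck]:
    """Run contamination checks over a species table.

    Uses the post-annihilation <S^2> when available, otherwise the
    pre-annihilation value with a warning; species without any <S^2>
    are skipped (closed-shell entries usually omit it).
    """
    checks = []
    for rec in species:
        s2 = rec.s2_after
        if s2 is None:
            if rec.s2_before is None:
                continue
            warnings.warn(
                f"{rec.label}: no post-annihilation <S^2>; using the "
                "pre-annihilation value",
                stacklevel=2,
            )
            s2 = rec.s2_before
        checks.append(
            contamination_flag(
                s2, rec.unpaired_electrons, tol_abs=tol_abs, tol_rel=tol_rel, label=rec.label
            )
        )
    return checks
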