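# metallokin

Thermodynamics and kinetics toolkit for assessing **secondary antioxidant
activity of metal chelators** — ligands such as pyridoxamine (PM),
ascorbate (ASC) and Amadori compounds (AMD) that bind Cu(II) or Fe(III)
and thereby slow the first, metal-reduction step of the Haber–Weiss
cycle (the source of hydroxyl radicals in oxidative stress and protein
glycation).

It is aimed at computational chemists who already have solution-phase
standard Gibbs energies (e.g. from a DFT/continuum-solvation workflow)
and need the downstream analysis done consistently:

**Complexation thermodynamics.** For a chelation equilibrium
`x L + [M(H2O)c]^q+ ⇌ [M(L)x(H2O)n]^(q−x)+ + (c−n) H2O (+ x·m H+)`
the formation free energy is

```
ΔGf° = ΣG°(products) − ΣG°(reactants) + ΔG_std-state + x·ΔG_dep
Kf   = exp(−ΔGf°/RT),   logKf = −ΔGf°/(RT ln 10)
```

where `ΔG_dep = (pK_cum − m·pH)·RT·ln 10` is the pH-dependent cost of
bringing a ligand from its dominant protonation state to its chelating
anion (m protons removed, cumulative pK), and the standard-state term
moves every solute to the 1 M convention.

**Electron-transfer kinetics.** The outer-sphere reduction
`M(ox)Lx + Ox⁻ → M(red)Lx + Ox` (Ox⁻ = superoxide or ascorbate) is
treated with Marcus theory, `ΔG‡ = (λ/4)(1 + ΔG°/λ)²`, the Eyring
equation `k = (k_B T/h)·e^(−ΔG‡/RT)`, and — for k above 10⁸ M⁻¹ s⁻¹ —
a Collins–Kimball diffusion correction built on Stokes–Einstein
diffusion coefficients and the Smoluchowski encounter rate.
Antioxidant strength is reported as the fold-reduction
k(hydrated ion)/k(complex).

A seeded synthetic-data generator emulates DFT-style G° tables with a
known additive per-ligand binding structure, so the whole pipeline is
testable end to end, including parameter recovery.

## Worked example

```python
from metallokin import (
    DiffusionParams, apparent_rate, formation_constant,
    marcus_activation, penalty, ph_corrected_formation, rate_ratio,
)

# pH-corrected stability of a 1:2 Cu(II)-pyridoxamine chelate:
# PM is a protonated zwitterion at pH 7.4 and sheds two protons
# (cumulative pK 20.08) to reach its chelating anion.
dep = penalty(pK_cumulative=20.077, m=2, pH=7.4, T=298.15)
dgf = ph_corrected_formation(-43.0, x=2, dep_penalty_per_ligand=dep)
kf, logkf = formation_constant(dgf, T=298.15)

# reduction kinetics: hydrated ion vs chelate
free = apparent_rate(marcus_activation(-35.0, 40.0),
                     params=DiffusionParams(radius_a=2.0, radius_b=2.0))
chelate = apparent_rate(marcus_activation(-2.0, 48.0))
print(rate_ratio(free.k_app, chelate.k_app))
```

prints

```
deprotonation penalty per ligand: 7.2 kcal/mol
pH-corrected dGf: -28.6 kcal/mol  ->  Kf = 9.23e+20, logKf = 20.97
hydrated ion: dG_act = 0.16 kcal/mol, k_app = 7.41e+09 /M/s (diffusion applied: True)
chelate:      dG_act = 11.02 kcal/mol, k_app = 5.19e+04 /M/s
fold reduction: 1.43e+05
```

Reading: paying the 2 × 7.2 kcal/mol deprotonation cost leaves the
chelate with logKf ≈ 21 (still overwhelmingly formed at physiological
pH), the nearly barrierless reduction of the free ion is clamped at the
aqueous diffusion limit (~7.4 × 10⁹ M⁻¹ s⁻¹), and the chelate's
11 kcal/mol Marcus barrier slows hydroxyl-radical-producing reduction
by five orders of magnitude — strong secondary antioxidant activity.

## Command line

```
metallokin synth    --seed 42 --out-dir fixtures/        # synthetic fixtures
metallokin validate --species species.csv --reactions reactions.json
metallokin thermo   --species species.csv --reactions reactions.json \
                    --config config.yaml --pH 7.4 --out results.json
metallokin kinetics --et et.json --out rates.json
metallokin qc       --species species.csv                # spin contamination
metallokin report   --thermo results.json --rates rates.json --out report.md
```

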