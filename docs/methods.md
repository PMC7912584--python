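# Methods

## Scope and model

`metallokin` post-processes solution-phase standard thermochemistry: it
takes per-species standard Gibbs energies G° (298.15 K reference state)
as *inputs* and computes complexation thermodynamics and
electron-transfer kinetics from them. It performs no electronic
structure: G°, vertical energy gaps, ΔG°_ET and pK values all come from
the user (or the synthetic generator).

### Chelation equilibria

Complex formation from the hydrated ion is written

    x L + [M(H2O)c]^q+  ⇌  [M(L)x(H2O)n]^(q−x)+ + (c−n) H2O (+ x·m H+),

with c = 4 (square-planar Cu(II)) or c = 6 (octahedral Fe(III)). The
raw reaction energy is the species-energy balance
ΔG_raw = Σ coeff·G°(products) − Σ coeff·G°(reactants). Two corrections
produce the reported ΔGf°:

1. **Standard state.** Under `one_molar_all` (default) each non-proton
   species contributes RT·ln(24.46) per unit of net stoichiometric
   change (gas 1 atm → solution 1 M). Under
   `one_molar_solutes_55M_water` released/consumed water additionally
   carries RT·ln(55.34), treating the solvent at its own liquid
   concentration. Both conventions are exposed because published
   chelation data use either; protons are always excluded since they
   are handled through pK values, not explicit concentrations.

2. **Deprotonation penalty.** A ligand whose dominant form at the
   working pH is not the chelating anion pays
   ΔG_dep = (pK_cum − m·pH)·RT·ln 10 per ligand, m protons removed with
   cumulative pK. The penalty is **added** to ΔG_raw — it reduces the
   stability magnitude, which is the only sign consistent with a
   protonation cost. Ligands already anionic at the working pH (e.g.
   ascorbate, pKa 4.1, at pH 7.4) are configured with m = 0 rather
   than given a negative penalty: crediting the ligand for being easy
   to deprotonate would artificially inflate complex stability relative
   to the convention under which the benchmark values were derived.

Formation constants are evaluated in log space first,
logKf = −ΔGf°/(RT·ln 10), so strongly bound complexes
(|ΔGf°| > 60 kcal/mol, logKf > 44) never overflow the exponential.
Stability rankings order ligands by the |ΔGf°| of their best complex,
ties broken lexicographically.

### Electron-transfer kinetics

The reduction M(ox)Lx + Ox⁻ → M(red)Lx + Ox is outer-sphere electron
transfer. The activation energy uses the classical Marcus quadratic,
ΔG‡ = (λ/4)(1 + ΔG°/λ)², which is non-negative, has its activationless
point at ΔG° = −λ and exhibits the inverted region beyond it. λ is
either a direct input or the single-point estimate λ = ΔE_vertical −
ΔG°_ET; a four-point (Nelsen-style) decomposition is not implemented —
callers with four-point data should feed the resulting λ directly.

Rate constants follow conventional transition-state theory,
k = (k_B T/h)·exp(−ΔG‡/RT), with the universal prefactor applied
against the 1 M bimolecular standard state (6.21 × 10¹² at 298.15 K).

### Diffusion correction

When k_act strictly exceeds 10⁸ M⁻¹ s⁻¹ the apparent constant is the
Collins–Kimball combination k_app = k_act·k_D/(k_act + k_D) with the
steady-state Smoluchowski encounter rate k_D = 4π·R_AB·(D_A + D_B)·N_A
·10³ and Stokes–Einstein diffusion coefficients D = k_B T/(6πηa).
Defaults: water viscosity 8.91 × 10⁻⁴ Pa·s at 298.15 K (standard
tabulated value), reaction distance R_AB = sum of the two Stokes radii,
per-species radii from the species table (3 Å generic default in the
CLI). With 2 Å reactants in water this yields k_D ≈ 7.4 × 10⁹ M⁻¹ s⁻¹,
the familiar aqueous diffusion limit and the scale of the measured
reduction of hydrated Cu(II) by superoxide (8.1 × 10⁹ M⁻¹ s⁻¹).
No Debye–Hückel electrostatic work term is applied to k_D for charged
pairs; for ions of opposite charge at physiological ionic strength this
can shift k_D by a factor of ~2, which users should keep in mind when
comparing absolute apparent constants.

### Antioxidant metrics and speciation

Fold-reduction = k(hydrated-ion reference)/k(complex), reported to
3 significant figures. Ratios within 5% of unity are classified
"neutral" (marginal values like 0.89–1.02 carry no mechanistic weight),
above as "inhibits", below as "accelerates".

Speciation distributes total metal over free ion and 1:1 … 1:N
complexes using cumulative constants β_i (stepwise constants are
converted by summing logK). The free-ligand concentration is the root
of the ligand mass balance on [0, L_total] — the balance is monotone in
L, so the bracket always contains exactly one root — refined by Brent's
method to machine precision; metal fractions then sum to 1 by
construction and ligand is conserved to better than 1 part in 10⁹.

### Spin quality control

Open-shell species are checked against ⟨S²⟩ = S(S+1), S = n/2: 0.75 for
a doublet (one unpaired electron, Cu(II) d⁹), 6.00 for a quintet
(high-spin Fe(II) d⁶) and 8.75 for a sextet (high-spin Fe(III) d⁵). A
species is flagged when |⟨S²⟩_obs − S(S+1)| > max(0.05, 0.10·S(S+1));
both tolerances are configurable since "negligible contamination" has
no universal numeric cutoff. The post-annihilation value is used when
present, else the pre-annihilation value with a warning.

## Synthetic data generator

The generator emulates the statistical structure of real chelation
series — per-ligand additive stability, where 1:2 complexes are roughly
twice as stable as 1:1 — without emulating electronic structure. For
each ligand L and stoichiometry x it draws

    ΔG_raw(L, x) = x·μ_L + ε,   ε ~ Normal(0, noise_sd²),

and back-constructs mutually consistent absolute G° values (at the
10⁵–10⁶ kcal/mol magnitudes typical of solution-phase DFT energies) for
metal-aqua, ligand, water and complex species, so the table exercises
the same large-number cancellation as real data. Noise is placed on the
reaction ΔG, not per-species G°, with independent draws — the simplest
structure matching the additive trend. Defaults: μ(PM) = −18,
μ(AMD) = −15, μ(ASC) = −12 kcal/mol (the per-ligand increments implied
by the benchmark tables), noise_sd = 0.5 kcal/mol, stoichiometries
1–3, λ ~ U(20, 60) and ΔG°_ET ~ U(−40, 10) kcal/mol for the
electron-transfer draws, ⟨S²⟩ contamination SD 0.01. All output is a
deterministic function of the seed.

What it does **not** emulate: correlations between H° and G°, geometry-
or coordination-dependent deviations from additivity, conformer
multiplicity, and systematic (method-level) energy errors. Passing
recovery tests therefore demonstrate that the pipeline arithmetic and
the regression are correct under the stated noise model, not that any
particular DFT protocol is accurate.

Parameter recovery fits ΔG_raw = μ·x through the origin per ligand
(μ̂ = Σx·ΔG/Σx², analytic SE = √(RSS/(k−1)/Σx²)); with stoichiometries
1–3 and noise 0.5 kcal/mol the estimator SE is 0.134 kcal/mol, and the
Monte-Carlo mean absolute error over replicate seeds sits near the
Gaussian expectation √(2/π)·SE ≈ 0.107, comfortably within the 3·SE
calibration bound checked by the tests.

## Numerical and design choices

- R = 1.9872042586 × 10⁻³ kcal mol⁻¹ K⁻¹ everywhere; T defaults to
  298.15 K, pH to 7.4 (RT·ln 10 = 1.3643 kcal/mol at default T).
- hartree → kcal/mol by the CODATA factor 627.5094740631 on input only;
  all internal energies are kcal/mol.
- The diffusion threshold comparison is strict (k_act > 10⁸): a rate
  exactly at the threshold is left uncorrected.
- Energies in result tables print at publication precision (ΔGf° to one
  decimal, logKf to two, constants to three significant figures); the
  JSON format keeps full precision and round-trips losslessly.
- Missing optional table columns are treated as absent, never zero —
  zero is a meaningful energy.
- Benchmark regression tolerance: a ΔGf° printed to one decimal induces
  a ±0.05 envelope on logKf at 298.15 K; all 42 tabulated benchmark
  complexes fall inside it. Published fold-reduction ratios were formed
  from unrounded rate constants, so quotients of the printed constants
  are checked to within one unit in the last printed digit.
- Test problem sizes: 200 replicate seeds for recovery calibration,
  1000 random draws for the deprotonation equilibrium-form oracle,
  10⁵-point (two-stage) grids for the speciation brute-force check —
  sizes at which the Monte-Carlo statistics are stable and the whole
  suite runs in seconds.

## Known limitations

- No electrostatic (Debye–Hückel) correction to encounter rates; no
  ionic-strength dependence anywhere.
- Single-point λ only; no nonadiabatic corrections, tunneling or
  electronic-coupling elements.
- pK values are inputs; no microspeciation or tautomer enumeration.
- Speciation assumes mononuclear 1:i complexes of a single ligand; no
  mixed-ligand or polynuclear species.
- The benchmark formation energies and absolute rate constants derive
  from electronic-structure calculations outside this package's scope;
  regression checks therefore target the *derived* quantities (logKf
  from ΔGf°, ratios from rate constants), not the absolute energies.
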