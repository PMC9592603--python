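# Methods

## Scope and assumptions

`nanoexo` models vesicle-mediated exocytosis of single, unaggregated,
surface-inert nanoparticles. The governing picture: an internalized NP sits in
a transport vesicle; exocytosis requires the vesicle to cross a repulsive
barrier ΔG‡_v/m to fuse with the plasma membrane, and releases the repulsive
NP–vesicle interaction energy ΔG_np/v when the particle desorbs. The net
energy change ΔG(d) = ΔG‡_v/m − ΔG_np/v is the single covariate of a
per-cell-line Arrhenius regression on measured rate constants.

Standing assumptions, inherited from the framework the package implements:

* vesicles share the chemistry of the cell membrane they fuse with (same γ
  components and ψ₀);
* one NP per vesicle; aggregation, agglomeration and lysosomal surface
  modification are out of scope;
* ligand–receptor binding and membrane-deformation energies are not computed;
  their influence is absorbed by the empirically fitted slope β;
* a single generic cell surface (γ^LW = 39, γ^+ = 2.6, γ^− = 71 mJ/m²,
  hence γ^AB ≈ 27; ψ₀ = −40 mV) stands in for all cell lines — cell-to-cell
  differences surface only through the fitted (β, ln A).

## Energy engine

Contact free energies per unit area use the van Oss–Chaudhury–Good rules:

* ΔG^LW(d₀) = 2(√γ₃^LW − √γ₁^LW)(√γ₂^LW − √γ₃^LW)
* ΔG^AB(d₀) = 2[√γ₃^+(√γ₁^− + √γ₂^− − √γ₃^−) + √γ₃^−(√γ₁^+ + √γ₂^+ − √γ₃^+)
  − √(γ₁^+γ₂^−) − √(γ₁^−γ₂^+)]

with medium 3 = water (γ^LW = 21.8, γ^+ = γ^− = 25.5 mJ/m², the standard
20–25 °C convention; the temperature dependence of γ is ignored). Distance
laws, with R_eff = r₁r₂/(r₁+r₂) for sphere–sphere and R_eff = r for
sphere–plate:

* LW: U(d) = 2π R_eff d₀² ΔG^LW(d₀)/d (unretarded)
* AB: U(d) = 2π R_eff λ ΔG^AB(d₀) exp((d₀−d)/λ)
* EL: constant-potential Hogg–Healey–Fuerstenau,
  U(d) = π ε₀ ε_r R_eff [2ψ₁ψ₂ ln((1+e^(−κd))/(1−e^(−κd)))
  + (ψ₁²+ψ₂²) ln(1−e^(−2κd))]

Per-particle energies are multiplied by Avogadro's number and reported in
kJ/mol, the convention of the published energy table.

Parameters that matter (all configurable via the YAML config):

| parameter | default | meaning |
|---|---|---|
| d₀ | 0.157 nm | minimum contact distance |
| λ | 0.6 nm | acid–base decay length in water |
| 1/κ | 0.78 nm | Debye length (0.154 M 1:1 electrolyte, 310 K) |
| ε_r | 74 | relative permittivity of water at 310 K |
| T | 310 K | temperature (RT = 2.577 kJ/mol) |
| d_max, n_grid | 20 nm, 2000 | profile grid |
| vesicle radius | NP radius (+ offset 0) | tight single-NP wrapping |

ΔG_np/v is the maximum of the NP–vesicle total profile (for the monotone
repulsive profiles typical here, the contact value); ΔG‡_v/m is the maximum
of the vesicle–membrane profile, floored at 0 with a `no-barrier` flag when
the profile is purely attractive, so the activation term never goes negative.
Ties in the grid maximum resolve to the smallest distance. Doubling the grid
changes barriers by < 0.1%.

Choices made where the design was open: constant-potential (not
constant-charge) double-layer boundary conditions; external sphere–sphere
approach for the NP–vesicle pair (consistent with taking the profile maximum
as the interaction energy); the same ψ₀ = −40 mV on both sides of the
vesicle–membrane pair; surface potential taken equal to zeta potential when
tables provide the latter.

## Kinetics

`fit_plateau_decay` fits y(t) = (y₀ − y_eq)e^(−kt) + y_eq by bounded
nonlinear least squares (k ∈ (0, 1] /s, y_eq ∈ [0, 1]), with y₀ pinned to the
first observation so the curve passes through the normalized start — note the
plateau form is parameterized so that y(0) = y₀ exactly. Initial guesses come
from a log-linear fit of the baseline-subtracted amounts. `fit_first_order`
is the log-linear regression of ln(y/y₀) on time through the origin (falling
back to a nonlinear fit if any amount is non-positive), and `two_point_rate`
is k = ln(initial/final)/duration; on a two-point series the two coincide to
machine precision. A series whose relative range is below 10⁻⁶ is rejected as
unidentifiable. Times enter in hours; all rates are reported in /s.

## Regression and intervals

`fit_cell_model` is OLS of ln k_exo on ΔG(d) (n ≥ 3, k > 0), reporting slope
β (mol/kJ), intercept ln A, their standard errors, R² and the two-sided slope
p-value at n−2 df. β is never constrained to −1/RT: the raw Boltzmann factor
of a typical ΔG_np/v (e.g. exp(−248/2.577) ≈ 10⁻⁴²) shows the literal
activation picture cannot carry the observed rates, so the slope is an
effective, cell-line-specific coefficient. Intervals on predictions are the
standard OLS mean-response intervals on the ln scale, exponentiated;
`interval="prediction"` switches to prediction intervals (the published
validation bars could be either). Width grows with |ΔG − mean ΔG|, and
predictions outside the training range carry an extrapolation flag rather
than being refused. No multiple-testing correction is applied; no automatic
outlier exclusion is performed.

`decompose_frequency` splits A = A_vesicle · exp(−ΔG_np/v/RT) in log space so
the identity survives Boltzmann-fraction underflow. `gamma_kow_regression`
correlates coating γ components with log K_ow, the classical hydrophobicity
descriptor, as a consistency check on the surface-energy description.

## Synthetic world

The generators emulate the studied materials: neutral coated NPs with
γ^LW ∈ [20, 45], γ^+ ∈ [0, 6], γ^− ∈ [10, 75] mJ/m², diameters 8–100 nm
(the span of the published panels); rates on a true Arrhenius line with
default (β, ln A) = (−0.0017, −7.3), the fitted HeLa values, and Gaussian
noise on the ln scale (sd 0.3 — the source is silent on error structure, so
this matches the visual scatter of the published regressions); plateau-decay
curves with additive Gaussian noise (sd 0.02) on normalized amounts, floored
at 0. All generators are bit-reproducible for a fixed seed.

What a green synthetic test establishes: the pipeline recovers known ground
truth (exactly without noise, unbiased with it) and its interval machinery
has honest coverage. What it does not establish: agreement with any
particular laboratory panel — real data bring protein coronas, aggregation,
cell-line-specific surfaces and digitization error that the generators do not
model, and the per-NP surface parameters behind the published 64-row energy
table are not redistributed here, so absolute energies are validated only
against that table's structure (positivity, ordering, linear size scaling),
not row by row.

## Known limitations

* The unretarded 1/d van der Waals tail is slow: at the default d_max = 20 nm
  a sphere–plate profile with R_eff = 50 nm still carries ≈1.16 kJ/mol, so
  "profiles vanish at 20 nm" holds only below ~86 nm diameter under the
  defaults. This is a property of the adopted distance law, not a numerical
  artifact; the strict long-range check in the acceptance suite documents it.
* Constant-potential electrostatics with ψ₀ = ζ is the simplest defensible
  choice; charge regulation and slipping-plane corrections are not modelled
  (a corrected ψ₀ can simply be supplied in the input table).
* Charged NPs are accepted by the engine but the regression framework was
  conceived for neutral, lysosome-inert particles; predictions for charged
  particles are extrapolations of the surface-energy description.
* The generic-cell description makes all cell-line specificity live in
  (β, ln A); cell types with unusual membranes (e.g. activated macrophages)
  may not be well served.
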