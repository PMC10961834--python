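# Methods

`aromatherm` implements the complete experimental-plus-computational chain used
to determine and predict standard molar enthalpies of formation of benzene
carboxylic acids, with trimellitic acid (benzene-1,2,4-tricarboxylic acid,
"TMAc") as the packaged worked case. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## 1. Bomb-calorimetry reduction (`calorimetry`)

An isoperibolic static-bomb experiment is reduced with the standard identities

```
ΔT_c            = T_f − T_i − ΔT_corr
ε(cont)·ΔT_c    = ε_i(cont)·(298.15 − T_i) + ε_f(cont)·(T_f − 298.15 − ΔT_corr)
|ΔU_IBP|        = ε(calor)·ΔT_c + ε(cont)·ΔT_c − ΔU_ign
(−m·Δc u°)(s)   = |ΔU_IBP| + ΔU(HNO3) − ΔU_corr − m_oil·|Δc u°(oil)| − m_cot·|Δc u°(cotton)|
Δc u°(sample)   = −(−m·Δc u°)(s) / m_sample
```

with all energies in kJ and the released-energy sign convention (combustion
energies negative, ΔU(HNO3) negative as recorded). The adiabatic temperature
correction ΔT_corr and the Washburn standard-state correction ΔU_corr are
*inputs*: computing them requires the temperature–time record and the bomb
inventory, which the record format does not carry.

The molar chain is Δc U°m = ⟨Δc u°⟩·M, Δc H°m = Δc U°m + Δn_g·R·T with
Δn_g = z/2 − y/4 for C_xH_yO_z (liquid water product), and the Hess cycle
Δf H°(cr) = x·Δf H°(CO2,g) + (y/2)·Δf H°(H2O,l) − Δc H°m with CODATA reference
values −393.51 ± 0.13 and −285.83 ± 0.04 kJ/mol. R is fixed at CODATA
8.314462618 J/(mol·K); all constants are config-overridable.

**Uncertainty budget.** The replicate uncertainty is twice the standard
deviation of the mean of the per-run massic energies. The expanded massic
budget adds, in quadrature, the calorimeter-equivalent and auxiliary-material
uncertainties, each scaled by its mean sensitivity (∂Δcu°/∂ε = ΔT_c/m, etc.)
and doubled to the expanded level; reference uncertainties enter the formation
enthalpy scaled by stoichiometry. On the packaged seven-run table this budget
gives ±2.70 kJ/mol on Δc U°m and ±2.94 kJ/mol on Δf H°(cr).

**Buoyancy.** Mass readings are corrected with
m·(1 − ρ_air/ρ_weights)/(1 − ρ_air/ρ_sample). Defaults: air at the ambient
78.8 kPa and 298.15 K (0.00092 g/cm³) and conventional 8.0 g/cm³ steel
weights; both are configurable because neither is part of the record. The
packaged experiment table stores masses that are already buoyancy-corrected.

**Rounding.** The printed experiment table carries 4–5 significant decimals;
reducing those *rounded* inputs reproduces each per-run massic energy to
within 0.0009 kJ/g of its printed value but leaves a systematic ≈0.0005 kJ/g
offset on the seven-run mean (the original data reduction carried unrounded
intermediates). The reproduction report therefore compares values rounded to
the table resolution (4 decimals in kJ/g, 1 decimal in kJ/mol) against the
published numbers; raw unrounded values are always reported alongside.

## 2. Thermogravimetric enthalpies (`tga`)

Free evaporation through a cup of known cross-section obeys the Langmuir
relation p = (dm/dt)/(A·γ)·√(2πRT/M). Combined with Clausius–Clapeyron and a
constant absorbing the gas-phase diffusion effect, it linearizes as

```
ln[(dm/dt)·√T] = B − ΔH/(R·T)
```

so OLS of y = ln(dm_dt·√T) on x = 1/T gives ΔH at the mean trace temperature
from the slope alone — orifice area and vaporization constant cancel into the
intercept, which is why the enthalpy needs neither calibrated. The standard
uncertainty is R times the slope's standard deviation
(σ̂²/Σ(x−x̄)² with σ̂² the residual mean square at n−2 dof). Replicate runs
are combined by inverse-variance weighting, u = (Σ 1/u_i²)^−1/2.

The mean temperature defaults to the arithmetic mean of the trace
temperatures; midpoint-of-range is a fit option since the definition is
convention. Sublimation uses the identical fit on a pre-melting temperature
window, selected by filtering the input trace, not automated. Rates are taken
directly from the input; differentiating raw mass-vs-time thermograms is out
of scope.

## 3. Chickos temperature adjustments (`chickos`)

All three adjustments share the affine form
ΔH(298.15) = ΔH(T_obs) + c·(T_obs − 298.15)/1000 with c in J/(mol·K):

| process      | c                                   |
|--------------|-------------------------------------|
| sublimation  | 0.75 + 0.15·Cp(cr)                  |
| vaporization | 10.58 + 0.26·Cp(l)                  |
| fusion       | 0.15·Cp(cr) − 0.26·Cp(l) − 9.83     |

The fusion coefficient equals sublimation-minus-vaporization, keeping the
three routes thermodynamically consistent. Coefficients live in a versioned
config file (`data/chickos_coefficients.json`) rather than in code, so the
parameterization is auditable and swappable. Cp inputs may be measured (the
module fits the molar heat-capacity polynomial Cp(T), checked against a
sapphire reference) or group-estimated.

For the packaged TMAc case, Cp(cr) = 1.18 J/(g·K) × 210.140 g/mol =
247.97 J/(mol·K) comes from the DSC measurement. Cp(l) is not reported
anywhere; the packaged value 297.9 J/(mol·K) is a synthetic stand-in
back-solved so that the DSC fusion enthalpy (56.6 ± 1.6 kJ/mol at
T_fus = 521.8 K, the high-pressure-capsule DSC value, not the 507.0 K SDT
onset) adjusts to the published 45.4 kJ/mol at 298.15 K. The 45.4 / 97.1 /
144.8 kJ/mol route values are therefore treated as calibration anchors
(reconciled to ±0.5 kJ/mol), not as independent predictions.

The adjustment term's standard uncertainty defaults to 10 % of the term,
combined in quadrature with the input uncertainty. That fraction matches the
published fusion budget (1.6 → 2.0 kJ/mol over an 11.2 kJ/mol adjustment);
literature practice ranges up to 30 %, and the fraction is a parameter.

## 4. Thermochemical cycle (`cycle`)

Two routes to the sublimation enthalpy at 298.15 K are always computed and
reported side by side, with no preference:

* route A: Δcr→g H = Δfus H(298) + Δvap H(298);
* route B: the directly measured sublimation value.

Δf H°(g) = Δf H°(cr) + Δcr→g H per route. Uncertainties combine in quadrature
at every step and are rounded only at report time. On the packaged inputs this
gives 142.5 ± 2.4 (route A), −1034.9 ± 3.8 and −1032.6 ± 6.1 kJ/mol. The raw
mass-loss tables behind the vaporization (97.1 ± 1.4) and direct-sublimation
(144.8 ± 5.4) values are unpublished, so those enter the packaged chain as
recorded inputs.

## 5. Benson group additivity (`benson`)

The decomposition covers the benzene + COOH/CH3 family: per COOH one
`CO-(O)(CB)`, one `O-(H)(CO)` and a `CB-(CO)(CB)2` ring carbon; per CH3 a
methyl group and a `CB-(C)(CB)2` ring carbon; `CB-(H)(CB)2` for the remaining
ring positions (the six ring-carbon groups always sum to 6). Every unordered
substituent pair produces a positional correction slot keyed by ring distance
(ortho/meta/para). Any molecule outside this family can be supplied as a
hand-written group vector.

Design choices that the published comparison tables pin down:

* **Methyl convention.** In original-Benson mode a ring methyl is always
  valued as `C-(H)3(C)`: Benson's convention makes the methyl value
  independent of attachment, and this (not the catalog's partially filled
  `C-(H)3(CB)` slot) reproduces the published 4-methylbenzoic estimates in
  both phases (327.2 gas / 425.7 cr).
* **Pair corrections.** No COOH–CH3 or para COOH–COOH correction is applied
  by default (terephthalic and 4-methylbenzoic reproduce as plain sums). The
  ortho/meta COOH–COOH corrections used for the di-/tri-acid rows are not
  printed in the source; the module ships a clearly-labelled *inferred* set
  (gas +29.16/+2.56, cr +34.18/+13.18 kJ/mol) back-derived self-consistently
  from the published phthalic/isophthalic/tricarboxylic rows, used only for
  self-consistency checks. Default corrections are zero.
* **Signs.** The catalog stores signed Δf H contributions; comparison tables
  report magnitudes of −Δf H, matching the published presentation.

## 6. MLR reparameterization (`mlr`)

Group values are refit by no-intercept OLS on a molecules × features count
matrix (groups + correction columns): ŵ = argmin Σ(y_i − Σ_j x_ij w_j)².
Hold-out evaluation uses scikit-learn's `train_test_split` (so the published
seeds 98 / 832 for the gas/crystal fits reproduce the same partitions), with
ceil(n·0.3) test molecules; metrics are R², MAE and RMSE on both sides.
Exactly dependent columns are dropped deterministically (later column goes,
mirroring the dummy-variable remedy) before fitting; residual rank deficiency
raises a multicollinearity error. The collinearity report gives the design's
condition number, maximal pairwise correlations (flag threshold 0.95) and
exactly aliased column sets. Prediction refuses features the fit never
retained rather than extrapolating silently.

The 55/67-molecule training tables and the per-molecule feature assignments
behind the published refit are unpublished, so the refit itself cannot be
reproduced number-for-number; the module's correctness is instead established
against a brute-force normal-equations oracle and by parameter-recovery
studies on synthetic datasets (below). The reparameterized catalog columns are
carried as data for prediction use.

## 7. Synthetic generators (`synthetic`)

Each generator inverts its pipeline stage exactly at zero noise (round trips
≤ 1e−9) and injects noise where measurement error physically enters:

* **Combustion** — solves the content-term-linear equation for T_f from a true
  massic energy; Gaussian noise on T_f (default truth: ~1 g samples at
  −15.3489 kJ/g, the packaged study conditions).
* **TGA** — dm/dt = exp(B − ΔH/(R·T))/√T on a 310–360 K grid with
  multiplicative lognormal rate noise; the default 91.4 kJ/mol magnitude
  mirrors the pyrene validation standard.
* **GC dataset** — integer counts from Poisson(1.2) clipped to 0–6 (the
  natural range and collinearity of benzene-substitution features), full
  column rank enforced by redraw, y = X·w + Gaussian noise; an option injects
  an exactly duplicated column for degeneracy tests.

What they do not emulate: real DSC endotherms, raw thermograms, temperature
drift within a trace, correlated replicate errors, or the structural
correlations of a hand-curated molecule set. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated error model, not
robustness to instrument artifacts.

## 8. Verification summary

The test suite checks, among others: every printed per-run massic energy
(±0.002 kJ/g) and the derived molar chain at table resolution; the uncertainty
budget against the published ±2.7/±2.9; the cycle sums and combined
uncertainties 2.4/3.8/6.1; the uncorrected group-additivity entries (±0.1);
OLS ≡ normal equations on random systems; 2σ/3σ recovery coverage over
hundreds of seeded noisy replicates; and byte-stability of the end-to-end
report. Problem sizes (7 runs, 10-point traces, n = 55 datasets, 100–200
replicates) follow the packaged study conditions and keep the whole suite in
a few seconds.

## Known limitations

* Washburn and adiabatic corrections are consumed, never computed.
* Combustion chemistry is limited to C/H/O compounds.
* Group perception is rule-based for one scaffold family, not graph-based.
* The Chickos Cp(l) for TMAc and the ortho/meta acid–acid corrections are
  inferred stand-ins, labelled as such where they appear.
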