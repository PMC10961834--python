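# aromatherm

Thermochemistry of benzene carboxylic acids: a tested Python implementation of
the full experimental data-reduction and prediction chain for standard molar
enthalpies of formation — bomb-calorimetry reduction, thermogravimetric
vapor-pressure enthalpies, Chickos temperature adjustments, thermochemical
cycles, Benson group additivity, and multiple-linear-regression
reparameterization of group values. The packaged worked case is trimellitic
acid (benzene-1,2,4-tricarboxylic acid, TMAc).

It is written for thermochemists and cheminformaticians who want the whole
chain — from raw bomb/TGA records to gas-phase formation enthalpies and
group-contribution predictions — as auditable, reusable library code rather
than spreadsheet arithmetic.

## The science in brief

* **Calorimetry.** Isoperibolic bomb records (masses, temperatures,
  energy-equivalent and correction terms) reduce to the standard massic
  combustion energy via
  Δc u° = −[|ΔU_IBP| + ΔU(HNO₃) − ΔU_corr − m·|Δc u°|(aux)]/m_sample,
  then to Δc U°m = ⟨Δc u°⟩·M, Δc H°m = Δc U°m + Δn_g·R·T, and by Hess cycle to
  Δf H°(cr) = x·Δf H°(CO₂,g) + (y/2)·Δf H°(H₂O,l) − Δc H°m.
* **Thermogravimetry.** The Langmuir relation p ∝ (dm/dt)·√(T/M) plus
  Clausius–Clapeyron linearize to ln[(dm/dt)√T] = B − ΔH/(R·T); the OLS slope
  gives the vaporization/sublimation enthalpy with u = R·sd(slope).
* **Chickos adjustment.** ΔH(298.15 K) = ΔH(T) + c·(T − 298.15)/1000 with
  c = 0.75 + 0.15·Cp(cr) (sublimation), 10.58 + 0.26·Cp(l) (vaporization) and
  their difference (fusion).
* **Cycle.** Δf H°(g) = Δf H°(cr) + Δcr→g H by two routes (fusion +
  vaporization, and direct sublimation), uncertainties in quadrature.
* **Group additivity.** Substituted benzenes decompose into Benson groups
  (e.g. benzoic acid → CO-(O)(C_B) + O-(H)(CO) + C_B-(CO)(C_B)₂ +
  5 C_B-(H)(C_B)₂) with ortho/meta/para pair-correction slots; −Δf H is the
  count-weighted sum of catalog values. An MLR module refits the catalog from
  a molecules × groups count matrix with hold-out evaluation (R², MAE, RMSE)
  and collinearity diagnostics.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from aromatherm.workbench import reproduce_tmac, RunConfig

report = reproduce_tmac(RunConfig())   # packaged seven-run experiment table
cal = report["calorimetry"]
print(round(cal["du_mean_kJ_per_g"], 4))        # -15.3494  kJ/g
print(round(cal["dcU_m_kJ_per_mol"], 1))        # -3225.5   kJ/mol
print(round(cal["dfH_cr"]["value"], 1),
      round(cal["dfH_cr"]["u"], 1))             # -1177.3 2.9  kJ/mol
print(round(report["cycle"]["sublimation_routeA"]["value"], 1),
      round(report["cycle"]["sublimation_routeA"]["u"], 1))   # 142.5 2.4
print(round(report["cycle"]["formation_g_routeA"]["value"], 1))  # -1034.8
print(report["benson"]["benzoic_gas"])          # 294.75  (magnitude of -dfH, gas)
```

Reading: the seven bomb runs average −15.3494 kJ/g of sample; scaled by the
molar mass and corrected for the gas-mole change this gives a crystalline
formation enthalpy of −1177.3 ± 2.9 kJ/mol; adding the fusion+vaporization
sublimation route (142.5 ± 2.4 kJ/mol) yields the gas-phase formation
enthalpy −1034.8 ± 3.8 kJ/mol. The Benson sum for benzoic acid (294.75)
reproduces the published group-additivity estimate of 294.8.

The same chain is scriptable from the shell:

```bash
aromatherm reproduce-tmac --out report.json
aromatherm benson --molecule benzoic.json --phase gas
aromatherm mlr-fit --dataset dataset.csv --seed 98 --out model.json
aromatherm simulate tga --seed 7 --n 10 --noise-sd 0.01
```

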