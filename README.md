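# cryoevb

Desk-scale analysis of enzyme cold-adaptation: empirical valence bond
(EVB) free-energy profiles, Arrhenius enthalpy–entropy decomposition,
transition-state-theory rates, and surface-loop flexibility (RMSF)
comparison.

Cold-adapted (psychrophilic) enzymes keep their catalytic rate near 0 °C
by repartitioning the activation free energy: compared to a mesophilic
ortholog with the same ΔG‡, they show a much lower activation enthalpy
ΔH‡, paid for by a more negative activation entropy ΔS‡.  Because the
temperature-dependent part of the Eyring rate is e^(−ΔH‡/RT), the
low-enthalpy variant wins at low temperature.  The canonical example is
the elastase pair from Atlantic salmon (SPE, psychrophilic) and pig (PPE,
mesophilic): ΔH‡ = 4.6 vs 17.2 kcal/mol and TΔS‡ = −13.4 vs −2.0
kcal/mol at 22 °C, at nearly identical barriers (18.0 vs 19.2 kcal/mol).
The difference has been traced to the flexibility of a handful of surface
loops, whose RMSF is some 30–40% higher in the psychrophile.

`cryoevb` implements the complete computational pipeline for quantifying
this partitioning —

* a two-state EVB energy model (ground surface
  Eg = ½(ε₁+ε₂′) − ½√((ε₁−ε₂′)² + 4H₁₂²), energy-gap reaction coordinate
  X = ε₁ − ε₂′, gas-phase shift Δα = 195.0, coupling H₁₂ = 113.0
  kcal/mol);
* free-energy perturbation over 51 mapping windows with the EVB umbrella
  correction, ΔG(X_b) = ΔG(λ_m) − RT ln⟨δ_b(X)·e^(−(Eg−ε_m)/RT)⟩_m;
* Arrhenius decomposition (ΔG‡/T vs 1/T: slope ΔH‡, intercept −ΔS‡) over
  285–305 K, with the replicate-growth rule (50 replicates, +10 until
  R² > 0.8) and bootstrap uncertainties;
* Eyring rates k = (k_BT/h)e^(−ΔG‡/RT) and variant-comparison arithmetic;
* Kabsch superposition, iterative average structures, per-atom RMSF and
  per-loop percent changes versus a reference variant

— driven by a calibrated **surrogate reactive system** in place of
cluster-scale all-atom MD: harmonic EVB diabats plus a bath of harmonic
modes whose stiffness rises at the transition state.  Classically the
bath contributes no enthalpy, only entropy, so the surrogate's ΔH‡ and
ΔS‡ are independently dialable and analytically known — every estimator
in the pipeline can be checked against a closed form.  Sixteen presets
reproduce the published activation parameters of the two wildtypes and
fourteen designed loop mutants.

## Worked example

```python
import dataclasses
from cryoevb import build_variant, analytic_profile
from cryoevb.study import recover_wildtype_parameters

spe = build_variant("SPE_like")          # calibrated psychrophile surrogate
prof = analytic_profile(spe, 295.15)     # closed-form free-energy profile
print(f"dG_act = {prof.dg_activation:.2f} kcal/mol")

out = recover_wildtype_parameters(master_seed=7)   # ~2 min: samples
for name, r in out.items():                        # 10 reps x 5 T x 51 windows
    p = r["params"]
    print(f"{name}: dH = {p.dh:.2f}, TdS(22C) = {p.tds_ref:.2f}, "
          f"dG(22C) = {p.dg_ref:.2f}  declared {r['declared']}")
```

prints

```
dG_act = 18.00 kcal/mol
SPE_like: dH = 5.28, TdS(22C) = -12.72, dG(22C) = 18.00  declared (4.6, -13.4)
PPE_like: dH = 17.14, TdS(22C) = -2.04, dG(22C) = 19.18  declared (17.2, -2.0)
```

i.e. the sampled pipeline recovers each preset's declared
enthalpy–entropy split within its bootstrap uncertainty (≈ ±1 kcal/mol at
10 replicates), and the barriers to a few hundredths of a kcal/mol.

For the rate layer alone, printed activation parameters are enough:

```python
from cryoevb import ActivationParameters, rate_table
from cryoevb.thermo import T_REF

wt = ActivationParameters("SPE wildtype", T_REF, dh=4.6, ds=-13.4 / T_REF)
print(rate_table([wt]))
```

```
        variant  temp_c  temp_k   k_per_s     k_x100
0  SPE wildtype     4.0  277.15  0.162976  16.297640
1  SPE wildtype    22.0  295.15  0.288847  28.884684
2  SPE wildtype    39.0  312.15  0.468261  46.826057
```

The 22 °C entry reproduces the published 28.9 (×100 s⁻¹) exactly; the
4 °C and 39 °C entries differ in the last digits because the published
table was computed from unrounded fit parameters.

## Command line

```bash
cryoevb validate run.toml          # check a TOML configuration
cryoevb report --config run.toml   # full pipeline -> table1/table2 CSVs,
                                   # Arrhenius plot, profiles, provenance
cryoevb simulate --variant SPE_like --out frames/   # persist frame tables
cryoevb profile frames/ --out profile.tsv
cryoevb arrhenius barriers.csv --out params.json
cryoevb rates params.json
cryoevb compare wt.json mut.json
cryoevb flex wt.pdb mut.pdb --regions loops.csv --reference wt
```

An empty configuration file reproduces the reference protocol (51
windows; 285/290/295/300/305 K; 50 replicates growing by 10 until
R² > 0.8).  Everything is deterministic given the master seed; reports
rerun byte-identically.

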