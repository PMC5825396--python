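# crosscell

**Population-based cross-cell-type translation of cardiac electrophysiology
drug responses.**

Drug screens are increasingly run on cardiomyocytes derived from induced
pluripotent stem cells (iPSC-CMs), but these cells are electrophysiologically
immature: the same ion-channel block can change their action potential (AP)
and Ca²⁺ transient (CaT) very differently than it changes an adult
ventricular myocyte's. `crosscell` builds a statistical bridge between the
two. It simulates *heterogeneous populations* of two mechanistic cell
models — every cell gets its own random expression profile, and the **same**
profile is applied to both cell types — measures a panel of AP/CaT biomarkers
under multiple experimental conditions, and fits a regression that translates
source-cell measurements into target-cell predictions.

The core objects and steps:

* **Populations.** The 13 shared ion-transport maximal rates
  (G_Na, G_K1, G_Kr, G_Ks, G_to, G_CaL, K_NCX, K_NaK, G_pCa, G_bNa, G_bCa,
  K_RyR, K_SERCA) are multiplied by log-normal scale factors
  (log-mean 0, log-SD σ = 0.2624, so 95% of factors lie in 60–167% of
  control).
* **Conditions.** Pacing at 0.5/1/2 Hz and raised/lowered extracellular
  Ca²⁺, Na⁺, K⁺; spontaneous beating for the immature cell kind. Conditions
  where >25% of cells show abnormal dynamics (afterdepolarizations,
  repolarization failure) are dropped.
* **Biomarkers.** APD90, APD50, time above −60 mV, V_peak, V_rest, CaT
  amplitude, diastolic/peak [Ca²⁺], CaD50, CaD90, e-fold Ca decay time, and
  (for spontaneous cells) beating rate.
* **Translation.** Partial least squares regression (SIMPLS) of the target
  population's features **Y** on the source population's features **X**
  across all retained conditions gives the coefficient matrix **B_cross**
  (on log/z-scored scales); the number of latent components is chosen by
  five-fold cross-validated PRESS. A drug's measured feature changes in the
  source cells form a change vector that, multiplied by **B_cross**,
  predicts the drug's effect on the target cells.
* **Pharmacology.** Drugs are concentration-dependent pore blocks,
  G_drug/G_ctrl = IC50/(IC50 + [C]), including a library of 90 hypothetical
  two-target drugs (primary/secondary IC50s an e-fold apart, dosed for 50% /
  ≈27% block) and CSV catalogs of multi-target drugs.
* **Protocol ranking.** Sequential inclusion, sequential exclusion, and
  exhaustive three-condition enumeration (56 models from 8 candidates) rank
  experimental conditions by their contribution to cross-validated R².

Two fast reduced cell models (an adult-ventricular-like paced cell and a
spontaneously beating immature cell) ship as fixtures; published models can
be plugged in through the same `CellModelSpec` ODE contract. The science and
all numerical conventions are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import crosscell as cc

adult, ipsc = cc.make_fixture_models()

# one scale-factor table -> two index-aligned 600-cell populations
table = cc.draw_scale_factors(cc.PopulationConfig(n_cells=600, seed=1))
src = cc.simulate_population_features(
    ipsc, table, cc.standard_protocol_set("ipsc-like", duration_s=30.0),
    rtol=1e-5, atol=1e-7, dt_out=1.0)
tgt = cc.simulate_population_features(
    adult, table,
    [p for p in cc.standard_protocol_set("adult-like", duration_s=30.0)
     if p.protocol_id == "pace1"],
    rtol=1e-5, atol=1e-7, dt_out=1.0)

print(sorted(src.dropped))          # conditions lost to the >25% rule
fit = cc.build_cross_model(src, tgt, "pace1", seed=2)
print(fit.model.n_components)
print(fit.cv.r2_per_output[["APD90", "CaTA"]].round(3))
```

Output from this exact script:

```
['KHigh']
23
feature
APD90    0.976
CaTA     0.960
dtype: float64
```

The high-K⁺ condition is dropped (51% of the spontaneous population stops
beating or fails to repolarize there), the PRESS rule keeps 23 latent
components, and the five-fold cross-validated R² for translating the adult
cell's APD90 and CaT amplitude from immature-cell measurements is ≈0.96–0.98 —
i.e., the regression almost fully explains the across-population variation
of the target biomarkers from source-side recordings alone.

From the shell, the same pipeline is available as subcommands:

```bash
crosscell simulate-population --model fixture-ipsc --kind ipsc-like --out out/
crosscell fit-cross-model --source-features ... --target-features ... --out out/
crosscell select-protocols ...
crosscell simulate-drugs --cross-model out/cross_model.json
```

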