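# Methods

`crosscell` implements population-based cross-cell-type translation of
cardiac electrophysiology: heterogeneous populations of two mechanistic
cardiomyocyte models are simulated under a battery of experimental
conditions, action-potential (AP) and Ca²⁺-transient (CaT) biomarkers are
extracted, and a partial-least-squares regression (PLSR) is fitted that
predicts the target cell type's physiology — including pore-block drug
responses — from the source cell type's measurements.

## Population model

Cell-to-cell variability is represented by multiplying the maximal rates of
13 ion-transport pathways (G_Na, G_K1, G_Kr, G_Ks, G_to, G_CaL, K_NCX,
K_NaK, G_pCa, G_bNa, G_bCa, K_RyR, K_SERCA) by i.i.d. log-normal scale
factors with log-mean 0 and log-SD σ = 0.2624, so that 95% of factors fall
between 60% and 167% of control. One factor table defines a population; the
*same* table is applied to both cell types, which index-aligns the two
populations and is what makes the cross-cell regression possible. σ is not
calibrated to any particular experimental data set.

## Fixture cell models

Two reduced cell models ship with the package. They are deliberately small
(7 state variables) so that full populations can be simulated in seconds,
but every one of the 13 pathways appears as a separable maximal-rate factor
and the qualitative pharmacology is preserved (I_Kr block prolongs the AP,
I_CaL block shrinks the CaT, monotonically over 0.5–1.5× scalings).

State vector: membrane potential V; Na⁺-current inactivation h; I_Kr
activation x_r; L-type inactivation f; cytosolic [Ca²⁺] (µM); SR [Ca²⁺]
(µM); pacemaker-current activation y_f. Currents: instantly activating
m³h-type I_Na; inwardly rectifying I_K1; I_Kr with a slow activation gate
and instantaneous rectification; quasi-steady I_Ks and I_to; I_CaL with
voltage- and Ca-dependent inactivation and an effective reversal of +80 mV;
a reduced Na/Ca exchanger (Luo–Rudy form, Km,Na = 60 mM); Na/K pump;
sarcolemmal Ca pump; Na⁺/Ca²⁺ backgrounds; and a "funny" pacemaker current
I_f with a slowly activating gate (zero conductance in the paced model).
Ca²⁺ handling is a single cytosolic pool with SERCA uptake into, gated RyR
release from, and passive leak out of, an SR compartment.

The **paced, adult-ventricular-like** model rests at −86 mV with APD90 ≈
250 ms and CaT amplitude ≈ 0.9 µM at 1 Hz. The **spontaneous, immature
(iPSC-like)** model has weak I_K1, a nonzero I_f, smaller I_Na and SR
fluxes; it self-oscillates at ≈ 1.4 Hz with a maximum diastolic potential
of ≈ −77 mV and a larger, slower CaT. Two constructional points were found
to matter for realism of the *population*, not just the baseline cell:

* The linear I_CaL driving force must stay inward at the AP peak
  (effective reversal +80 mV). With a lower reversal the model has a
  spike-vs-plateau bistability, and the population's APD90 distribution
  becomes bimodal — a discontinuity that no linear (log-scale) regression
  can represent.
* The pacemaker current needs a slow activation gate (τ ≈ 0.15–1.5 s,
  activating below ≈ −64 mV). An instantaneous I_f either stalls the
  diastolic ascent (dead zone near −55 mV) or races the clock; the gate
  provides the hysteresis that makes the limit cycle robust across the
  log-normal population.

Kinetic shape constants (gate midpoints, slopes, time constants) are fixed
parts of the equations; the 13 transport rates plus extracellular
concentrations (Na_o, Ca_o, K_o), fixed intracellular Na⁺/K⁺, and the
pacemaker parameters are the model's named parameters. External models can
be plugged in through the same `CellModelSpec` contract (an ODE
right-hand-side plus a pathway→parameter map).

## Numerical integration

The default integrator is a compiled (numba) adaptive Dormand–Prince 5(4)
with relative tolerance 1e-6 and absolute tolerance 1e-8, cubic-Hermite
dense output on a uniform 0.5 ms grid, and exact stepping across stimulus
edges (rectangular current, 1 ms, 60 µA/µF ≈ 1.5× the paced fixture's
diastolic threshold of 39 µA/µF). The fixture equations were built to be
only mildly stiff (no gate faster than 1 ms), so an explicit pair is
reliable; a scipy LSODA reference path (`integrate(..., method="scipy")`)
is cross-checked against it in the test suite. Repeated integration is
bit-reproducible. Integration failure flags the trace rather than raising,
so population sweeps continue.

Protocols nominally run 120 s; the reduced fixtures reach steady state
within ~20 beats, and features at 30 s agree with 120 s to better than
1e-3 relative (the steady-state diagnostic — final two beats differing in
APD90 by <1% in ≥95% of cells — is asserted in the tests). Population-scale
runs in the tests and the acceptance script therefore use 30 s; the drug
panel additionally relaxes to rtol 1e-5 with 1 ms output, which changes
features by <0.4%.

## Protocols and biomarkers

The standard condition set (10 conditions) comprises pacing at 0.5/1/2 Hz
and raised/lowered extracellular Ca²⁺ (3.0/0.9 mM), Na⁺ (300/70 mM) and K⁺
(10/3 mM); for the spontaneous cell kind the baseline and all ion-override
conditions run without stimulation. Concentration overrides are applied as
parameter changes at t = 0 (no solution-exchange kinetics).

The last complete beat is segmented (from the final stimulus, or between
the last two detected upstrokes; upstroke = maximum dV/dt, detected at 10%
of peak dV/dt with a 100 ms refractory window) and eleven biomarkers are
computed: total time above −60 mV (APDm60); APD90/APD50 from the upstroke
to the interpolated crossing of V_peak − q·(V_peak − V_rest); V_peak;
V_rest (potential at the stimulus for paced beats, minimum diastolic
potential otherwise); CaT amplitude, diastolic and peak [Ca²⁺]; CaD50/CaD90
from the Ca 10%-rise point to 50%/90% return toward the within-beat
baseline; and the e-fold Ca decay time from the Ca peak. Spontaneous beats
add the beating rate. Undefined features (threshold never crossed) are NaN
and flag the cell. These start/baseline conventions are package choices;
they reproduce the closed-form values of triangular-AP and exponential-CaT
test fixtures to <0.5 ms.

### Abnormality screening

A beat is abnormal if: amplitude < 30 mV (`no_beat`); V never returns
below −60 mV after the upstroke (`repolarization_failure`); or a local
minimum after 50% repolarization is followed by a depolarizing excursion
≥ 2 mV (`afterdepolarization`). For cells without intrinsic automaticity
the afterdepolarization window extends over the whole remaining cycle and
an elevated potential at the stimulus onset (≥ 5 mV above the repolarized
minimum) also counts — this catches delayed afterdepolarizations and
period-2 triggered activity whose recorded beat looks clean. For
intrinsically spontaneous cells the window ends at 90% repolarization,
since their diastolic depolarization is physiological. All thresholds are
configurable. A condition is dropped from the analysis when strictly more
than 25% of the population's cells are abnormal under it; with the fixture
models this removes the high-K⁺ condition for the spontaneous population
(9 of 10 conditions retained). Flagged cells are excluded row-wise when
fitting.

## Cross-cell regression

The input matrix X holds the source population's features under all
retained conditions (one row per cell); the output matrix Y holds the
target population's features under its baseline condition. Strictly
positive features (durations, Ca levels, amplitudes, rates) are
log-transformed; voltages stay linear; all columns are z-scored with
training-set statistics. B_cross is fitted by SIMPLS (deterministic; equal
to ordinary least squares at full rank, which the tests verify against a
normal-equations oracle to 1e-8).

Model quality is assessed by k-fold (default 5) cross-validation with
seeded fold assignment: PRESS is the sum of squared held-out residuals on
the preprocessed scale, with per-fold refitting of both the preprocessing
statistics and the regression. The number of latent components is the
smallest one whose PRESS is within 5% (configurable; 0 = strict argmin) of
the minimum over 1..max_components — a parsimony rule that trades a
negligible PRESS increase for fewer components. Per-output R² is computed
from pooled held-out predictions on the log/linear transform scale, and
adjusted R² uses p = number of components (not raw predictor count).

Drug-induced changes travel on the transform scale: a change vector holds
log-ratios (post/pre, population means of per-cell paired ratios) for log
columns and differences for linear columns, is divided by the training SDs,
multiplied by B_cross, and rescaled; log-column changes are reported as
percent changes. A zero change vector maps to exactly zero.

Population sensitivity analysis reuses the same machinery at full rank on
log-outputs vs log-scale-factors; for noiseless power-law outputs the
coefficients equal the exponents (verified to ±0.02), and outputs that can
be non-positive (voltages) enter linearly as semi-elasticities.

## Protocol ranking

Conditions are ranked by greedy forward inclusion (add the condition with
the largest gain in mean cross-validated R² over all outputs), greedy
backward exclusion (drop the condition whose removal costs least), and
exhaustive enumeration of all C(n,3) three-condition models (56 for 8
candidates) scored by adjusted R². The mean over outputs is unweighted.
Full rankings are always produced; no stopping rule is applied.
Zero-variance condition blocks are excluded with a warning. Rows are
restricted to cells complete under *all* candidate conditions so that every
compared model sees the same cells.

## Pharmacology

A drug is 1–5 (pathway, IC50) targets plus a concentration [C]; each
targeted maximal rate is multiplied by IC50/(IC50 + [C]) — a static pore
block with no state-dependent binding. The hypothetical two-target library
takes 10 pathways (the 13 minus the sarcolemmal Ca pump and the two
backgrounds), forms all 90 ordered (primary, secondary) pairs with the
secondary IC50 e-fold higher, and doses at the primary IC50, i.e. 50%
primary and ≈26.9% secondary block. Graded selective block f is dosed at
[C]/IC50 = f/(1−f). Catalog CSVs (name, pathway_i, IC50_i) default the
concentration to the drug's lowest IC50.

The panel evaluation simulates paired populations (default 100 cells) with
and without each drug and reports, per drug: the direct source readout
(mean ± SD percent change of APD90/CaTA under the source baseline
condition), the cross-model prediction (population-mean change vector over
the model's input conditions pushed through B_cross), and the directly
simulated target change. Cells flagged abnormal before or after drug are
excluded from means, with the count reported. Accuracy across drugs is the
coefficient of determination about the line of identity (which can be
negative for estimates worse than the mean).

## What the fixtures do and do not show

The synthetic populations exercise every pipeline stage with realistic
structure: shared latent variability between cell types, nonlinear
feature-vs-parameter responses, conditions of very unequal information
content, abnormality-driven condition loss, and drug responses whose
magnitudes genuinely differ between cell types. Passing tests demonstrate
that the statistical machinery recovers known structure and that the
translation beats the naive source-equals-target readout *within this
model world*. They do not establish accuracy for any published adult or
iPSC myocyte model — plugging those in through the `CellModelSpec`
contract is the intended path — nor do they address kinetics-level drug
action, temperature, or beat-to-beat variability, none of which the
fixtures contain.

## Numerical and degenerate-input conventions

Ties in component selection break toward fewer components. Zero-variance
columns raise with the column named. Flat traces and amplitude < 30 mV are
`no_beat`. Fold assignment is a seeded permutation split into near-equal
folds (600 cells / 5 folds = 120 exactly). Ca and SR concentrations are
floored at 1e-6/1e-3 µM inside the RHS to keep Nernst terms defined during
transients. All randomness flows from explicit integer seeds; repeated
runs are bit-identical.

## Command-line interface

`crosscell simulate-population | fit-cross-model | select-protocols |
simulate-drugs | evaluate`, a thin layer over the library. Feature
extraction happens inside `simulate-population` (its output *is* the
feature table), so no separate extract-features subcommand exists. Every
artifact embeds the config hash and seeds.
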