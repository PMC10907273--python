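# Methods

## Model

PGK1 ("E") is tracked through 10 configurations: the seven TZ-free forms
E, E·ADP, E·BPG, E·ADP·BPG, E·ATP, E·PG, E·ATP·PG and the three TZ-bound
forms E·TZ, E·TZ·BPG, E·TZ·PG. Five free ligands (ADP, BPG, ATP, PG, TZ)
complete the 15-species state. Binding is random-order on both the
substrate side (ADP/BPG) and the product side (ATP/PG), giving two
diamonds of states joined by the reversible phosphotransfer step
E·ADP·BPG ⇌ E·ATP·PG.

The 14 reversible reactions and their rate-constant assignments
(forward/reverse):

| Reaction | Step | Rates |
|---|---|---|
| R1 | E + ADP ⇌ E·ADP | a⁺ / a⁻ |
| R2 | E + BPG ⇌ E·BPG | c⁺ / c⁻ |
| R3 | E·ADP + BPG ⇌ E·ADP·BPG | b⁺ / b⁻ |
| R4 | E·BPG + ADP ⇌ E·ADP·BPG | d⁺ / d⁻ |
| R5 | E·ADP·BPG ⇌ E·ATP·PG | k⁺ / k⁻ |
| R6 | E + ATP ⇌ E·ATP | a⁺ / a⁻ |
| R7 | E + PG ⇌ E·PG | c⁺ / c⁻ |
| R8 | E·ATP + PG ⇌ E·ATP·PG | b⁺ / b⁻ |
| R9 | E·PG + ATP ⇌ E·ATP·PG | d⁺ / d⁻ |
| R10 | E + TZ ⇌ E·TZ | η·a⁺ / a⁻ |
| R11 | E·BPG + TZ ⇌ E·TZ·BPG | η·d⁺ / d⁻ |
| R12 | E·PG + TZ ⇌ E·TZ·PG | η·d⁺ / d⁻ |
| R13 | E·TZ + BPG ⇌ E·TZ·BPG | b⁺ / b⁻ |
| R14 | E·TZ + PG ⇌ E·TZ·PG | b⁺ / b⁻ |

ATP/PG binding constants re-use the measured ADP/BPG constants (the
product-side constants have not been measured). Terazosin occupies the
nucleotide pocket, so its binding edges mirror the nucleotide edges of the
same acceptor form — association to free E scales a⁺, association to
E·BPG/E·PG scales d⁺, both by the dimensionless factor η — and TZ
dissociation re-uses the corresponding nucleotide dissociation constants
a⁻ and d⁻. BPG/PG binding to E·TZ uses b± by analogy with binding to a
nucleotide-occupied enzyme. These assignments are a modeling choice where
direct measurements do not exist; with them the model reproduces the
observed TZ occupancy (≈93% TZ-bound at 25 µM under 1 mM ADP competition).

Net flux of a reaction is forward minus reverse mass-action rate,
positive in the direction written above. Each species' time derivative is
the signed sum of its incident fluxes; this bookkeeping identity is
asserted exactly in the tests.

The model deliberately does **not** impose thermodynamic detailed balance:
the measured constants give a⁺b⁺/a⁻b⁻ ≠ c⁺d⁺/c⁻d⁻ around the substrate
diamond, and "correcting" them would change the published behavior. The
model is a kinetic fit, not an equilibrium-consistent free-energy model.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| a⁺ / a⁻ | 6.1 / 38 | s⁻¹µM⁻¹ / s⁻¹ | nucleotide ⇌ free enzyme |
| b⁺ / b⁻ | 170 / 160 | 〃 | acid ⇌ nucleotide-occupied enzyme |
| c⁺ / c⁻ | 450 / 14 | 〃 | acid ⇌ free enzyme (c⁻ is the slow release) |
| d⁺ / d⁻ | 4.1 / 270 | 〃 | nucleotide ⇌ acid-occupied enzyme |
| k⁺ = k⁻ | 5.0 | s⁻¹ | phosphotransfer (unmeasured, assigned) |
| η | 562 | – | TZ association multiplier (chosen to place the biphasic response at the observed doses) |

Default protocol: 0.04 µM enzyme (all initially free), 1 mM ADP, 1,3-BPG
clamped at 80 µM, ATP = PG = 0, TZ ∈ {0, 2.5 nM, 25 nM, 50 nM, 0.25, 0.5,
2.5, 25 µM}, integrated to 60 s. All concentrations are µM and times
seconds internally; mM/nM are converted at the config boundary.

Clamping is a per-species flag, not hard-wired to BPG: the linear-oracle
tests clamp every ligand, which makes the 10-form enzyme subsystem exactly
linear and lets a null-space solve serve as an independent steady-state
oracle.

Terazosin is dynamic and conserved, never clamped: at 2.5 nM TZ against
40 nM enzyme, depletion of free TZ by binding is material.

## Readouts

**ATP production** is the total ATP pool [ATP] + [E·ATP] + [E·ATP·PG] at
t_end = 60 s. The pool is fed only by the phosphotransfer step (nucleotide
binding/release moves ATP between pool members), so it equals the time
integral of R5's net flux — used as a cross-check. By 60 s the production
rate has reached its quasi-equilibrium maximum, so pool-at-60 s ≈ rate ×
60 s; an instantaneous-rate readout is available as an option. The
dose–response reports 100·(ATP(tz) − ATP(0))/ATP(0).

**Occupancy** is each form's share of total enzyme at t_end. TZ-free forms
additionally report percent change versus the TZ = 0 baseline; a baseline
concentration below 10⁻¹⁵ µM makes the percent change undefined (NaN)
rather than a huge ratio. TZ-bound forms report percent of total enzyme
(their baseline is identically zero).

**Apparent Km** (`predict_apparent_km`): for each ADP concentration the
early-time production rate is the linear slope of the ATP pool over
t ∈ [0.5, 2] s — after the sub-second binding transient, before
substrate depletion — and the rates are fit to v = Vmax·S/(Km+S). The
window is configurable.

**Sweeps**: each (parameter value, TZ) cell runs a fresh simulation pair
(the TZ = 0 baseline depends on the swept parameter) and reports the
production ratio with/without TZ. The default c⁻ grid is 25 log-spaced
points spanning c⁻/b⁻ ∈ [0.005, 1.2], bracketing both qualitative regimes
and the measured value (0.0875). Cells are classified as stimulation
(ratio > 1 + ε), inhibition (< 1 − ε) or neutral with ε = 0.01 by default.
A solver failure in one cell is recorded with diagnostics and does not
abort the sweep; results are independent of evaluation order.

A note on the high-dose limit: on this parameterization the 25 µM dose
remains inhibitory for *every* c⁻/b⁻ on the default grid (its ratio
approaches 1 only from below as c⁻/b⁻ → 0). At that dose the TZ rebinding
rate η·d⁺·[TZ] ≈ 5.8·10⁴ s⁻¹ exceeds every dissociation constant, so the
enzyme cannot leave the TZ-bound cycle — the same trapping that produces
the −90% headline result. "All doses stimulate as c⁻/b⁻ → 0" therefore
holds for doses up to 2.5 µM here, not for the top of the default grid.

## Synthetic assay

`generate_assay` emulates initial-rate measurements of a Michaelis–Menten
enzyme under competitive inhibition: rates are
Vmax·S/(Km(1 + I/Ki) + S) plus additive homoscedastic Gaussian noise
(standard deviation configurable; the real assay's noise structure is not
known, so homoscedastic is the default assumption), deterministic per
seed. An inhibited dataset is mathematically an MM curve with inflated
Km, which is what `fit_mm` recovers. Fitting is direct bounded nonlinear
least squares on the hyperbola — no Lineweaver–Burk linearization — with
rates and substrate normalized to O(1) internally so convergence is
unit-independent. Standard errors are asymptotic least-squares SEs from
the Jacobian at the optimum with variance RSS/(n − 2); the Monte-Carlo
test checks they sit within a factor of two of the replicate spread. The
coupled GAPDH reporter reaction is not modeled mechanistically; the
observable is the initial rate itself.

What the synthetic generator does *not* emulate: absorbance calibration,
coupled-enzyme lag, substrate depletion within a read, or heteroscedastic
noise. Passing recovery tests therefore demonstrates correctness of the
generator/fitter pair, not robustness to every feature of real assay data.

## Numerical choices

- Stiff integration: LSODA with the analytic Jacobian, rtol 1e-9,
  atol 1e-12 µM. Conservation of enzyme, adenine and TZ totals drifts by
  ≲1e-14 relative over a default run (requirement: ≤1e-8); tightening the
  tolerances 100× moves the ATP readout by <0.1%.
- Tiny negative concentrations from the integrator (|x| < 1e-12 µM) are
  clipped to zero; anything more negative raises an error rather than
  propagating silently.
- Species and reaction orderings are fixed (the canonical tables above),
  and CSV floats are written with 12 significant digits, so identical
  configurations produce byte-identical outputs.
- The linear-oracle comparison integrates to t = 400 s at rtol 1e-12 /
  atol 1e-16 so that component-wise relative error ≤1e-6 is meaningful
  even for sparsely populated forms.

## Limitations

- The TZ rate assignments (η on a⁺/d⁺, dissociation via a⁻/d⁻) are
  analogical, not measured; alternative assignments would move the dose
  axis of the biphasic curve.
- Product-side binding constants are copies of the substrate-side ones.
- η and k± are assigned, not fit; absolute ATP numbers (and the model-side
  apparent Km of ~50 µM, versus mM-scale in the real assay) are therefore
  not quantitative predictions — the dose–response *shape* and the flux
  rerouting are the claims. Relatedly, on this parameterization low-µM TZ
  raises the fitted Vmax itself by ~20% (ADP cannot bind E·PG, so the
  bypass accelerates the saturating rate) — a stronger Vmax effect than
  real-assay data show.
- Single compartment, single set of substrate concentrations, no
  stochasticity, no SBML exchange, no thermodynamic consistency.
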