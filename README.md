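# pgktz

Mass-action kinetics of the terazosin–PGK1 interaction: how a competitive
inhibitor can *stimulate* its target enzyme.

## The problem

Phosphoglycerate kinase 1 (PGK1) catalyzes the first ATP-generating step of
glycolysis, transferring a phosphate from 1,3-bisphosphoglycerate (BPG) to
ADP to give 3-phosphoglycerate (PG) and ATP. Terazosin (TZ) binds PGK1's
ADP/ATP pocket and at high concentrations behaves as a textbook competitive
inhibitor — yet at low concentrations it *increases* PGK1 activity and
cellular ATP, a biphasic dose–response relevant to its investigation as a
neuroprotective agent.

`pgktz` implements a deterministic mass-action model that resolves the
paradox. The enzyme is tracked through 10 liganded configurations connected
by 14 reversible elementary steps (random-order substrate/product binding
on two "diamonds" joined by phosphotransfer, plus three TZ-bound forms).
Release of 3-PG from E·PG is slow (rate constant c⁻ = 14 s⁻¹); when TZ
binds E·PG, 3-PG instead leaves E·TZ·PG at the much faster b⁻ = 160 s⁻¹.
Low TZ therefore opens a *bypass cycle*

E·PG → E·TZ·PG → E·TZ → E·TZ·BPG → E·BPG → E·ADP·BPG → (phosphotransfer)

that circumvents the slow product-release step and accelerates turnover,
while high TZ traps the enzyme in the TZ-bound forms and inhibits.

The package is for modelers and enzymologists who want to simulate the
dose–response, inspect per-interaction net fluxes and enzyme-form
occupancies, map the stimulation/inhibition regimes as a function of the
c⁻/b⁻ ratio, and emulate/fit the competitive-inhibition initial-rate assay.

## The model

For each reversible interaction written `A + L ⇌ B` (rate constants k₊, k₋)
the net flux is the mass-action difference `k₊[A][L] − k₋[B]`, and the ODE
system is the signed sum of incident fluxes per species. Defaults are the
published rate constants (a: 6.1/38, b: 170/160, c: 450/14, d: 4.1/270 in
s⁻¹µM⁻¹ and s⁻¹; phosphotransfer k± = 5 s⁻¹) with TZ association scaled by
η = 562 relative to the corresponding nucleotide edge. The default protocol
is 0.04 µM enzyme, 1 mM ADP, BPG clamped at 80 µM, no products, integrated
to 60 s with a stiff solver and analytic Jacobian; "ATP production" is the
total ATP pool (free + enzyme-bound) at 60 s. See `docs/methods.md` for the
full reaction list, assumptions and numerical choices.

## Worked example

```sh
pgktz dose-response --out results/
```

prints (and writes to `results/dose_response.csv` with a JSON run manifest):

```
  tz_uM   atp_uM  percent_change
 0.0000 7.913696        0.000000
 0.0025 8.112738        2.515153
 0.0250 8.964464       13.277843
 0.0500 9.229502       16.626941
 0.2500 8.870132       12.085838
 0.5000 8.036816        1.555788
 2.5000 4.478903      -43.403145
25.0000 0.753874      -90.473804
```

Reading: without terazosin the run produces 7.91 µM ATP in 60 s. 50 nM TZ
is the most stimulatory dose (+16.6%), and 25 µM is deeply inhibitory
(−90.5%) — the biphasic signature. At 25 µM, `pgktz occupancy` shows 92.9%
of the enzyme sequestered in TZ-bound forms (90.8% as E·TZ·BPG alone).

The same model reproduces the competitive-inhibition signature seen in
initial-rate assays:

```python
>>> import numpy as np
>>> from pgktz import build_canonical_network, predict_apparent_km
>>> net = build_canonical_network()
>>> for tz in (0.0, 0.5):
...     fit = predict_apparent_km(net, tz, np.logspace(1, 4.7, 10))
...     print(f"TZ={tz} uM: apparent Km = {fit.km:.1f} uM")
TZ=0.0 uM: apparent Km = 50.5 uM
TZ=0.5 uM: apparent Km = 314.2 uM
```

Other subcommands: `simulate` (one trajectory), `fluxes` (per-reaction net
fluxes at each dose), `occupancy`, `sweep` (e.g. `--param c_minus` to map
the stimulation/inhibition regimes), `assay-generate` / `assay-fit`
(synthetic Michaelis–Menten data with additive Gaussian noise and direct
nonlinear fitting).

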