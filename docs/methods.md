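# Methods

## Model and assumptions

`peatbudget` reconstructs annual soil-organic-matter (SOM) N
mineralization in a flooded-rice peat soil from a mass balance on crop N
uptake, then converts it to soil C loss and subsidence. The chain is:

1. **Growing-season partition.** Aboveground N uptake in fertilizer-
   omission plots is treated as the sum of residue-derived N (¹⁵N pool
   dilution), surface-water N (inlet concentration × crop-adjusted ET),
   shallow-groundwater N (mesocosm contrast), atmospheric deposition,
   biological N₂ fixation, and a residual attributed to surface-peat
   mineralization. Key assumptions: the 0N crop is N-limited enough that
   uptake indexes supply; groundwater N originates from subsurface SOM
   mineralization (supported by the absence of NO₃ at depth and
   near-natural-abundance ¹⁵N signatures); deposition and fixation enter
   as exact constants.
2. **NUE adjustment.** Plants capture only a fraction (NUE) of
   mineralized N; gross mineralization is the peat-derived total divided
   by NUE. Gaseous and leaching losses are folded into this one term.
   The division is applied to the *total* peat-derived N (surface
   remainder + groundwater), matching the published ledger convention.
3. **Fallow season.** Soil NO₃-N at flood-up (assumed subsequently
   denitrified, hence a true annual loss) minus overwinter residue N
   release gives fallow peat mineralization. Unmeasured fallow losses
   make this term, and hence the total, conservative.
4. **C conversion.** Mineralized N × soil C:N (to 30 cm) = mineralized
   C; subtracting the residue C returned at tillage gives net C loss;
   dividing by SOM carbon fraction, bulk density and the SOM-share of
   subsidence (f_min) converts to cm yr⁻¹. This assumes C and N are
   oxidized in the bulk-soil stoichiometric ratio and that C:N, %C and
   bulk density are representative point values.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `n_deposition` | kg N ha⁻¹ yr⁻¹ | 6 | regional wet+dry deposition estimate |
| `n_fixation` | kg N ha⁻¹ yr⁻¹ | 25 | mid-range for cyanobacterial fixation in paddies; deliberately conservative (inflates non-SOM supply) |
| `nue` | fraction | 0.50 | common fertilizer-N uptake efficiency in rice; scanned 0.30–0.90 |
| `crop_coefficient` | – | 1.06 | flooded rice Kc |
| `som_pct_c` | g C g⁻¹ SOM | 0.58 | conventional SOM carbon fraction |
| `f_min` | fraction | 0.67 | share of recent Delta subsidence attributed to SOM oxidation |
| `se_mode` | – | `"paper"` | see *Uncertainty* |
| `mc_draws`, `mc_seed` | – | 10 000, 1432 | Monte-Carlo twin defaults |

Site-specific measured inputs (uptake, tracer, water, mesocosm, fallow,
C:N, bulk density, residue C) carry their own SEs; the packaged
`twitchell_2012` fixture holds the published site-level values for the
two Delta rice fields.

## Uncertainty

Sums and differences combine SEs in quadrature; exact conversion factors
(ET volume, C:N, 1/NUE, the kg ha⁻¹ → g cm⁻² factor) scale the SE; the
tracer product uses a first-order delta approximation. All inputs are
treated as independent (no covariances are available).

Two conventions exist for the peat-derived total. The line-by-line table
convention (`se_mode="paper"`, default) combines the surface-peat SE with
the groundwater SE — counting the groundwater SE twice, since it already
entered the surface-peat line. The `"consistent"` mode propagates the
total directly from uptake − residue − surface water − constants, in
which groundwater cancels algebraically; this is the true sampling SE of
the estimator, and it is what the Monte-Carlo twin reproduces (the MC
chain evaluates the algebra per draw, so the cancellation happens
automatically). Monte-Carlo vs analytic agreement is therefore asserted
in consistent mode; the default mode is retained for fidelity to the
published ledger. Draws are untruncated Normals by default (truncation
would bias the sd comparison); negative draws of physical quantities are
counted and warned about, with opt-in clipping.

## Synthetic data

The generator emulates the measurement design: n=4 replicate 0N plots,
n=4 labelled-residue microplots (tiller atom-% from the forward mixing
model plus instrument noise, paired with microplot uptakes), n=4 paired
mesocosms, 5 inlet-water sampling dates, 5 fallow residue plots and 4
soil cores. Replicate noise levels are calibrated so the SE of a site
mean at that replication matches the published SEs (e.g. plot sd
20 kg N ha⁻¹ → SE 10 at n=4). It does **not** emulate spatial
autocorrelation, within-season dynamics, non-Normal measurement error,
or operator/instrument drift — so passing recovery tests demonstrate
correctness of the estimators under the assumed error model, not
robustness to real-world error structure.

Two deliberate wrinkles are documented:

* Water concentrations are drawn from a zero-truncated Normal (negative
  concentrations are unphysical) while the closed-form truth keeps the
  untruncated mean; at the default noise level this leaves a ~0.8
  kg N ha⁻¹ (≈0.08 SE) bias in the surface-water line, small relative to
  every acceptance band and accepted as the price of physical realism.
* The fall/spring absolute residue-N levels (37.2/20.3 kg N ha⁻¹) are
  chosen to reproduce the published overwinter difference (16.9); only
  the difference is identified by the budget.

Parameter-recovery tests run 200 seeded campaigns and check (a) bias of
the peat-derived-N estimator below 0.5 theoretical SE and (b) ~95 %
coverage of ±1.96 SE intervals. Coverage is judged against the
scenario's closed-form theoretical SE rather than each campaign's
estimated SE: with n=4 replicates, estimated-SE intervals undercover
(~85 %) purely through small-sample SE noise (the t-vs-z effect), which
is a property of the interval construction, not of the estimator under
test.

## Numerical choices

* All arithmetic at full double precision; rounding only at report time
  (N lines 1 decimal, C lines integers, subsidence 2 decimals), mirroring
  the conventional presentation. JSON reports store 12 significant
  digits; reruns of the same configuration are byte-identical.
* Tracer fractions outside [0,1] (sample enrichment outside the
  background–input interval) are returned raw with a warning; clamping
  would bias the residue-N flux. Likewise negative budget remainders,
  groundwater contrasts and fallow mineralization are warned, never
  clipped.
* fNdr and Ndr are computed per replicate and then averaged (preserving
  replicate pairing and spread), not from averaged atom-% readings.
* The seasonal inlet mean is unweighted across sampling dates; a
  time-weighted variant would require sampling-interval metadata the
  design does not include.
* Degenerate inputs are hard errors where the estimate is undefined
  (empty replicate groups, zero tracer contrast, nonpositive NUE/C:N/
  bulk density) and warnings where it is merely uninformative (single
  replicate → SE 0).

## Problem sizes

The study system is small by construction: two sites, ≤8 replicates per
measurement. The Monte-Carlo validation uses 10⁵ draws (sd estimator
precision ≈0.2 %, comfortably inside the 3 % assertion), the recovery
study 200 campaigns; the entire test suite runs in a few seconds on one
core.

## Known limitations

* NUE is the dominant structural uncertainty; results are reported as a
  scan, not a single value, and the curve's convexity means low-NUE
  assumptions dominate the error budget.
* Fallow-season gaseous losses other than the flood-up NO₃ pool are not
  modelled; the fallow term is a lower bound.
* The C:N conversion inherits any depth- or pool-dependence of soil
  stoichiometry; an SE on C:N can be supplied to the Monte-Carlo path
  but the analytic path treats it as exact.
* Published downstream SE columns for the C-loss lines are not
  reconstructible from the published component SEs under the stated
  propagation rule; the package reports its own internally consistent
  SEs instead.
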