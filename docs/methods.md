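# Methods

## Standardization

Profiles are compared across specimens, scenarios and quantities after a
similarity transformation. For temperature,

    θ = (T − T_w) / (T_w − T_o)

with `T_w` the nasopharyngeal wall (body) temperature and `T_o` the
external/ambient temperature; analogously for absolute humidity with
`H_w` (saturation density at body temperature) and `H_o`. At the inlet
the air is still at ambient conditions, so θ = −1 exactly; at full
equilibration with the wall θ = 0. The reference pair is deliberately
read as *(wall, ambient)*: only that reading makes the inlet slice equal
−1, which every reference table prints, and it is the reading under
which profiles from 28 °C, 40 °C and 5 °C environments collapse onto one
curve. Distances are normalized by the nostrils-to-choana length `d_c`
(80.28 mm for the subadult specimen, 155.57/157.24 mm for the adults),
`d* = d/d_c ∈ [0, 1]`.

Humidity enters as absolute humidity ρ_v (kg/m³). The sources report
ρ_v without a conversion convention, so the package fixes one: Magnus
saturation pressure `e_s(T) = 6.112 hPa · exp(17.62 T / (243.12 + T))`
(valid −20…50 °C) and the ideal-gas relation `ρ_v = RH · e_s /(R_v T_K)`
with `R_v = 461.5 J/(kg K)`. This gives 0.0473 kg/m³ at 38.5 °C
saturation and 0.0163 kg/m³ at 28 °C/60 %RH, consistent with standard
psychrometric tables to ±0.0002.

### Printed-average audit

The embedded tables store the printed values verbatim (4 decimals,
typographic minus normalized to ASCII). Recomputing each table's average
column as the mean of its three printed scenario cells reproduces 128 of
the 144 printed averages exactly at 4 decimals (half-even rounding). The
remaining 16 cells differ by one unit in the fourth decimal; the pattern
(recomputed means ending in thirds, e.g. −0.250033 vs printed −0.2501)
shows the printed averages were taken over unrounded solver output
before the scenario columns were rounded for print. These cells are kept
as printed and surfaced by `standardize.audit_printed_averages`; they are
never silently "passed".

One further oddity is kept as printed: one healthy adult table repeats a
row pattern at slice 6 that breaks the local monotone trend (it matches
the subadult's outlet row); the fit and statistics consume it unchanged.

## Hyperbolic collapse

Averaged θ(d*) is fitted to

    θ(d*) = tanh((d* + α)/β) − 1

by minimizing the sum of squared residuals over (α, β), β > 0. With
α ≈ 0 the curve starts at −1 and rises toward 0, the acclimatization
signature. The derived descriptor is the slope at the inlet,
`θ'(0) = (1/β)·sech²(α/β)`: a steeper take-off means the airway
conditions air in a shorter fraction of the tract. The alternative
parsing `tanh(d*·β + α) − 1` was rejected because it cannot satisfy the
inlet condition for the fitted tables.

**Optimizer.** Deterministic and derivative-free: an exhaustive coarse
grid (α from −0.5 to 0.5 in steps of 0.01; β log-spaced, 50 points on
[0.02, 2]) picks the basin — ties broken toward smaller β by grid order —
and bounded Powell refinement (xtol 1e−12) polishes it. β is constrained
positive by bound, not by reparameterization. Powell was chosen over
Nelder–Mead because the default NM initial simplex degenerates when the
grid start lands exactly on α = 0 and then stalls short of the optimum;
Powell from the same starts matches an exhaustive 1e−3-step grid oracle
to better than 1e−8 in SSE on all sixteen reference columns. Profiles
with no acclimatization signal (constant θ = −1) drive β to the search
bound; the fit is then reported as a convergence error carrying the
best-so-far parameters rather than a silently meaningless optimum.

No reference values for (α, β) exist, so fitting is validated two ways:
equivalence with the brute-force grid oracle, and parameter recovery on
forward-generated profiles (9 slices, Gaussian θ-noise σ = 0.005), where
the median absolute error on both parameters is ≈ 0.002, an order of
magnitude inside the 0.02 requirement.

## Surgery statistics

**Exact Wilcoxon signed-rank.** Paired θ samples are small (9 or 18
pairs), so the test is exact rather than asymptotic. Zero differences
are dropped (their count is reported — the original treatment of zeros,
appropriate at these sample sizes); absolute differences are ranked with
mid-ranks for ties; the null distribution of W⁺ is the distribution of
rank-subset sums under random signs, computed by subset-sum convolution
over the doubled (integer) ranks — identical to enumerating all 2ⁿ sign
assignments, but O(n³). Two-sided p doubles the smaller tail, capped at
1. The implementation is checked against literal 2ⁿ enumeration (ties
included) and against scipy's exact mode on tie-free instances.

**Pooling.** State comparisons use the temperature and humidity
average-θ columns concatenated (18 pairs per comparison). This is the
operative choice: the comparison quantifies the whole conditioning
function, and with only 7–8 informative temperature pairs a single-
quantity test has essentially no resolution between "restored" and
"altered". On the reference tables the pooled test reproduces the
documented pattern: the subadult's de-obstruction changes function
significantly (p ≈ 0.016), while both adults' operated states are
indistinguishable from their originals (p ≈ 0.14), and the sibling
specimens' pooled θ concord at slope 0.998, r 0.9998.

**Concordance** is plain OLS of one sibling's pooled θ on the other's,
with the product-moment correlation; it is the replicate-precision check
for the virtual-surgery protocol.

## Mesh-convergence QC

`RE = |v_finest − v| / |v_finest| × 100` per probe, normalized by the
finest mesh (deliberately asymmetric). The verdict requires every
medium-mesh RE at or below the threshold (default 2 %) and reports the
coarse→medium RE reduction. Velocity probes are the contractual surface:
the probe pressures are printed as integers within ~10 Pa of atmospheric,
so their printed REs (0.02–0.16 %) cannot be reproduced from the printed
values (recomputed ≈ 0.002 %) and are annotated accordingly. Likewise
two of the printed velocity REs differ in the last digit from values
recomputed off the 3-decimal velocities (0.94 vs 0.97, 2.17 vs 2.31);
they were evidently computed from unrounded solver output. The one RE
fully determined by printed inputs — coarse-mesh right-nostril velocity,
4.98 % — reproduces exactly.

## Synthetic airway generator

The generator replaces the 3-D CFD stage with the smallest model that
preserves what the analysis consumes: a quasi-1D duct in which the bulk
air state relaxes toward the wall value,

    dx/ds = −(k P(s)/Q) (x − x_wall),    x(0) = ambient,

integrated exactly (exponential) across stations of constant properties.
In θ form the solution for a uniform duct is θ(d*) = −exp(−K d*) with
K = k P d_c / Q.

Defaults are the study conditions: flow Q = 15 L/min; wall at 38.5 °C
and 100 %RH; the three environmental scenarios above; nine equidistant
stations over d_c = 157.24 mm (the adult specimen); cross-section
400 mm², wetted perimeter 300 mm (turbinate-lined lumen, so perimeter is
large relative to area). The single calibration constant, the exchange
coefficient k ≈ 0.0588 m/s, is fixed by requiring slice-2 θ = −0.25 on
the healthy default duct — the scale of the healthy reference tables
(−0.2501 at the second slice of the adult). Temperature and humidity use
the same exchange coefficient (heat/mass-transfer analogy); their
profiles differ only through noise, as in the reference tables.

An obstruction scales the affected stations' area *and* perimeter by
(1 − blockage fraction): the smaller perimeter cuts local exchange and
delays acclimatization downstream (the functional signature of a blocked
vestibule), and the smaller area raises the local bulk velocity Q/A (the
qualitative CFD signature). The default 70 % blockage at slice 2
produces slice-2 θ ≈ −0.66 against −0.25 healthy, matching the
obstructed-vs-healthy contrast in the reference tables. Removing the
obstruction restores the geometry object exactly, so noise-free
"operated" profiles are bit-identical to "original" ones — the ideal
surgery against which the statistics are calibrated.

Noise is additive Gaussian on θ per scenario column (default σ = 0.005,
the between-scenario scatter of the reference tables), with the inlet
pinned at exactly −1 and values clipped to [−1, 0]. Child RNG streams
are spawned per (state, quantity) from one seed, so a bundle is fully
reproducible and the operated state has noise independent of the
original's.

**What the generator does not emulate:** the slightly positive
mid-airway humidity θ of the real tables (super-saturation effects near
the wall), the non-monotone outlet dip (nasopharynx geometry), pressure
fields and any secondary/3-D flow structure. Pipeline tests passing on
synthetic data therefore demonstrate the *analysis* is correct and
sensitive at realistic scales — not that the duct model is a faithful
flow solver. Because the tanh family cannot represent a pure exponential
exactly, noise-free simulated profiles fit with a small irreducible SSE
(≈ 5e−4 per 9-point profile); this bound is asserted in the tests.

## Problem sizes and determinism

All analyses run on 9-slice profiles; simulation replicates use 20 seeds
for the significance-pattern check and 100 profiles for parameter
recovery — enough for the binomial/median criteria they feed while
keeping the full suite under a minute of compute for the statistics and
a few tens of seconds for the oracle fits. Every stochastic component
takes an explicit seed; the optimizer and all reports are deterministic,
and repeated pipeline runs are byte-identical.
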