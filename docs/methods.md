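# Methods

This note records the models, conventions and numerical choices behind
`carbonledger`, including the decisions made where the underlying
assessment leaves the procedure open.

## Budget identity and conventions

All fluxes are annual, global, in GtC yr⁻¹. Sinks (S_LAND, S_OCEAN) are
positive when removing carbon from the atmosphere; sources (E_FOS, E_LUC)
positive when adding it; G_ATM is positive atmospheric accumulation. The
imbalance is B_IM = E_FOS + E_LUC − S_LAND − S_OCEAN − G_ATM. Corrections
are stored as signed additions to the component they touch, so the land
corrections carry negative signs and the ocean and land-use corrections
positive ones.

Decadal means are arithmetic means of annual values; the reported decadal
1σ is the **mean of the annual sigmas**, not σ/√n. Component uncertainties
are dominated by systematic, year-persistent errors (model structure,
density assumptions), so averaging years does not shrink them; this also
matches the reported decadal uncertainties, which are of the same size as
annual ones. Reported values are rounded half-up to one decimal; internal
computation keeps full precision.

Trends are ordinary least squares of flux against calendar year, rescaled
to per-decade, with a two-sided iid-error t-test on the slope and no
autocorrelation correction — the plain estimator whose calibration the test
suite verifies empirically (type-I error within [0.035, 0.065] at nominal
0.05 over 2000 null simulations).

Error combination is quadrature (√Σσᵢ²) throughout, treating sources as
independent. Missing sigmas are treated as absent, never as zero.

The airborne fraction is computed annually as AF_t = G_ATM/(E_FOS + E_LUC).
The denominator is a genuine open choice (total emissions vs G_ATM + sinks;
annual vs cumulative); annual total-emissions is used as the default
because it makes AF the fraction of that year's anthropogenic input that
stays airborne, and the alternative "budget" denominator is available as an
option (the two coincide under perfect closure).

## Transient-density correction of E_LUC (δL)

Bookkeeping models track committed fluxes from land-cover transitions using
equilibrium carbon densities. Static (present-day) densities understate the
historical growth of biomass and soil carbon under rising CO₂. Models with
both static- and transient-density runs supply per-year
transient/static ratios for each of five gross subcomponents
(deforestation, regrowth, wood-harvest sources, wood-harvest sinks, other
transitions); ratios are averaged across the reference models and applied
per subcomponent to static-only models, whose rescaled subcomponents are
then re-summed to net E_LUC. Choices:

* Ratios are formed and applied **per year**; "average ratio" is read as
  averaging across reference models, not across time.
* Where a static subcomponent is ~0 (|flux| < 1e−6 GtC yr⁻¹) the ratio is
  undefined and falls back to 1 (no information ⇒ no scaling), with a
  warning.
* Models that simulate density evolution endogenously enter as precomputed
  (transient − static) difference series.

The ensemble δL is the unweighted cross-model mean. Its 1σ combines the
two stated sources — per-model uncertainty and cross-model spread — as
σ = √(τ² + mean sᵢ²), with τ² the DerSimonian–Laird between-model variance
(inverse-variance weights, truncated at zero). DL is the standard
random-effects estimator, and adding the mean within-model variance keeps
σ at least as large as either source alone.

## Replaced-sinks-and-sources correction of S_LAND

Fixed-cover sink simulations keep pre-industrial (year-1700) land cover
while CO₂ and climate vary; since forest area has since fallen by roughly a
fifth and forests out-absorb the ecosystems that replaced them, the fixed-
cover sink is biased high. The correction reconstructs the sink under
transient cover:

    S_t = Σ_cells Σ_PFT nbp(cell, pft, t) × cover_transient(cell, pft, t) × area(cell)

with per-PFT net biome production interpreted as **per unit PFT area**
(sink positive), which makes the recombination dimensionally consistent.
The bias is fixed-cover S minus the reconstruction, positive when the sink
was overestimated; ensemble mean and inter-model (n−1) standard deviation
summarize the member biases.

PFTs present in the transient cover but never simulated under fixed cover
(e.g. expanding cropland types) have no density; the default fills them
with the cell-year's cover-weighted mean density over the PFTs that do
(avoids silently dropping area), and an "exclude" mode drops them instead —
neither mode is asserted as canonical. Residual bare fraction contributes
zero flux. Per-PFT soil and litter pools are not tracked separately; their
effect is assumed embedded in PFT-level NBP. Cells carry explicit areas; no
spherical geometry is computed.

## Lateral-carbon-export correction of S_LAND

The anthropogenic perturbation of the land→inland-water export F′_LI
(0.54 ± 0.44 GtC yr⁻¹, present decade vs pre-industrial) partitions by fate
into aquatic evasion F′_IA (0.34 ± 0.26), sediment burial F′_IS
(0.09 ± 0.03) and ocean export F′_IE (0.11 ± 0.08), and by origin into a
dissolved-soil-CO₂ half (0.27) and a terrestrial-organic-carbon half
(0.27). Both identities are validated to a default tolerance of 0.005
GtC yr⁻¹ (half the last printed digit). The land-sink reduction is the
organic-origin carbon decomposed and evaded in inland waters:
organic − F′_IS − F′_IE = 0.07 ± 0.06 GtC yr⁻¹; the dissolved share is a
lateral displacement of already-respired CO₂ with no sink impact. No
correction is applied to the ocean sink — exported carbon is assumed to
stay there. The source assessments print the organic-share uncertainty
inconsistently (±0.31 and ±0.22); both are retained as metadata and
neither is propagated — the correction's ±0.06 is carried as given.

Only the present-decade perturbation is assessed; its history is not. The
annual application multiplies the scalar correction by a per-year ramp in
[0, 1], by default linear from 0 (pre-industrial) to 1 at the start of the
final decade — the minimal assumption consistent with a perturbation
defined as present-decade minus pre-industrial.

## Ocean-sink corrections

S_OCEAN is the mean of two streams: an ocean-model ensemble and an
observation-product ensemble. The model stream is scaled up by
+10% ± 8% (applied to annual fluxes; this reproduces the decadal numbers),
giving +0.26 ± 0.21 GtC yr⁻¹ on a 2.6 GtC yr⁻¹ stream. The observation
stream gains a time-constant +0.18 GtC yr⁻¹ (cool-skin +0.42 minus
warm-layer −0.24) with σ = 0.4. Sigma calibration from stated sign
confidences: σ = c/|Φ⁻¹(1−p)| — 90% confidence on the +10% scaling gives
Z = −1.28 and σ = 7.8% (adopted 8%); 66% confidence on +0.18 gives
Z = −0.41 and σ ≈ 0.44 (adopted 0.4). The inverse normal is
`scipy.stats.norm.ppf` (accurate far beyond the 1e−8 documented here).

No rule is stated for combining the two correction sigmas; half-quadrature
(σ = ½√(σ₁² + σ₂²)) is adopted because it is the exact variance rule for
the mean of two independent streams and reproduces the reported ±0.23 from
±0.21 and ±0.4. The consolidated S_OCEAN sigma adds this combined
correction sigma in quadrature to the baseline stream sigma (0.4 → 0.46,
printing 0.5); the land and land-use corrections do **not** inflate their
components' reported sigmas, whose published values are ensemble spreads
that already subsume them — this asymmetry mirrors the reported table.

## Conversion factor and the G_ATM uncertainty band

Each inversion member supplies its net annual atmospheric input (fossil
emissions + inverse net land and ocean fluxes) and station-sampled mole
fractions. Annual growth in ppm is computed as for the observations:
the record is deseasonalized by a two-harmonic annual cycle fitted jointly
with a cubic trend (so curvature does not contaminate the harmonics), the
deseasonalized curve is interpolated to 1-January boundaries, and
consecutive boundaries are differenced. This is an approximation to the
operational curve-fitting procedures; on piecewise-linear-plus-seasonal
records it is exact to <0.01 ppm yr⁻¹. The member's annual factor is net
input / growth; years with |growth| < 0.05 ppm yr⁻¹ are flagged unreliable
and excluded. Ensemble statistics (per-year mean and n−1 spread, plus the
interannual sd of the mean over the 2001–2023 analysis window) feed the
G_ATM uncertainty: the three sources — observational growth sigma,
interannual factor variability, mean member spread — are treated as
independent **relative** errors combined in quadrature and scaled by G_ATM
(the absolute-vs-relative composition is unstated in the source; relative
is adopted and flagged). G_ATM itself is never adjusted; only its sigma
band is produced, and years with |B_IM| ≤ k·σ (k = 1 by default) are
flagged as having no significant imbalance.

## Climate attribution

Paired runs differ only in climate forcing; the effect on a sink is stored
as fixed-climate minus full-forcing, i.e. **positive = weakening**, so that
G_ATM^clim = AF × (S_LAND^clim + S_OCEAN^clim) adds positively to
atmospheric growth (display layers negate for plotting as a flux). The
cumulative ppm contribution is Σ G_ATM^clim / 2.124 since the series start.
Percentage reductions are relative to the no-climate-change counterfactual:
−100 × effect / (sink + effect); 0.8 on a revised land sink of 2.7 gives
−22.9% (printing −23%), 0.18 on 3.1 gives −5.5% (the reported −6% stems
from unrounded inputs). Regional decompositions carry CO₂-fertilization
(sink), climate (source) and land-use (source) terms; net = CO₂ − climate −
LUC with quadrature sigma, and a Global row may be checked against the sum
of regions.

## Synthetic world

The generator produces every pipeline input around a truth budget that
closes exactly (G_ATM defined as the residual of the other four
components, so B_IM ≡ 0 to machine precision). What it emulates:

* smooth component trajectories anchored to the assessed 2014–2023 decadal
  means (E_FOS 9.7, consolidated S_LAND 2.7, S_OCEAN 3.1, static E_LUC 1.1
  GtC yr⁻¹) with 1960 values near the historical record;
* interannual variability as stationary AR(1) with lag-1 correlation
  φ = 0.5 and component-specific innovation sigmas (land 0.5, ocean 0.2,
  land-use 0.1, fossil 0.05 GtC yr⁻¹ — land largest, ENSO-scale), a config
  default rather than a claim about the real spectra;
* a CO₂ trajectory 277 + a·exp(k(t−1700)) ppm anchored at 316 (1960) and
  423 (2024); transient densities scale as 1 + β ln(CO₂/277) with β = 0.25,
  set once so the transient/static ratio over the recent decade yields the
  assessed δL ≈ 0.11 on the 1.1 GtC yr⁻¹ static base;
* ensembles at the documented sizes (4 bookkeeping models of which 2 are
  reference pairs, 7 PFT-resolving vegetation models, 10 ocean models, 10
  observation products, 14 inversions) with per-member level offsets and
  AR(1) spread;
* the documented biases at their assessed magnitudes: ocean models low by
  truth/(1+0.10), observation products low by a constant 0.18 GtC yr⁻¹,
  a cover-change bias ramping linearly to a 0.54 GtC yr⁻¹ slope endpoint
  (≈0.5 decadal mean) realized **exactly** in closed form by the toy PFT
  worlds, and the lateral-export ramp shared between generator and
  pipeline;
* inversion members built from a known conversion-factor series (2.124 ×
  AR(1) wobble, 2% innovations) by integrating each member's growth into
  monthly mole fractions with a two-harmonic seasonal cycle;
* paired climate runs with known weakening trajectories amp·x^p (land
  0.88·x^1.2, ocean 0.27·x^6 with x normalized time), calibrated to the
  assessed decadal weakenings (0.8 and 0.18 GtC yr⁻¹). The implied
  cumulative sink reduction (~28 GtC) and atmospheric contribution
  (~6.4 ppm at the toy world's airborne fraction) are consistent in scale
  but not tuned to the corresponding cumulative assessments, which depend
  on the real trajectories' shapes.

A single seed sequence is split into independent streams per ensemble, so
changing one knob never reshuffles unrelated noise; a fixed seed gives
bit-identical outputs (series are written with 17 significant digits).

What the generator does **not** emulate: geography, seasonality of fluxes,
process-based land/ocean dynamics, observational gaps, or non-Gaussian
error structure. Passing recovery tests therefore demonstrates the
correctness of the accounting and statistics, not the realism of any
correction's magnitude on real data.

Problem sizes used by the test suite and the acceptance script — 64-year
worlds, 100–120 seeds for Monte-Carlo recovery, 1500–2000 replicates for
estimator calibration — were chosen to keep Monte-Carlo error well below
the tolerances being asserted.

## Worked-example inputs and known discrepancies

The assessed decadal inputs (budget rows, correction scalars) live in
`carbonledger.published` as fixed constants. Two printed-rounding
discrepancies are retained rather than hidden: the baseline-row imbalance
computed from rounded inputs is −0.5 (the assessment prints −0.4 from
unrounded series), and the revised land sink from rounded inputs is
3.2 − 0.5 − 0.07 = 2.63 where the assessment prints 2.7. The acceptance
tests assert the exact arithmetic and note the offsets.

## Known limitations

* The δL ratio machinery assumes subcomponent sign stability; strongly
  sign-alternating subcomponents would make ratios noisy (mitigated by the
  ~0 fallback but not eliminated).
* The growth-rate algorithm is a fitted-harmonic approximation; records
  with drifting seasonal amplitude would leak a few hundredths of a ppm
  into annual growth.
* The random-effects sigma uses DL with equal conceptual weight per model;
  no small-sample (Knapp–Hartung-style) adjustment is applied.
* The LCE ramp shape is an assumption; cumulative (but not decadal)
  LCE effects depend on it linearly.
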