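# Methods

## Scope and model

`cytogate` quantifies three particle populations in FDA/PI-stained samples
measured on a pulse-shape cytometer — viable yeast cells (green⁺/red⁻), dead
yeast cells (red⁺/green⁻) and solid medium particles (broad scatter,
green⁻, stochastically weak red) — and derives bioprocess monitoring
quantities from the counts. The package makes no attempt to model optics or
fluidics; events are treated as independent sampled signal traces, one per
detector channel (FSC, SSC, green FL, red FL).

## Pulse features

Each trace yields three scalars per channel:

- **total** = Σ max(sample − baseline, 0); the baseline defaults to 0 a.u.
  because instruments typically pre-subtract it.
- **maximum** = peak sample.
- **length** = (number of samples above a threshold) × sample spacing. All
  above-threshold samples are counted, not only the longest run: for the
  essentially unimodal pulses of cells and compact particles this equals the
  pulse extent, is monotone under pointwise increases of the trace, and
  needs no run-length bookkeeping. The spacing defaults to 0.5 µm/sample;
  it is set by the flow speed and is configurable.
- **saturation** = at least `min_run` (default 2) consecutive samples at the
  detector ceiling `adc_max`. Requiring a run of two suppresses isolated
  single-sample ADC spikes.

The analysis pipeline uses a length threshold of 50 a.u., safely above the
simulator's noise floor (σ = 3 a.u.), so length reflects the particle
rather than noise crossings.

## Gating

Gates are *fitted from reference runs*, not hard-coded, since no universal
coordinates exist across detector-gain settings. For each pure reference
(viable, dead, medium blank) the gate is the convex hull of the central 99 %
of events in (log₁₀ green total, log₁₀ red total) space — points ranked by
coordinate-wise-scaled distance from the median — expanded outward by 0.15
log units. The margin reflects how gates are drawn in practice (generously
around a cluster) and keeps a reference population's own tail events inside
its gate; without it, roughly 2–3 % of genuinely viable events fall outside
and self-classification stalls near 97 %. Totals are floored at 1 a.u.
before the log.

Biomass additionally requires membership in FSC-length and SSC-total
windows spanning the 0.5–99.5 % quantiles of the pooled cell references,
padded by 5 % of the span per side. This is what keeps PI-tinged SSL
particles (which can reach the red-fluorescence range of a weak dead gate)
out of the biomass counts.

Decision order: dead gate ∧ windows → dead; viable gate ∧ windows → viable;
background gate ∨ outside windows → background; otherwise unclassified.
An event inside both fluorescence gates counts as dead — PI positivity is
the membrane-integrity criterion, and compromised cells can retain residual
esterase activity. Green-saturated events inside the windows stay viable
(saturation indicates very high esterase activity, typical of budding
agglomerates) and are tallied in a `saturation_fraction` flag. Fitting
fails with the measured overlap fraction when the viable and dead hulls
intersect, e.g. when the same population is supplied twice.

The morphology split is a straight-line discriminant in (log₁₀ FSC length,
log₁₀ SSC total), fitted by linear discriminant analysis with equal class
priors on singlet and doublet references. The log transform turns the
doublet's multiplicative increase in extent and side scatter into an
additive shift, which a line separates cleanly; equal priors make the
boundary balanced rather than prevalence-weighted. The viable reference
used for window fitting should itself contain budding cells (a growing
culture does), otherwise doublets fall above the SSC window.

## Calibration math

Expected mixture composition follows the pure-suspension count equations in
the README. Cross-staining counts default to 0: pure-suspension endpoint
measurements reported as exactly 100 %/0 % support that, but both remain
parameters. Ratios are computed in double precision and rounded to integer
percent only at the reporting layer. `fit_yield_factor` minimizes squared
error of `Ratio_V(P) = 100·P/(P + r(100−P))` over non-endpoint design
points with bounded scalar optimization on r ∈ (0, 1]. One published-style
expected row (93/78/72/70/46-type patterns) cannot be reproduced exactly by
any single-r zero-cross-staining model; such rows are not force-fitted —
the fit reports the least-squares r and the residuals speak for themselves.

Accuracy evaluation passes a design point iff both |replicate mean −
expected| and the replicate SD are ≤ 10 percentage points (the documented
accuracy envelope of the method; configurable). Particle-load QC passes at
or below 1 × 10⁶ events·mL⁻¹ and otherwise recommends the smallest
power-of-ten dilution that brings the sample in range, matching serial
dilution practice (1:10 staining step, 1:100 measurement step).

## Synthetic data generator

The simulator defines the study conditions for all self-tests. Traces are
64-sample Gaussian profiles with additive N(0, 3 a.u.) noise, clipped to
[0, 65535] (16-bit ADC). Population defaults:

| population | size (FWHM, µm) | FSC amp | SSC amp | green amp | red amp | notes |
|---|---|---|---|---|---|---|
| viable | LN(4.5, σ=0.10) | LN(3000, 0.3) | LN(2000, 0.3) | LN(8000, 0.35) | noise | green⁺ fraction 1.0 |
| dead | LN(4.0, σ=0.18) | LN(2500, 0.3) | LN(1800, 0.3) | noise | LN(6000, 0.35) | slightly shrunken |
| SSL particle | LN(3.0, σ=0.9) | LN(1500, 0.8) | LN(1000, 0.8) | noise | LN(150, 1.0) w.p. 0.3 | broad scatter, heavy-tailed partial red |

LN(m, σ) is log-normal with median m (a.u. for amplitudes) and log-space σ.
These were chosen once so that the three clusters separate in fluorescence
while overlapping in scatter — small SSL particles sit inside the cell size
window and only fluorescence excludes them, and large ones exceed any cell —
forcing the classifier to use both, as the method prescribes. SSL events
carry zero green amplitude by construction (FDA hydrolysis requires
esterase activity), so the no-false-green invariant holds exactly.

Budding doublets add a daughter lobe offset by 3.2–3.8 σ along the flow
axis at 0.75–0.95 of the mother amplitude, with the green amplitude scaled
×2.2 (agglomerate fluorescence, occasionally saturating). Mixture event
counts are the deterministic rounded expectation (n_viable ∝ P_viable,
n_dead ∝ P_dead·r_yield, n_SSL ∝ ssl_level), so ground-truth composition is
exact by construction and all randomness lives in per-event draws; a fixed
seed reproduces the stream byte-identically.

Instrument overload is modeled as brightness-weighted subsampling (weights ∝
summed channel peaks^1.5) down to the fraction limit/concentration. The
real instrument only documents that acquisition is reduced and results
become inaccurate; preferential retention of large/bright events is an
assumption chosen to reproduce the qualitative bias — overloaded 50/50
mixtures read several points wrong while the same mixture below the limit
reads within a fraction of a point.

**What the simulator does not emulate:** spectral spillover (a green→red
bleed coefficient exists but defaults to 0, as the reference workflow had no
compensation), staining kinetics, coincidence/doublet artifacts other than
budding, electronic drift, and day-to-day gain changes. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under realistic cluster geometry — not the biological accuracy of
any instrument's raw data.

## Monitoring

Viability = 100·viable/(viable+dead); SSL fraction = 100·background/total;
zero denominators yield missing values, never zero. Washout follows
X(t) = X₀·e^{(µ−D)t} and inert background approaches the feed level as
C(t) = C_feed + (C₀−C_feed)·e^{−Dt}. The volumetric ethanol rate is
r = D·c + dc/dt with central finite differences (one-sided at the
boundaries), reducing to D·c at steady state. The viable-biomass basis
converts counts with a per-cell dry mass of 15 pg (order-of-magnitude
*S. cerevisiae* literature value; configurable, and normalized outputs are
invariant to it). The nutrient-pulse rule fires once per sustained
excursion below the viability threshold lasting at least the minimum
duration. Retentostat solute balances assume full cell retention with free
solute passage.

## File formats

Full traces travel in a documented long-format CSV (header block with
sample spacing and ADC ceiling; `event_id,channel,sample_index,value`
rows). Derived features travel as FCS 3.1 float listmode with one named
parameter per channel × feature plus integer-coded label parameters; FCS
has no standard for full traces, and 3.1 (named parameters, float data) was
chosen for tool interoperability. The FCS reader/writer is a minimal
implementation covering float list-mode files; readers reject rather than
coerce malformed input, and all writers are atomic (temp file + rename).
Concentrations serialize as events·mL⁻¹, times in hours.

## Problem sizes and numerical choices

The calibration sweep used by the tests and the acceptance script runs the
full design — three media paired with dead-suspension yield factors
(buffer ↔ 0.51, filtered SSL ↔ 0.96, unfiltered SSL ↔ 1.0) × seven mixing
ratios × three technical replicates of 20 000 cell events, with gates
fitted per medium on 4 000-event pure references. These sizes give binomial
sampling noise well under 1 percentage point per replicate while the whole
sweep completes in about a minute and a half on one CPU. Recovered
viability deviates from the expectation by at most ~0.2 points under these
conditions, far inside the 10-point acceptance envelope.

Degenerate inputs are handled explicitly: empty traces, missing channels
and duplicate event ids are structural errors; collinear reference clouds
get a tiny bounding box instead of a convex hull; mixtures with no cells
report viability as missing; a morphology split with no singles flags the
budding ratio as infinite rather than dividing by zero.

## Known limitations

- Gate quality depends on the pure-population references; detector gains
  that saturate a large fraction of events compress the hulls.
- The length feature counts all above-threshold samples; for genuinely
  multimodal pulses (rare coincidences) it overstates extent.
- The overload bias model is qualitative; only the *direction* and
  *existence* of the bias are asserted, not its magnitude.
- `fit_yield_factor` assumes zero cross-staining; rows generated with
  appreciable cross-staining fit a compromise r.
- The FCS implementation targets this package's own float list-mode
  exports; it is not a general-purpose FCS parser.
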