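# Methods

This note records the models implemented in pelagic-sync, the defaults
and numerical choices behind them, what the synthetic generators do and
do not emulate, and the known limitations.

## Marine heatwave detection

A heatwave is defined against a day-of-year climatology fit on a
baseline period (default: the full series; configurable). For each day
of year *d* (indexed 1–366 on a leap-year calendar), all baseline
values within ± `window_halfwidth` days of *d* are pooled; the pooled
mean gives the seasonal curve and the pooled empirical 90th percentile
(linear-interpolation / type-7 quantile, fixed for reproducibility)
gives the threshold. Both curves are then smoothed by a centered moving
average of width `smooth_width` that wraps across the year boundary.
Defaults follow the established heatwave literature: half-width 5 days
(an 11-day window), smoothing 31 days, minimum duration 5 days, maximum
merge gap 2 days; all four are parameters.

Events are maximal runs of days with SST strictly above the threshold,
of length ≥ `min_duration`; qualifying runs separated by ≤ `max_gap`
below-threshold days merge into one event whose intensity statistics
(mean, max, cumulative anomaly relative to the seasonal mean) include
the gap days. Two deliberate choices:

- **Missing data** count as below threshold during detection and are
  ignored in climatology fitting (conservative: a gap can split an
  event but never fabricate one). Baselines with more than 25% missing
  are rejected outright, naming the gap fraction.
- **Feb 29** climatology is interpolated from its neighbours rather
  than estimated from the 1-in-4 sample.

Two edge behaviours are worth knowing. First, chain merging breaks
strict monotonicity of the event *count* in `min_duration`: lowering
the duration threshold can create a short middle run that bridges two
events into one. The per-day exceedance set is unaffected. Second, on a
perfectly deterministic seasonal cycle the smoothed threshold dips
slightly below the raw seasonal peak (a moving average attenuates an
extremum), so noise-free input can nominally exceed the threshold near
the peak; with any realistic day-to-day variance the 90th percentile
sits well above the mean and the effect vanishes. Tests of degenerate
deterministic inputs therefore disable smoothing.

The 2014–2016 summary period is calendar-bounded (Jan 1 2014 – Dec 31
2016); event days are intersected with the period and the mean
intensity is the duration-weighted mean of per-event mean anomalies
over the intersecting days.

## Availability indices and portfolio effects

Frequency of occurrence is a per year × guild × species proportion of
diet samples containing the species; the species set defaults to the
three preferred forage fish (capelin, sand lance, herring) and is
configurable. The variance ratio over a window of years is
var(ΣF)/Σvar(F) with the sample (n−1) convention in both numerator and
denominator — the ratio is invariant to that convention, which a test
asserts. Windows are 3-year centered by default and require every
species to have data in every window year; no zeros are imputed for
missing years (the alternative — treating absence as F = 0 — would
manufacture variance from sampling gaps). The statistic is computed on
raw frequencies, not anomalies; an optional detrending switch exists
but defaults off.

Windows in which every species is constant have an undefined variance
ratio and are returned as missing rather than mapped to any value: a
constant community carries no synchrony information. Degeneracy is
detected with a relative tolerance (Σvar ≤ 1e−25 × max|F|²) because a
numerically constant series still produces rounding-level variance.

Guild correlations are Pearson *r* over shared years with the two-sided
t-transform p-value.

## Acoustic classification and NASC

Cell means on the 5-ping × 5-m sample grid are computed in the linear
domain (sᵥ = 10^(Sv/10)) and converted back to dB, the standard
echo-integration convention; the dB difference is then taken between
cell means. A pure log-domain mean is available (`mean_domain="log"`)
for sensitivity checks. Cell means below the −80 dB floor are floored
there before differencing (this prevents noise-driven dB differences);
cells floored at both frequencies are excluded from classification as
`below_threshold`. The macrozooplankton rule is inclusive:
8 dB ≤ ΔSv ≤ 30 dB.

Bins are surface-referenced and half-open [top, top + Δz); the valid
domain keeps bins lying fully within [4 m below surface, 1 m above the
per-ping bottom]. Trailing partial cells (pings or bins) are kept when
at least half full, otherwise dropped and logged.

NASC per 0.5 km × 5 m export cell is 4π·1852² times the ping-averaged
integral of linear sᵥ (120 kHz) over macrozooplankton-classified bins
in the cell; non-macrozooplankton backscatter contributes zero, and
integration is restricted to classified samples (consistent with an
index that is explicitly a *macrozooplankton* index — integrating all
samples within regions is the obvious sensitivity variant). Fully
masked export cells are missing, not zero. The 4π·1852² constant is
explicit in the code. Regional indices are arithmetic means over export
cells per region-year.

## Lognormal mixtures for length frequencies

The mixture is fit as a Gaussian mixture on log-lengths by EM:
responsibilities from normal densities in the E-step,
weighted-moment updates in the M-step, convergence when the
log-likelihood changes by less than `tol` (default 1e−8). The
log-likelihood path is retained and tested to be non-decreasing at
every iteration. Initialization seeds component means at interior
quantiles of the log-lengths with seeded jitter; the best of `n_starts`
(default 10) runs by final log-likelihood wins, ties to the lowest
start index, and components are reported in ascending meanlog order so
label-swapped starts converge to one canonical solution. A σ floor of
1e−3 (log scale) aborts collapsing starts; if all starts collapse the
fit errors with the seeds reported. K defaults to 3 (age-0 plus two
older groups), with a BIC-checked fallback to K−1 for years where a
component collapses — in heatwave years large fish can be nearly absent
and a 3-component fit is unidentifiable.

Size classes are defined by boundary integrals: the class proportion
is Σₖ πₖ[Φ((log b_hi−μₖ)/σₖ) − Φ((log b_lo−μₖ)/σₖ)] over the class
interval, with classes partitioning (0, ∞); the 100 mm boundary
separates age-0 fish. Proportions are multiplied by annual CPUE to give
the abundance-weighted index; mixtures are fit per year (pooled fitting
with year-specific weights is a noted alternative, not implemented).

## Energetics

Energy density from proximate composition is linear:
ED = 0.103·C:N + 32.6·(dry/wet) − 2.902 (kJ g⁻¹ wet). Non-positive
results are flagged invalid rather than propagated. Total energy
requires the caller to name the mass basis (wet for the C:N model, dry
for calorimetry-derived densities) so the two conventions cannot be
silently mixed. The juvenile herring filter keeps fork lengths in
55–115 mm, logging what it drops.

The annual model is log(TE) ~ year (categorical) with a random
intercept for site nested in year, fit by REML through statsmodels
MixedLM. Least-squares means per year are the fixed-effect predictions
at each year level, back-transformed by exponentiation without bias
correction (CIs transformed the same way, normal-theory ± 1.96 SE). A
singular random-effect variance triggers a flagged refit without the
random term. Both marginal R² (fixed effects over total variance:
var_f/(var_f + var_site + var_resid)) and conditional R² (fixed plus
random) are reported, since either convention is defensible for an
"explained variation" summary. The year comparison for balanced designs
uses one-way ANOVA with Tukey HSD at α = 0.05 and a greedy
compact-letter display. The two-sample length comparison defaults to
Welch's t (group SDs of field length data are rarely equal); the pooled
test is a flag.

## Standardized indices

Anomalies are z = (x − mean)/SD with the sample SD, computed within
season × region across years by default (per-panel scaling; grouping is
an argument, so season × year standardization is one call away).
Groups with fewer than two values or zero SD are flagged and left
missing. Extreme flagging is strict (z > 2). Encounter rates divide
pooled counts by pooled effort — the mean of per-segment rates is not
the pooled rate, and a test pins the distinction. Percent change is
100(first − second)/first, positive for declines. Region labels for
biomass summaries (Inner shelf < 50 km from shore, Middle shelf to the
1000 m isobath, Oceanic beyond) are input metadata and validated, never
recomputed from bathymetry.

## Synthetic generators

Each generator is a pure function of (scenario config, seed); streams
are seeded as (seed, per-generator offset) so adding one generator
never perturbs another, and reruns are bit-identical. What they
emulate, and what they do not:

- **SST**: mean + seasonal sinusoid + AR(1) noise (φ = 0.8, innovation
  SD 0.35 °C) + warm boxcar events. The default injects a 200-day +2.5 °C
  event from June 2014 and a 300-day +2.2 °C event from March 2015 over
  a 1982–2018 span — a stylized version of a multi-winter heatwave. No
  spatial correlation, trend, or El Niño teleconnection.
- **Diets**: yearly presence probability per species is
  logit⁻¹(logit(base) + ρ·common + (1−ρ)·idiosyncratic) with shock SD
  1.0 on the logit scale; ρ ∈ [0,1] is the synchrony dial, and the
  default scenario adds a shared −2.5 logit shock in 2014–2015. Base
  frequencies (0.45, 0.55, 0.25 for capelin, sand lance, herring) and
  200 samples per guild-year are of the order seen in colony diet
  programs. Both guilds share one latent field, so guild indices
  correlate; real guilds differ in accessibility (divers reach deeper
  prey), which is not modelled.
- **Echograms**: horizontal layers with fixed true Sv₁₂₀ and ΔSv
  (zooplankton layer +16 dB, fish layer −2 dB by default) plus
  independent Gaussian dB noise per frequency (SD 0.5 dB). No beam
  geometry, TVG noise, bubble layers, or bottom echoes.
- **Lengths**: straight mixture draws (defaults: weights 0.5/0.3/0.2,
  modes ≈ 60/100/150 mm).
- **Energetics**: log TE = log(base ED × wet mass) + year effect + site
  intercept (SD 0.15) + residual (SD 0.25), with C:N drawn and the
  dry/wet ratio back-solved through the ED formula so stored records
  are exactly self-consistent. Six years × 4 sites × 15 fish by
  default, matching a modest nursery-bay sampling program.

Because the generators share none of the analysis code paths (ground
truth is recorded at generation time), recovery tests are genuine
round trips. Passing them shows the estimators are correct under the
stated stochastic structure; it does not show robustness to the
features real data add (spatial autocorrelation, observer effects,
gear selectivity, non-stationary seasonality).

## Problem sizes and numerical conventions

The verification suites run at sizes where the relevant Monte-Carlo
error is small relative to the tested tolerance: 200 random series for
the event-detection oracle sweep, 1000 random windows for the
variance-ratio closed form (1e−12), 200 replicate diet datasets for the
synchrony ordering, 50 echograms for the acoustic per-bin oracle, 50
seeds at n = 5000 for mixture recovery, 200 replicates for mixed-model
CI coverage, and 1000 null replicates for the ANOVA type-I rate.
Floating-point output in the pipeline bundle is printed at fixed 1e−6
precision so checksums are stable; provenance hashes exclude output
paths.

## Limitations

- Acoustic classification implements the single two-frequency
  [8, 30] dB rule only; no multi-class inversion or calibration
  processing.
- The mixed model's CIs use normal quantiles, not Kenward-Roger or
  Satterthwaite df; with very few sites per year coverage can run
  slightly below nominal.
- No stock assessment, ageing, detection-function, or GIS machinery:
  region and season labels are inputs.
- Synthetic magnitudes are structural, not calibrated to real Gulf of
  Alaska biomass or NASC levels.
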