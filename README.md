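# pelagic-sync

Quantitative machinery for studying how a sustained marine heatwave can
synchronize a pelagic forage community and disrupt energy flow to
predators, built around the kinds of time series collected in the Gulf
of Alaska: gridded daily SST, seabird diet samples, two-frequency
echosounder transects, forage-fish length frequencies, fish energetics
records, and predator survey densities. It is aimed at marine
ecologists who need the individual analyses as reusable, tested
building blocks rather than one-off survey scripts.

## What it computes

**Marine heatwave detection** (`pelagic_sync.mhw`). A day-of-year
climatology (mean and empirical 90th percentile, pooled over an
±11-day window and smoothed with a 31-day circular moving average) is
fit on a baseline period; a marine heatwave is a run of ≥ 5 consecutive
days with SST above the threshold, with runs separated by ≤ 2
below-threshold days merged. Per-cell summaries report cumulative
heatwave days and mean intensity (anomaly relative to the
climatological mean) over a chosen period.

**Diet-based availability and portfolio effects**
(`pelagic_sync.portfolio`). The availability index for prey species *s*
in year *t* and feeding guild *j* is the frequency of occurrence
F<sub>s,t,j</sub> — the share of diet samples containing the species.
Over a 3-year centered rolling window *i*,

    VR_ij = var( Σ_s F_s ) / Σ_s var( F_s ),      PE_ij = 1 − VR_ij

so PE ≈ 0 for independent species, PE = 1 for perfect compensation, and
strongly negative PE flags a synchronized community (for *k* identical
series, PE = 1 − k).

**Acoustic macrozooplankton index** (`pelagic_sync.acoustics`). Mean
volume backscattering strength Sv (dB re 1 m⁻¹) in 5-ping × 5-m
samples is computed at 38 and 120 kHz (linear-domain averaging, −80 dB
floor); samples with ΔSv₁₂₀₋₃₈ ∈ [8, 30] dB are classified
macrozooplankton. The index is the nautical area scattering
coefficient NASC = 4π·1852²·∫sᵥ dz (m² nmi⁻²) from the 120 kHz data
over macrozooplankton cells, exported on 0.5 km × 5 m cells and
averaged by region and year.

**Size-structure mixtures** (`pelagic_sync.sizestruct`). Annual length
frequencies are decomposed into K lognormal components by EM (a
Gaussian mixture on log-lengths with multi-start initialization and a
σ floor); component mass is integrated over length intervals (class 1 =
fish < 100 mm, roughly age-0) and scaled by CPUE.

**Fish energetics** (`pelagic_sync.energetics`). Herring energy density
(kJ g⁻¹ wet) from proximate composition:
ED = 0.103·C:N + 32.6·(dry/wet) − 2.902; total energy TE = ED × mass
with an explicit wet/dry basis. Annual estimates come from one-way
ANOVA with Tukey HSD letters, or from the mixed model
log(TE) ~ year + (1 | site-in-year) with back-transformed least-squares
means and 95% CIs.

**Standardized indices** (`pelagic_sync.indices`). z-standardization of
survey densities to mean 0, SD 1 within season × region, > 2 SD extreme
flagging, encounter rates (individuals km⁻¹), percent change, and
seasonal biomass summaries.

**Synthetic data** (`pelagic_sync.synth`). Seeded generators emulate
each input's statistical structure (seasonal AR(1) SST with injected
warm events, Bernoulli diets with a latent synchrony parameter ρ,
layered two-frequency echograms, mixture lengths, hierarchical
energetics) and record ground truth, so every stage is testable without
any download.

## Worked example

```
$ python examples/heatwave_detection.py
injected warm anomalies: [{'start': '2014-06-01', 'end': '2014-12-17', 'amplitude': 2.5},
                          {'start': '2015-03-01', 'end': '2015-12-25', 'amplitude': 2.2}]
detected events (whole series): 56
longest event: 2015-03-01 to 2015-12-25, 300 d, mean intensity 2.26 degC
2014-2016 summary: 522 heatwave days, mean intensity 2.36 degC
```

The generator injected two warm boxcars; detection recovers the 300-day
2015 anomaly in full, and the 2014–2016 window accumulates 522 heatwave
days at a mean anomaly of 2.36 °C above the day-of-year climatology.

```
$ python examples/diet_portfolio_effects.py
portfolio effect (diver guild), 3-year centered windows:
  2000: PE = -0.15
  2008: PE = +0.65
  2014: PE = -1.31
  2015: PE = -1.38
  2018: PE = +0.85
capelin diet correlation between guilds: r = 0.98 (p = 3.28e-19)
```

Windows covering the injected 2014–2015 shared crash drive PE strongly
negative (synchronized collapse); windows outside it sit near or above
zero (buffered community). The other `examples/` scripts cover the
acoustic index, the length mixture, the energetics model, the anomaly
utilities, and the end-to-end pipeline; a thin CLI (`pelagic-sync
mhw|portfolio|acoustics|sizestruct|energetics|indices|simulate|run`)
wraps the same functions for file-based use.

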