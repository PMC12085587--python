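# coralchron

Massive *Porites* corals lay down one high/low density band couplet per year,
so a core drilled from a living colony is a multi-decadal growth archive.
`coralchron` implements the full analysis chain that turns such archives into
growth–environment inference for nearshore reefs:

1. **Densitometry** — calibrate CT grey values against a hydroxyapatite
   step phantom (five inserts, 1.26–1.92 g/cm³), average density in a
   5 × 5 mm window perpendicular to the growth axis every 50 μm, detect
   annual density maxima, and build a chronology of linear extension
   (cm/yr), skeletal density (g/cm³) and calcification
   (extension × density, g CaCO₃/cm²·yr). Sub-seasonal "double bands" that
   would be misread as extra years are detected and merged.
2. **Environmental metrics** — annual and summer (Jan–Apr) SST means and
   anomalies, Degree Heating Weeks from daily SST
   (DHW_t = Σ hotspots ≥ 1 °C over a trailing 84 days ÷ 7, hotspot =
   max(SST − MMM, 0)), counts of stress events ≥ 4 °C-weeks, turbidity
   (K_d490) and chlorophyll-a composites, and five-year bins
   (1998–2002 … 2013–2016).
3. **Growth statistics** — relative extension versus a 1998–2012 baseline,
   core/location/archipelago composites, turbidity–growth GLMs at several
   granularities, repeated-measures ANOVA with Tukey HSD across five-year
   bins, and a Gaussian linear mixed model

   extension ~ K_d490 + SST_summer + DHW + (1 | location) + (1 | core) + AR(1)

   fitted by ML/REML with AIC model selection. The mixed-model likelihood is
   implemented here and verified against `nlme::lme` to six decimals.
4. **Synthetic study generator** — daily site environments (seasonal SST
   with marine-heatwave events and AR(1) weather noise, seasonal turbidity
   coupled to chlorophyll, rainfall, wind), per-core annual growth from a
   known linear response with colony random intercepts and serial
   correlation, and rendered 16-bit CT volumes of banded cores with their
   calibration phantom. Every random draw is retained, so each downstream
   stage is testable against exact ground truth. The default configuration
   reproduces the observed conditions at twelve Fijian reef locations
   (mean K_d490 0.035–0.070 m⁻¹, near-identical SST climatologies, a
   sustained 2014–2016 warm anomaly with DHW well above 5 °C-weeks).

## Worked example

The numbered scripts under `analysis/` run the study end to end and write
tables under `results/`. With the default seed:

```sh
python analysis/01_simulate_study.py
python analysis/04_growth_statistics.py
```

prints

```
spatial: 27 cores, 12 locations, 513 core-years
gradient spans 0.70-1.66 cm/yr across K_d490 0.035-0.070 m^-1, ...
GLM extension ~ kd490 [annual_pooled]: slope -22.6 cm/yr per m^-1, R2 = 0.47, p = 7.8e-72
GLM extension ~ kd490 [location_means]: slope -22.8 cm/yr per m^-1, R2 = 0.81, p = 6.9e-05
GLM extension ~ kd490 [core_means]: slope -22.6 cm/yr per m^-1, R2 = 0.66, p = 3e-07
RM-ANOVA across bins: F = 7.0, p = 0.0011; 2013-2016 significantly below 2 earlier bins (Tukey)
composite relative extension declines 25% by 2016 relative to the 1998-2012 baseline
AIC-best mixed model: extension ~ kd490 + sst_summer + dhw (rho = 0.38, marginal R2 = 0.66)
```

Reading: growth falls steeply along the turbidity gradient (negative GLM
slope, about half the annual variance explained when pooling core-years and
~80 % across location means), the 2013–2016 bin sits significantly below
earlier bins once the warm anomaly arrives, and AIC prefers the mixed model
containing turbidity, summer SST and thermal stress with a first-order
serial correlation of ~0.4 within cores.

`analysis/02_core_densitometry.py` renders virtual cores to CT volumes and
recovers every annual band within a few voxels;
`analysis/03_environmental_metrics.py` writes the annual and binned
environmental tables; `analysis/05_full_pipeline.py` runs the packaged
`simulate → calibrate → chronology → envmetrics → analyze` pipeline with
figures. The same pipeline is available as a CLI:

```sh
coralchron run --seed 1 --outdir results/pipeline_run
coralchron calibrate --standard standard.csv
coralchron chronology --image core.tiff --calibration cal.json --out chron.csv
```

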