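# Methods

This note records the models implemented in `coralchron`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
study generator does and does not emulate.

## Densitometry

**Calibration.** CT grey values are assumed affine in skeletal density,
`grey = a·ρ + b`, fitted by least squares through the five phantom inserts
(1.26, 1.44, 1.65, 1.77, 1.92 g/cm³). An affine curve is the minimal model a
five-point standard determines robustly; the fit R² is reported so a
departure from linearity is visible. Densities implied to be ≤ 0 by the
inverse map are flagged (NaN) and excluded from window averages rather than
imputed — air, voids and bioeroded patches should not dilute skeletal
density.

**Profile extraction.** The growth axis is a user-supplied polyline (axis
picking is inherently manual; no automated axis discovery is attempted,
default: the straight line through the cross-section centre). At every 50 μm
step the calibrated density is averaged over a square window in the slice
plane — 5 × 5 mm (100 × 100 voxels) by default, large enough to average
across ≥ 20 corallites but small enough not to mix skeleton deposited in
different seasons on a domed colony. Windows that leave the image are
truncated and flagged; steps with > 50 % excluded voxels are marked
unreliable.

**Band detection.** Annual boundaries are local maxima of the profile after
a centred moving average (default 5 steps), filtered by prominence
(0.02 g/cm³) and minimum separation (2 mm). The profile is reflect-padded so
a core cut exactly at a band boundary still yields that boundary; peaks
found in the pad are folded back to their mirror position. Positions are
reported on the unsmoothed 50 μm grid. The defaults resolve annual bands of
0.78–1.44 cm/yr — the range observed in the study system — with one-voxel
accuracy on noiseless images; they are all exposed as parameters.

**Chronology.** Years are anchored so the outermost *complete* band gets the
last complete calendar year before the collection date (May 2017 → 2016);
material above the first detected maximum is an incomplete growing season
and is excluded (`edge-partial`). Extension is the boundary spacing in cm,
annual density the mean profile density over the segment, calcification
their exact product — an identity the tests assert to machine precision.
The convention that the core top is the most recent growth is an assumption,
recorded here because collection-date anchoring depends on it.

**Double-band correction.** Some colonies deposit a secondary intra-annual
density couplet; counted as year boundaries these halve apparent growth. The
default rule flags a *pair* of consecutive spacings that are both below
0.6 × the running-median spacing (window 7) and removes their shared
boundary. A running median is robust while doubling is sporadic; it cannot,
by construction, recognise a chronology in which every year is split (the
median is then itself sub-annual). For that case `annual_reference_cm`
accepts an external annual-scale estimate — in practice the mean extension
of neighbouring cores from the same reef — used in place of the median, with
a threshold of ~0.7 covering uneven (≈ 60/40) splits. Merged years are
flagged and all quantities recomputed.

## Environmental metrics

Annual means are arithmetic means of daily data per calendar year; summer
means restrict to January–April, the climatologically warmest months at this
latitude. Anomalies subtract the series' own 1998–2016 composite mean, so
they average to zero over that period by construction.

DHW follows the Coral Reef Watch accumulation rule: hotspot =
max(SST − MMM, 0) with MMM the maximum of the twelve monthly climatology
means; only hotspots ≥ 1 °C accumulate; DHW is the trailing 84-day sum ÷ 7,
in °C-weeks. By default MMM is computed from the supplied series' own
1998–2016 climatology — this keeps the module self-contained but differs
from the operational product, whose MMM uses a recentred 1985–2012 baseline;
an external MMM can be passed instead. For a rectangular pulse of height
h ≥ 1 °C lasting d days the maximum DHW is h·min(d, 84)/7 exactly, which the
tests verify against a brute-force rolling sum. Mean-type statistics ignore
gaps and report coverage; DHW is strict (a gap anywhere in the 84-day window
makes that day's DHW missing) because a running sum silently truncated would
understate stress.

Thermal-stress events are maximal contiguous runs of DHW ≥ 4 °C-weeks; a
run is attributed to the interval containing its peak, so events straddling
bin edges are counted once. Whether "events" should instead mean
calendar years containing an exceedance is ambiguous; a `per_year` option
implements that reading. Five-year bins are 1998–2002, 2003–2007,
2008–2012 and a four-year 2013–2016, aggregating means for continuous
variables, maxima for DHW and counts for events.

## Growth statistics

**Relative growth.** Only cores covering every year of 1998–2016 enter
composites (shorter records would bias year-to-year comparisons); each
core-year is expressed as percent change from that core's 1998–2012 mean —
a baseline chosen to predate the thermal anomaly — so baseline-period means
are exactly zero. Composites are unweighted arithmetic means over cores with
SE = sd/√n (undefined for n = 1). Location composites do not weight by core
count; weighting is a reasonable alternative left as future work.

**GLM.** Identity-link Gaussian regression (OLS via statsmodels), with
two-sided t tests (n − 2 df for the simple slope) and no small-sample
corrections. Fits are offered at annual-pooled, per-core-mean and
per-location-mean granularities, with and without the 2013–2016 stress
years, because the spatial gradient question is posed at all of them.

**Repeated-measures ANOVA.** Cores are subjects, five-year bins the within
factor: SS_total = SS_bins + SS_subjects + SS_error, F with
(b−1, (b−1)(n−1)) df; incomplete subjects are excluded listwise and
reported. Tukey HSD uses the studentized range with the within-subject error
term at α = 0.05. The implementation is a direct transcription of the
sums-of-squares definitions and is cross-checked against pingouin.

**Mixed model.** The growth equation is realised as a Gaussian linear mixed
model with random intercepts for location and core-within-location and an
AR(1) correlation of within-core annual residuals (`corr = ρ^|Δyear|`, which
also handles gaps). The "s(·)" random terms are intercepts, not smoothers —
the model lists no smoothing covariate — and penalised-spline estimation is
explicitly out of scope. The likelihood is profiled: variance *ratios* and
atanh(ρ) are optimised (Nelder–Mead on log/atanh scales, clipped to avoid
degenerate Cholesky factors) with the residual variance and fixed effects
solved in closed form per evaluation; blocks are independent across
locations, so the cost is a handful of ≤ 60 × 60 Cholesky factorisations
per evaluation. Covariates are standardised internally and coefficients
mapped back to original units (the delta map is exact since the transform is
linear). ML is the default so AIC (= 2k − 2·logLik, k counting fixed
effects, variance components, ρ and σ²) is comparable across fixed-effect
structures; REML is available and preferred for interval estimation because
ML variance components are biased low with ~11 cores. Intervals and p-values
use a t reference with n_cores − p degrees of freedom — conservative for
covariates that vary mostly between colonies, where normal-theory Wald
intervals undercover (observed per-coefficient coverage rises from ~80 % to
95 % in the recovery experiment). The reported R² is the marginal one:
variance of fixed-effect predictions over fixed + random + residual
variance; this definition is stated because "variance explained" is
otherwise ambiguous for mixed models. The ML fit (coefficients, ρ, logLik)
is verified against `nlme::lme` with `corAR1` to ~10⁻⁶.

## Synthetic study generator

The generator's defaults *are* the study conditions; they were fixed from
the observed system before the validation experiments were run.

* **Sites.** Twelve reef locations with observed 1998–2016 means: annual
  SST 26.8–27.8 °C, summer SST 27.8–29.1 °C (sinusoid peaking
  mid-February, amplitude set from the summer–annual offset), K_d490
  0.035–0.070 m⁻¹ with site-specific seasonality (December–January peaks,
  plus a May–June secondary peak at the wind-exposed sites), chlorophyll-a
  coupled to K_d490 with the cross-site slope 9.63 mg/m³ per m⁻¹. Daily
  chlorophyll noise is set in closed form so the pooled monthly
  K_d490–chlorophyll regression attains R² = 0.93; SST carries slow AR(1)
  weather noise (φ = 0.97, innovation 0.08 °C, stationary SD ≈ 0.33 °C)
  giving interannual summer-mean variability of ~0.25 °C.
* **Heat events.** The sustained 2014–2016 warm anomaly is emulated by
  plateau events of 1.3–1.8 °C lasting 40–65 days in the 2014, 2015 and
  2016 summers, producing maximum DHW ≈ 3 (2014) and ≈ 9–15 (2015/16)
  °C-weeks and near-zero DHW in other years. Anomalies much larger than
  ~2 °C for ~90 days would drive DHW beyond 20 °C-weeks, far outside the
  observed scale, which is why the defaults are milder.
* **Growth.** extension = β₀ + β_kd·K_d490 + β_sst·SST_summer + β_dhw·DHW +
  core intercept + AR(1) residual, with β₀ = 5.45, β_kd = −18.3 cm/yr per
  m⁻¹ (the slope implied by the observed cross-site means), β_sst = −0.12,
  β_dhw = −0.022, core-intercept SD 0.15, residual SD 0.20, ρ = 0.3. These
  reproduce site means of ≈ 1.43 (clearest site) to ≈ 0.78 cm/yr (most
  turbid), annual-pooled turbidity GLM R² ≈ 0.4 and location-mean R² ≈ 0.8.
  Non-positive draws are resampled and counted — a warning sign of a
  degenerate parameterisation.
* **Imagery.** Density along the core is one sinusoidal cycle per year with
  maxima exactly at band boundaries (the simplest shape with well-defined
  maxima; real intra-annual density profiles are not modelled). Flagged
  years add a second harmonic (relative amplitude 0.6), creating a
  secondary intra-annual maximum of comparable prominence — the misreading
  mode the double-band correction targets. Grey = 1000·ρ − 260 plus
  Gaussian noise, rendered as 16-bit multi-page TIFF with a sidecar
  metadata file; pitch coarser than the smallest band is rejected.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: satellite sensor merging, cloud masking and retrieval
error structure; rainfall/wind beyond white noise around site means;
site-level growth deviations from the shared linear response (real site
means scatter around the turbidity line; simulated ones lie on it up to
core-intercept luck); curved growth axes, growth scars and bioerosion
(densitometry is validated on straight-axis cores); and any nonlinear or
interactive growth response. One consequence is structural: with shared
coefficients, relative declines under a common stress scale inversely with
site mean extension, so the *most turbid* site shows the largest relative
decline — in the real system the clearest site declined most (31 %),
indicating site-specific thermal sensitivity the linear model cannot
express. The simulated per-site declines span ≈ 10–25 % with the all-core
composite reaching ≈ 25–35 % by 2016.

## Validation experiment sizes

Chosen as the smallest sizes at which the checked quantities stabilise:
five seeded replicates for study-level medians (GLM R², site means,
declines); 100 replicates of 11 cores × 19 years for the mixed-model
recovery experiment in the test suite (60 in the acceptance script);
virtual cores of 5–19 bands at 50 μm pitch with 2–6 mm cross-sections.
In the recovery experiment, 95 % intervals cover each generating
coefficient in ≥ 90 % of replicates and the fitted turbidity slope is
negative in all of them. AIC selects exactly the generating fixed-effect
set {K_d490, SST_summer, DHW} in just under half of replicates: with the
summer-SST effect at |t| ≈ 2 and two spurious optional covariates (wind,
rainfall) in the candidate set, the compound probability of exact selection
under AIC is ≈ 0.75 × 0.84² ≈ 0.5 — a known property of AIC-based
selection at moderate effect sizes, not an estimation defect; the selected
model contains all three generating terms in ≈ 70 % of replicates.

## Known limitations

Single straight (polyline) growth axis; no automated axis discovery or
distorted-growth avoidance; no luminescence or geochemical (δ¹⁸O/Sr-Ca)
chronologies; MMM from the series' own climatology unless supplied; no
spatial correlation between sites in either generator or models; no
penalised-spline GAMM, Bayesian fitting, or location-weighted composites.
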