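"""Default study configuration: a synthetic analogue of the Fijian
nearshore-reef system.

Site means are the observed 1998–2016 environmental conditions at twelve
Fijian reef locations (annual and summer SST in °C, K_d490 in m⁻¹,
chlorophyll-a in mg/m³, rainfall converted to mm/day, wind in m/s).  The
growth model coefficients are anchored on the cross-site gradient those
means imply (extension falls by roughly 18 cm/yr per m⁻¹ of K_d490), and the
default heat events emulate the sustained 2014–2016 warm anomaly, producing
maximum DHW of roughly 5–10 °C-weeks at every site.

The eleven-core "interannual" subset (three Coral Coast cores, three Namuka,
two Suva, three Nananu-i-Ra) mirrors the records spanning the full
1998–2016 window on which composite and binned analyses run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import (GrowthModelParams, HeatEventSpec, SiteConfig,
                        BandingSpec, calibrate_chl_noise, gen_growth_response,
                        gen_site_env)

__all__ = [
    "reference_sites",
    "interannual_core_counts",
    "default_heat_events",
    "default_growth_params",
    "default_banding_spec",
    "generate_study_env",
    "generate_study",
    "annual_weather_covariates",
]

# Jan-Apr mean of a sinusoid peaking mid-February, relative to its amplitude.
_SUMMER_PROJECTION = 0.798

# location, annual SST, summer SST, kd490, kd amplitude, kd peak months, wind, rain mm/day
_SITE_TABLE = [
    ("Coral Coast",          27.07, 27.87, 0.035, 0.010, (12, 1),       2.27, 8.1),
    ("Namada",               26.91, 27.79, 0.036, 0.010, (12, 1),       3.23, 8.1),
    ("Namuka",               26.93, 27.86, 0.053, 0.012, (12, 1),       3.82, 8.1),
    ("Muaivuso",             26.82, 27.81, 0.052, 0.012, (12, 1),       3.87, 8.1),
    ("Suva",                 26.93, 27.85, 0.060, 0.014, (12, 1, 5, 6), 5.35, 8.0),
    ("Dennis Patch",         26.89, 27.81, 0.060, 0.014, (12, 1, 5, 6), 5.41, 8.0),
    ("Nananu-i-Ra",          27.10, 27.95, 0.070, 0.018, (12, 1, 5, 6), 6.25, 6.5),
    ("Vuda Point",           27.82, 29.09, 0.057, 0.012, (12, 1),       1.75, 8.0),
    ("Kubulau",              27.32, 28.85, 0.062, 0.012, (12, 1),       4.46, 5.4),
    ("Savusavu",             27.36, 28.73, 0.045, 0.010, (12, 1),       2.87, 6.5),
    ("Vanua Balavu",         26.85, 28.40, 0.036, 0.010, (12, 1),       6.41, 6.2),
    ("Great Astrolabe Reef", 26.81, 28.35, 0.046, 0.010, (12, 1),       6.47, 5.9),
]

#: Cores per location in the interannual (full 1998–2016 coverage) subset.
INTERANNUAL_CORES = {"Coral Coast": 3, "Namuka": 3, "Suva": 2, "Nananu-i-Ra": 3}

#: Cores per location in the full spatial compilation.
SPATIAL_CORES = {name: 2 for name, *_ in _SITE_TABLE}
SPATIAL_CORES.update(INTERANNUAL_CORES)

CHL_SLOPE = 9.63      # (mg/m³) per (m⁻¹), cross-site coupling
CHL_INTERCEPT = -0.18


def reference_sites(chl_r2: float = 0.93,
                    years: tuple = (1997, 2016)) -> list:
    """Site configurations for the twelve reference reef locations.

    The daily chlorophyll noise is set by closed form so the pooled monthly
    K_d490–chlorophyll regression attains the target R² (0.93 by default).
    """
    sites = []
    for name, sst, sst_summer, kd, kd_amp, peaks, wind, rain in _SITE_TABLE:
        sites.append(SiteConfig(
            site_id=name,
            mean_kd490=kd,
            kd_seasonal_amplitude=kd_amp,
            kd_peak_months=peaks,
            mean_sst=sst,
            sst_seasonal_amplitude=(sst_summer - sst) / _SUMMER_PROJECTION,
            sst_ar1_phi=0.97,
            chl_slope=CHL_SLOPE,
            chl_intercept=CHL_INTERCEPT,
            mean_rainfall=rain,
            mean_wind=wind,
            noise_sd={"sst": 0.08, "kd490": 0.008, "chl": 0.05,
                      "rainfall": 10.0, "wind": 1.5},
        ))
    chl_sd = calibrate_chl_noise(sites, years, target_r2=chl_r2)
    for s in sites:
        s.noise_sd["chl"] = chl_sd
    return sites


def interannual_core_counts() -> dict:
    return dict(INTERANNUAL_CORES)


def default_heat_events() -> list:
    """The sustained warm anomaly of the 2014–2016 El Niño period."""
    return [
        HeatEventSpec("2014-01-20", "2014-02-28", amplitude=1.3, ramp_days=10),
        HeatEventSpec("2015-01-15", "2015-03-15", amplitude=1.7, ramp_days=10),
        HeatEventSpec("2016-01-10", "2016-03-15", amplitude=1.8, ramp_days=10),
    ]


def default_growth_params() -> GrowthModelParams:
    return GrowthModelParams()


def default_banding_spec(**overrides) -> BandingSpec:
    return BandingSpec(**overrides)


def generate_study_env(seed: int, sites: list | None = None,
                       events: list | None = None,
                       years: tuple = (1997, 2016)) -> dict:
    """Daily environment per site, with one spin-up year before 1998 so the
    DHW trailing window is full from the first analysis year."""
    sites = sites if sites is not None else reference_sites(years=years)
    events = events if events is not None else default_heat_events()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(sites))
    return {cfg.location_id: gen_site_env(cfg, events, years, s)
            for cfg, s in zip(sites, seeds)}


def annual_weather_covariates(env_by_site: dict,
                              years: tuple = (1998, 2016)) -> pd.DataFrame:
    """Annual-mean wind and rainfall per site — optional model covariates."""
    from . import env_metrics
    rows = []
    for loc, env in env_by_site.items():
        wind = env_metrics.annual_mean(env, "wind").set_index("year")["mean"]
        rain = env_metrics.annual_mean(env, "rainfall").set_index("year")["mean"]
        for y in range(years[0], years[1] + 1):
            rows.append({"location_id": loc, "year": y,
                         "wind": wind.get(y), "rainfall": rain.get(y)})
    return pd.DataFrame(rows)


def generate_study(seed: int, subset: str = "interannual",
                   params: GrowthModelParams | None = None,
                   years: tuple = (1998, 2016)) -> dict:
    """Generate the full synthetic study: environment plus growth tables.

    ``subset`` selects the eleven-core interannual set or the full spatial
    compilation ("spatial").  Returns a dict with ``env`` (per-site daily
    series), ``growth`` (core-year table with covariates) and ``truth``.
    """
    params = params or default_growth_params()
    counts = INTERANNUAL_CORES if subset == "interannual" else dict(SPATIAL_CORES)
    sites = [s for s in reference_sites() if s.location_id in counts]
    ss_env, ss_growth = np.random.SeedSequence(seed).spawn(2)
    env = generate_study_env(ss_env, sites=sites)
    growth, truth = gen_growth_response(env, params, counts, ss_growth,
                                        years=years)
    return {"env": env, "growth": growth, "truth": truth,
            "sites": sites, "params": params}
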