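"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from coralchron import densitometry as dns
from coralchron.synthetic import BandingSpec, SiteConfig, gen_core_image


@pytest.fixture(scope="session")
def quiet_site():
    """A site with no seasonality and no noise: every output deterministic."""
    return SiteConfig(site_id="flat", mean_kd490=0.05, kd_seasonal_amplitude=0.0,
                      mean_sst=27.0, sst_seasonal_amplitude=0.0,
                      noise_sd={"sst": 0.0, "kd490": 0.0, "chl": 0.0,
                                "rainfall": 0.0, "wind": 0.0})


@pytest.fixture(scope="session")
def exact_standard():
    """Phantom measured with greys exactly affine in density."""
    dens = (1.26, 1.44, 1.65, 1.77, 1.92)
    greys = tuple(1000.0 * d - 260.0 for d in dens)
    return dns.CalibrationStandard(dens, greys)


@pytest.fixture(scope="session")
def exact_curve(exact_standard):
    return dns.fit_calibration(exact_standard)


@pytest.fixture(scope="session")
def noiseless_core():
    """A five-band noiseless core image with its truth and calibration."""
    extensions = [1.2, 0.9, 1.44, 0.78, 1.1]
    spec = BandingSpec(grey_noise_sd=0.0, cross_section_mm=3.0)
    result = gen_core_image(extensions, spec, seed=5)
    std = dns.measure_standard(result.standard_image, result.standard_regions,
                               result.insert_density)
    curve = dns.fit_calibration(std)
    profile = dns.extract_profile(result.image, curve, window_mm=2.0)
    return {"extensions": np.asarray(extensions), "result": result,
            "curve": curve, "profile": profile, "spec": spec}


def daily_series(values: dict, start="2000-01-01", periods=None) -> pd.DataFrame:
    """Helper: build a daily env frame from per-variable arrays/constants."""
    n = periods
    for v in values.values():
        if np.ndim(v):
            n = len(v)
    dates = pd.date_range(start, periods=n, freq="D")
    out = {"date": dates}
    for k, v in values.items():
        out[k] = np.broadcast_to(np.asarray(v, dtype=float), n).copy()
    return pd.DataFrame(out)
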