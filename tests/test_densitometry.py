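"""Calibration, profile extraction, band detection and chronologies."""

import numpy as np
import pandas as pd
import pytest

from coralchron import densitometry as dns
from coralchron.synthetic import BandingSpec, gen_core_image


class TestCalibration:
    def test_exact_affine_standard(self, exact_standard):
        curve = dns.fit_calibration(exact_standard)
        assert curve.slope == pytest.approx(1000.0)
        assert curve.intercept == pytest.approx(-260.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_identity_mapping(self):
        dens = (1.0, 1.5, 2.0)
        curve = dns.fit_calibration(dns.CalibrationStandard(dens, dens))
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        dens = np.array([1.26, 1.44, 1.65, 1.77, 1.92])
        grey = 950 * dens - 210 + rng.normal(0, 15, 5)
        curve = dns.fit_calibration(dns.CalibrationStandard(tuple(dens),
                                                            tuple(grey)))
        # closed-form normal equations
        A = np.column_stack([dens, np.ones(5)])
        slope, intercept = np.linalg.inv(A.T @ A) @ A.T @ grey
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError):
            dns.CalibrationStandard((1.5,), (1000.0,))
        with pytest.raises(ValueError):
            dns.CalibrationStandard((1.5, 1.4), (1000.0, 1100.0))  # not increasing

    def test_grey_to_density_inverts_curve(self, exact_curve):
        assert dns.grey_to_density(1000.0, exact_curve) == pytest.approx(1.26)
        # grey equal to the intercept maps to zero density -> flagged as NaN
        assert np.isnan(dns.grey_to_density(-260.0, exact_curve))

    def test_affine_commutes_with_averaging(self, exact_curve):
        rng = np.random.default_rng(3)
        grey = rng.uniform(900, 1700, (20, 20))
        a = dns.grey_to_density(grey, exact_curve).mean()
        b = dns.grey_to_density(grey.mean(), exact_curve)
        assert a == pytest.approx(b, rel=1e-12)


class TestProfileExtraction:
    def test_uniform_image_gives_constant_profile(self, exact_curve):
        grey = int(round(1000 * 1.5 - 260))
        img = np.full((40, 30, 30), grey, dtype=np.uint16)
        prof = dns.extract_profile(img, exact_curve, window_mm=1.0)
        assert np.allclose(prof["density"], 1.5, atol=1e-3)

    def test_window_holds_expected_voxel_count(self, exact_curve):
        img = np.full((3, 120, 120), 1240, dtype=np.uint16)
        prof = dns.extract_profile(img, exact_curve, window_mm=5.0)
        # 5 mm at 50 um pitch: 100 x 100 = 10 000 voxels
        assert prof["n_voxels"].iloc[0] == 10_000
        assert not prof["truncated"].any()

    def test_truncated_window_flagged(self, exact_curve):
        img = np.full((3, 40, 40), 1240, dtype=np.uint16)
        prof = dns.extract_profile(img, exact_curve, window_mm=5.0)
        assert prof["truncated"].all()

    def test_profile_matches_generating_sinusoid(self, noiseless_core):
        res = noiseless_core["result"]
        spec = noiseless_core["spec"]
        prof = noiseless_core["profile"]
        ext = noiseless_core["extensions"]
        z = prof["position_um"].to_numpy()
        b = res.boundaries_um
        band = np.clip(np.searchsorted(b, z, side="right") - 1, 0, len(ext) - 1)
        u = (z - b[band]) / (ext[band] * 1e4)
        expected = (spec.annual_density_mean
                    + spec.annual_density_amplitude * np.cos(2 * np.pi * u))
        assert np.allclose(prof["density"], expected, atol=2e-3)


class TestPeakDetection:
    def _sine_profile(self, period_mm=10.0, length_mm=50.0, noise=0.0, seed=0):
        pos = np.arange(0, length_mm * 1000 + 1, 50.0)
        dens = 1.4 + 0.15 * np.cos(2 * np.pi * pos / (period_mm * 1000))
        if noise:
            dens = dens + np.random.default_rng(seed).normal(0, noise, len(pos))
        return pd.DataFrame({"position_um": pos, "density": dens})

    def test_pure_sinusoid_five_interior_periods(self):
        prof = self._sine_profile()
        maxima = dns.detect_density_maxima(prof, min_separation_um=5000)
        # maxima at 0, 10, 20, 30, 40, 50 mm (ends included via reflection)
        assert len(maxima) == 6
        spacing = np.diff(maxima)
        assert np.all(np.abs(spacing - 10_000) <= 50)

    def test_noise_does_not_move_peaks_beyond_one_step(self):
        # peak curvature must dominate smoothed noise for stable positions:
        # a 2.5 mm period gives ~4e-3 g/cm3 curvature per step vs 9e-4 noise
        clean = dns.detect_density_maxima(self._sine_profile(period_mm=2.5),
                                          min_separation_um=1000)
        noisy = dns.detect_density_maxima(
            self._sine_profile(period_mm=2.5, noise=0.002),
            min_separation_um=1000)
        assert len(noisy) == len(clean)
        assert np.all(np.abs(noisy - clean) <= 50)

    def test_second_harmonic_doubles_peak_count(self):
        pos = np.arange(0, 50_000 + 1, 50.0)
        dens = (1.4 + 0.15 * np.cos(2 * np.pi * pos / 10_000)
                + 0.09 * np.cos(4 * np.pi * pos / 10_000))
        prof = pd.DataFrame({"position_um": pos, "density": dens})
        doubled = dns.detect_density_maxima(prof, min_separation_um=2000)
        assert len(doubled) == 11      # primary + secondary per 10 mm period

    def test_flat_profile_warns_and_returns_empty(self):
        prof = pd.DataFrame({"position_um": np.arange(0, 5000, 50.0),
                             "density": 1.4})
        with pytest.warns(UserWarning, match="no density maxima"):
            out = dns.detect_density_maxima(prof)
        assert len(out) == 0


class TestChronology:
    def _flat_profile(self, length_um=40_000, density=1.5):
        pos = np.arange(0, length_um + 1, 50.0)
        return pd.DataFrame({"position_um": pos,
                             "density": np.full(len(pos), density)})

    def test_equal_spacing_gives_unit_extensions(self):
        chron = dns.build_chronology([0, 10_000, 20_000, 30_000],
                                     "2017-05-01", self._flat_profile())
        assert np.allclose(chron.table["extension_cm"], 1.0)

    def test_calcification_is_exact_product(self):
        chron = dns.build_chronology([0, 10_000, 20_000], "2017-05-01",
                                     self._flat_profile(density=1.5))
        t = chron.table
        assert np.allclose(t["calcification_g_cm2yr"],
                           t["extension_cm"] * t["density_g_cm3"])
        assert t["calcification_g_cm2yr"].iloc[0] == pytest.approx(1.5)

    def test_collection_in_may_anchors_previous_year(self):
        chron = dns.build_chronology([0, 10_000, 20_000], "2017-05-01",
                                     self._flat_profile())
        assert chron.table["year"].tolist() == [2016, 2015]

    def test_extension_sum_equals_total_span(self):
        rng = np.random.default_rng(7)
        bounds = np.concatenate([[0], np.cumsum(rng.uniform(6000, 14000, 12))])
        chron = dns.build_chronology(bounds, "2017-05-01",
                                     self._flat_profile(length_um=150_000))
        total = chron.table["extension_cm"].sum()
        assert total == pytest.approx((bounds[-1] - bounds[0]) / 1e4, abs=1e-12)

    def test_non_monotonic_positions_rejected(self):
        with pytest.raises(ValueError):
            dns.build_chronology([0, 10_000, 9_000], "2017-05-01",
                                 self._flat_profile())


class TestDoubleBandMerge:
    def _chron_from_bounds(self, bounds, density=1.5):
        pos = np.arange(0, max(bounds) + 1, 50.0)
        prof = pd.DataFrame({"position_um": pos,
                             "density": np.full(len(pos), density)})
        return dns.build_chronology(bounds, "2017-05-01", prof)

    def test_clean_chronology_is_fixed_point(self):
        bounds = np.arange(0, 110_000, 10_000)
        chron = self._chron_from_bounds(bounds)
        merged = dns.merge_double_bands(chron)
        assert np.array_equal(merged.boundaries_um, chron.boundaries_um)
        assert merged.table["year"].tolist() == chron.table["year"].tolist()

    def test_sporadic_doubles_merged_by_running_median(self):
        # years of ~1.0 cm with the third year split 0.45/0.55
        bounds = [0, 10_000, 20_000, 24_500, 30_000, 40_000, 50_000, 60_000]
        merged = dns.merge_double_bands(self._chron_from_bounds(bounds))
        assert np.array_equal(merged.boundaries_um,
                              [0, 10_000, 20_000, 30_000, 40_000, 50_000, 60_000])
        assert (merged.table["flags"] == "merged-double-band").sum() == 1

    def test_halving_law_inverted_exactly_with_reference(self):
        rng = np.random.default_rng(11)
        ext = rng.uniform(1.1, 1.6, 10)            # cm
        bounds = np.concatenate([[0], np.cumsum(ext)]) * 1e4
        # split every year near its middle, preserving total length
        split = []
        for a, b in zip(bounds, bounds[1:]):
            split += [a, a + (b - a) * rng.uniform(0.42, 0.58)]
        split.append(bounds[-1])
        misread = self._chron_from_bounds(np.asarray(split))
        assert misread.mean_extension == pytest.approx(ext.mean() / 2, rel=0.01)
        # 0.7 x annual reference covers uneven splits up to ~60/40 of the
        # largest year; every sub-annual spacing falls below it
        merged = dns.merge_double_bands(misread, rel_threshold=0.7,
                                        annual_reference_cm=float(np.mean(ext)))
        assert np.allclose(merged.boundaries_um, bounds)
        assert merged.mean_extension == pytest.approx(2 * misread.mean_extension)

    def test_generator_flagged_doubles_recovered_exactly(self, exact_curve):
        rng = np.random.default_rng(1)
        ext = np.round(rng.normal(1.2, 0.2, 19), 2)
        flags = np.zeros(19, bool)
        flags[[3, 9, 15]] = True
        res = gen_core_image(ext, BandingSpec(cross_section_mm=3.0), seed=5,
                             double_band_flags=flags)
        prof = dns.extract_profile(res.image, exact_curve, window_mm=2.0)
        maxima = dns.detect_density_maxima(prof, min_separation_um=1500)
        chron = dns.build_chronology(maxima, "2017-05-01", prof)
        merged = dns.merge_double_bands(chron)
        assert len(merged.table) == 19
        flagged = merged.table["flags"] == "merged-double-band"
        assert list(np.where(flagged)[0]) == [3, 9, 15]
        # years not touching a doubled year recover within one voxel per
        # boundary pair; the secondary harmonic skews the shared boundary of
        # adjacent years by a few voxels
        adjacent = np.zeros(19, bool)
        for i in np.where(flags)[0]:
            adjacent[max(i - 1, 0):i + 2] = True
        err = np.abs(merged.table["extension_cm"].to_numpy() - ext)
        assert np.all(err[~adjacent] <= 0.011)
        assert np.all(err <= 0.031)

    def test_fewer_than_three_bands_rejected(self):
        chron = self._chron_from_bounds([0, 4000, 8000])
        with pytest.raises(ValueError, match="three bands"):
            dns.merge_double_bands(chron, annual_reference_cm=1.6)


class TestRoundTripAndInvariance:
    def test_noiseless_roundtrip_recovers_bands_within_one_voxel(
            self, noiseless_core):
        res = noiseless_core["result"]
        maxima = dns.detect_density_maxima(noiseless_core["profile"])
        assert len(maxima) == len(res.boundaries_um)
        assert np.all(np.abs(maxima - res.boundaries_um)
                      <= res.voxel_pitch_um)

    def test_chronology_invariant_to_affine_grey_rescaling(self, noiseless_core):
        res = noiseless_core["result"]
        img = res.image.astype(np.float64)
        std_grey = np.array([res.standard_image[r].mean()
                             for r in res.standard_regions])

        def chron_from(img_g, greys):
            std = dns.CalibrationStandard(res.insert_density, tuple(greys))
            curve = dns.fit_calibration(std)
            prof = dns.extract_profile(
                np.clip(img_g, 0, 65535).astype(np.uint16), curve,
                window_mm=2.0)
            maxima = dns.detect_density_maxima(prof)
            return dns.build_chronology(maxima, "2017-05-01", prof)

        base = chron_from(img, std_grey)
        scaled = chron_from(img * 1.5 + 2000, std_grey * 1.5 + 2000)
        assert np.array_equal(base.boundaries_um, scaled.boundaries_um)
        assert np.allclose(base.table["density_g_cm3"],
                           scaled.table["density_g_cm3"], atol=1e-2)
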