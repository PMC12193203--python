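import numpy as np
import pandas as pd
import pytest

from msidiff.io import Spectrum
from msidiff.preprocess import (
    estimate_noise,
    normalize,
    pick_peaks,
    recalibrate,
    smooth,
    tophat_baseline,
)

from conftest import make_spectrum


class TestSmooth:
    def test_constant_spectrum_unchanged(self):
        s = make_spectrum(np.arange(900.0, 910.0, 0.1), np.full(100, 3.0))
        out = smooth(s, 0.2)
        np.testing.assert_allclose(out.intensity, 3.0)

    def test_unit_impulse_becomes_unit_mass_gaussian(self):
        y = np.zeros(201)
        y[100] = 1.0
        s = make_spectrum(np.arange(900.0, 902.01, 0.01), y)
        out = smooth(s, 0.05)
        assert out.intensity[100] < 1.0
        np.testing.assert_allclose(out.intensity.sum(), 1.0, rtol=1e-6)
        assert np.argmax(out.intensity) == 100

    def test_total_ion_current_preserved(self, gaussian_spectrum):
        s = gaussian_spectrum(centers=1000.0, amps=50.0, sigma=0.05)
        out = smooth(s, 0.03)
        assert abs(out.intensity.sum() - s.intensity.sum()) / s.intensity.sum() < 1e-3

    def test_oversized_sigma_errors(self):
        s = make_spectrum(np.arange(900.0, 910.0, 0.1), np.zeros(100))
        with pytest.raises(ValueError, match="half the mass range"):
            smooth(s, 100.0)


class TestTopHat:
    def test_constant_signal_annihilated(self):
        s = make_spectrum(np.arange(900.0, 910.0, 0.1), np.full(100, 7.0))
        out, baseline = tophat_baseline(s, 1.0)
        np.testing.assert_allclose(out.intensity, 0.0)
        np.testing.assert_allclose(baseline, 7.0)

    def test_hand_computed_opening_on_ten_points(self):
        # hand-checked morphological opening on a 10-point vector with a
        # 3-sample flat element: erosion leaves [.. 0 5 0 ..], dilation of
        # that gives [.. 5 5 5 ..], and the subtraction keeps the apex
        y = np.array([0, 0, 0, 0, 5.0, 8.0, 5.0, 0, 0, 0])
        s = make_spectrum(900.0 + 0.1 * np.arange(10), y)
        out, baseline = tophat_baseline(s, 0.3)
        expected_erosion = np.array([0, 0, 0, 0, 0, 5.0, 0, 0, 0, 0])
        expected_opening = np.array([0, 0, 0, 0, 5.0, 5.0, 5.0, 0, 0, 0])
        np.testing.assert_allclose(baseline, expected_opening)
        np.testing.assert_allclose(out.intensity, y - expected_opening)

    def test_wide_element_preserves_peak_exactly(self, gaussian_spectrum):
        s = gaussian_spectrum(centers=1000.0, amps=10.0, sigma=0.05)
        out, baseline = tophat_baseline(s, 1.5)
        np.testing.assert_allclose(baseline, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.intensity, s.intensity, atol=1e-12)

    def test_idempotent_and_bounded(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 200))
            y = np.clip(rng.standard_normal(n).cumsum() + rng.random(n) * 5, 0, None)
            s = make_spectrum(900 + 0.05 * np.arange(n), y)
            once, _ = tophat_baseline(s, 0.5)
            twice, _ = tophat_baseline(once, 0.5)
            assert np.all(once.intensity <= s.intensity + 1e-12)
            np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_nonpositive_width_errors(self):
        s = make_spectrum(np.arange(900.0, 910.0, 0.1), np.zeros(100))
        with pytest.raises(ValueError, match="width"):
            tophat_baseline(s, 0.0)


class TestPickPeaks:
    def test_single_gaussian_on_noise(self, gaussian_spectrum):
        s = gaussian_spectrum(centers=1000.0, amps=10.0, sigma=0.05,
                              noise_sd=1.0, seed=3)
        s, _ = tophat_baseline(s, 1.5)
        peaks = pick_peaks(s, snr_threshold=4.0, noise_window=50.0)
        assert len(peaks) == 1
        assert abs(peaks["mz"].iloc[0] - 1000.0) < 0.05
        assert 6.0 < peaks["snr"].iloc[0] < 16.0  # apex 10 on noise sd ~1

    def test_subthreshold_apex_yields_no_peak(self, gaussian_spectrum):
        s = gaussian_spectrum(centers=1000.0, amps=1.5, sigma=0.05,
                              noise_sd=1.0, seed=4)
        s, _ = tophat_baseline(s, 1.5)
        peaks = pick_peaks(s, snr_threshold=2.0)
        assert not np.any(np.abs(peaks["mz"] - 1000.0) < 0.1)

    def test_symmetric_peak_centroid_at_apex(self, gaussian_spectrum):
        s = gaussian_spectrum(centers=1000.0, amps=100.0, sigma=0.05)
        peaks = pick_peaks(s, snr_threshold=2.0)
        assert len(peaks) == 1
        assert abs(peaks["mz"].iloc[0] - 1000.0) < 1e-6

    def test_all_zero_spectrum_empty_not_error(self):
        s = make_spectrum(np.arange(900.0, 950.0, 0.01), np.zeros(5000))
        assert len(pick_peaks(s)) == 0

    def test_recovers_planted_peaks_at_snr_4(self, rng):
        # >=95% recovery of peaks whose apex SNR is >= 4
        axis = np.arange(800.0, 1600.0001, 0.01)
        found = total = 0
        for rep in range(5):
            centers = 810 + 780 * rng.random(10)
            centers = centers[np.argsort(centers)]
            centers = centers[np.r_[True, np.diff(centers) > 2.0]]
            y = rng.standard_normal(len(axis))
            for c in centers:
                y += 4.5 * np.exp(-0.5 * ((axis - c) / 0.0425) ** 2)
            s = make_spectrum(axis, np.clip(y, 0, None))
            s, _ = tophat_baseline(s, 1.5)
            pk = pick_peaks(s, 2.0, 50.0)
            for c in centers:
                total += 1
                found += int(np.any(np.abs(pk["mz"].to_numpy() - c) < 0.1))
        assert found / total >= 0.95

    def test_pure_noise_rarely_yields_peaks(self, rng):
        # detection at SNR 2 on noise-only spectra: well under 1% of the
        # 50-Da noise windows may contain a (false) peak
        axis = np.arange(800.0, 1600.0001, 0.01)
        n_windows = int((1600 - 800) / 25)
        false = 0
        n_spec = 8
        for _ in range(n_spec):
            y = np.clip(rng.standard_normal(len(axis)), 0, None)
            s = make_spectrum(axis, y)
            s, _ = tophat_baseline(s, 1.5)
            false += len(pick_peaks(s, 2.0, 50.0))
        assert false / (n_spec * n_windows) <= 0.01


class TestRecalibrate:
    def _peaks(self, mz):
        return pd.DataFrame(
            {
                "spectrum_id": "s1", "patient_id": "P1", "region": "diagnosis",
                "x": 0, "y": 0, "mz": np.asarray(mz, float),
                "intensity": 10.0, "snr": 5.0,
            }
        )

    def test_pure_offset_recovered_exactly(self):
        cal = [1000.0, 1500.0, 2000.0]
        peaks = self._peaks([c + 0.05 for c in cal])
        corrected, fit = recalibrate(peaks, cal, search_window=0.5)
        assert fit.applied
        np.testing.assert_allclose(fit.slope, 1.0, atol=1e-9)
        np.testing.assert_allclose(fit.offset, -0.05, atol=1e-9)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)
        np.testing.assert_allclose(corrected["mz"], cal, atol=1e-9)

    def test_affine_drift_recovered_to_machine_precision(self):
        cal = [1000.0, 1500.0, 2000.0, 2500.0]
        a, b = 1.00002, 0.01
        peaks = self._peaks([a * c + b for c in cal])
        _, fit = recalibrate(peaks, cal, search_window=0.5)
        # closed-form least squares on exact affine data is exact
        np.testing.assert_allclose(fit.slope * a, 1.0, atol=1e-10)
        np.testing.assert_allclose(np.abs(fit.residuals).max(), 0.0, atol=1e-9)

    def test_single_calibrant_flagged_uncorrected(self):
        peaks = self._peaks([1000.02, 1700.0])
        with pytest.warns(UserWarning, match="left uncorrected"):
            corrected, fit = recalibrate(peaks, [1000.0, 1500.0], search_window=0.5)
        assert not fit.applied
        np.testing.assert_allclose(corrected["mz"], peaks["mz"])

    def test_correction_reduces_calibrant_residuals(self, rng):
        cal = np.array([1000.0, 1400.0, 1800.0, 2200.0])
        drifted = 1.00002 * cal + 0.05 + rng.normal(0, 0.003, 4)
        peaks = self._peaks(drifted)
        corrected, fit = recalibrate(peaks, list(cal), search_window=0.5)
        before = np.abs(drifted - cal).mean()
        after = np.abs(corrected["mz"].to_numpy() - cal).mean()
        assert after < before


class TestNormalize:
    def _two_spectra(self, factor=2.0):
        rows = []
        for sid, scale in (("a", 1.0), ("b", factor)):
            for mz, inten in ((1000.0, 5.0), (1200.0, 10.0)):
                rows.append(
                    {"spectrum_id": sid, "patient_id": "P1", "region": "diagnosis",
                     "x": 0 if sid == "a" else 1, "y": 0,
                     "mz": mz, "intensity": inten * scale, "snr": 5.0}
                )
        return pd.DataFrame(rows)

    def test_tic_removes_global_scale(self):
        peaks = self._two_spectra(2.0)
        out, factors = normalize(peaks, "tic")
        a = out[out.spectrum_id == "a"].sort_values("mz")["intensity"].to_numpy()
        b = out[out.spectrum_id == "b"].sort_values("mz")["intensity"].to_numpy()
        np.testing.assert_allclose(a, b)
        assert not factors["flagged"].any()

    def test_none_is_identity(self):
        peaks = self._two_spectra()
        out, _ = normalize(peaks, "none")
        np.testing.assert_allclose(out["intensity"], peaks["intensity"])

    def test_calibrant_scaling_tracks_calibrant_intensity(self):
        # calibrant peak doubled in one spectrum only: relative to the tic
        # result, that spectrum's peptide intensities halve
        rows = []
        for sid, cal_scale in (("a", 1.0), ("b", 2.0)):
            rows.append({"spectrum_id": sid, "patient_id": "P1", "region": "diagnosis",
                         "x": 0 if sid == "a" else 1, "y": 0, "mz": 1000.0,
                         "intensity": 10.0, "snr": 5.0})          # analyte
            rows.append({"spectrum_id": sid, "patient_id": "P1", "region": "diagnosis",
                         "x": 0 if sid == "a" else 1, "y": 0, "mz": 1296.685,
                         "intensity": 20.0 * cal_scale, "snr": 5.0})  # calibrant
        peaks = pd.DataFrame(rows)
        out, _ = normalize(peaks, "calibrant", calibrant_masses=[1296.685])
        analyte = out[out["mz"] == 1000.0].set_index("spectrum_id")["intensity"]
        np.testing.assert_allclose(analyte["a"] / analyte["b"], 2.0)

    def test_zero_tic_spectrum_flagged_and_excluded(self):
        peaks = self._two_spectra()
        peaks.loc[peaks.spectrum_id == "b", "intensity"] = 0.0
        with pytest.warns(UserWarning, match="flagged"):
            out, factors = normalize(peaks, "tic")
        assert set(out["spectrum_id"]) == {"a"}
        assert factors.set_index("spectrum_id").loc["b", "flagged"]


class TestNoiseEstimate:
    def test_positive_on_nonconstant_signal(self, rng):
        s = make_spectrum(np.arange(900.0, 1000.0, 0.01),
                          np.abs(rng.standard_normal(10000)))
        est = estimate_noise(s, 50.0)
        assert np.all(est.levels > 0)
        assert est.window == 50.0

    def test_calibrated_on_gaussian_noise(self, rng):
        s = make_spectrum(np.arange(900.0, 1000.0, 0.01),
                          np.clip(rng.standard_normal(10000) + 10, 0, None))
        est = estimate_noise(s, 50.0)
        np.testing.assert_allclose(est.levels, 1.0, rtol=0.1)
        np.testing.assert_allclose(est.floors, 10.0, rtol=0.02)
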