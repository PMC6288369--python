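import math

import numpy as np
import pytest

from filamech.diffraction import (DetectorGeometry, DiffractionProfile, PeakFit,
                                  sum_profiles, subtract_background, fit_peak,
                                  pixel_to_spacing, spacing_to_pixel,
                                  spacing_change, write_profile, read_profile)
from filamech.synthetic import ProfileParams, make_profile_pair


def _profile(intensity, state="relaxed", **kw):
    return DiffractionProfile(np.asarray(intensity, float), state, **kw)


def _gauss_profile(center, sigma=2.0, amp=1e4, n=1000, bg=(300.0, -0.2)):
    x = np.arange(n, dtype=float)
    return _profile(bg[0] + bg[1] * x + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2))


class TestSumProfiles:
    def test_single_profile_identity(self):
        p = _gauss_profile(500.0)
        s = sum_profiles([p])
        np.testing.assert_array_equal(s.intensity, p.intensity)

    def test_linearity(self):
        p = _gauss_profile(500.0)
        s = sum_profiles([p] * 5)
        np.testing.assert_allclose(s.intensity, 5 * p.intensity)
        assert s.label == "sum-of-5"

    def test_mixed_states_rejected(self):
        a = _gauss_profile(500.0)
        b = _profile(a.intensity, state="activated")
        with pytest.raises(ValueError, match="states"):
            sum_profiles([a, b])
        with pytest.raises(ValueError, match="lengths"):
            sum_profiles([a, _profile(a.intensity[:-1])])

    def test_snr_grows_as_sqrt_n(self):
        p = ProfileParams(amplitude=500.0, seed=9, n_exposures=25)
        rel, _ = make_profile_pair(p)

        def snr(prof):
            sub = subtract_background(prof)
            peak = sub.intensity.max()
            flank = sub.intensity[np.abs(np.arange(len(sub.intensity))
                                         - p.peak_center) > 20]
            return peak / flank.std()

        single, summed = snr(rel[0]), snr(sum_profiles(rel))
        assert summed / single == pytest.approx(math.sqrt(25), rel=0.4)


class TestSubtractBackground:
    def test_pure_ramp_removed(self):
        x = np.arange(1000.0)
        p = _profile(200.0 + 0.3 * x)
        out = subtract_background(p)
        assert abs(out.intensity.mean()) < 1e-8

    def test_recovers_generator_line(self):
        p = ProfileParams(seed=10)
        rel, _ = make_profile_pair(p)
        out = subtract_background(sum_profiles(rel))
        intercept, slope = out.background_line
        assert intercept / p.n_exposures == pytest.approx(p.background[0], rel=0.05)
        assert slope / p.n_exposures == pytest.approx(p.background[1], rel=0.10)

    def test_background_free_peak_amplitude_preserved(self):
        p = _gauss_profile(500.0, bg=(0.0, 0.0))
        out = subtract_background(p)
        assert out.intensity.max() == pytest.approx(1e4, rel=1e-3)

    def test_insufficient_flanks_rejected(self):
        p = _gauss_profile(8.0, n=16)
        with pytest.raises(ValueError, match="flanking"):
            subtract_background(p, exclusion_halfwidth=10)


class TestFitPeak:
    @pytest.mark.parametrize("window", [3, 4])
    def test_noiseless_gaussian_exact(self, window):
        prof = subtract_background(_gauss_profile(500.30, sigma=2.0))
        fit = fit_peak(prof, window)
        assert fit.success
        assert fit.center == pytest.approx(500.30, abs=1e-6)
        assert fit.sigma == pytest.approx(2.0, abs=1e-3)

    def test_poisson_center_recovery(self):
        errs = []
        for seed in range(20):
            p = ProfileParams(peak_center=538.25, amplitude=1e4, seed=seed)
            rel, _ = make_profile_pair(p)
            fit = fit_peak(subtract_background(sum_profiles(rel)), 4)
            errs.append(abs(fit.center - 538.25))
        assert np.median(errs) < 0.05

    def test_unresolvable_spike_flagged(self):
        y = np.zeros(200)
        y[100] = 1000.0
        y[101] = 900.0
        fit = fit_peak(_profile(y), 3)
        assert not fit.success

    def test_edge_maximum_flagged(self):
        y = np.linspace(0, 100, 50)
        fit = fit_peak(_profile(y), 4)
        assert not fit.success
        assert "edge" in fit.message

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            fit_peak(_gauss_profile(500.0), 5)


class TestSpacingMapping:
    def test_reference_geometry_gives_tn3_spacing(self):
        # 0.1 nm x 3.47 m camera: a 26.90 mm radius maps to d = 12.90 nm
        geom = DetectorGeometry(wavelength=0.1, camera_length=3.47, pixel_size=0.05)
        d = pixel_to_spacing(26.90 / 0.05, geom)
        assert d == pytest.approx(0.1e-9 * 3.47 / 26.90e-3 * 1e9, rel=1e-12)
        assert d == pytest.approx(12.90, abs=0.005)

    def test_reciprocity(self):
        geom = DetectorGeometry()
        assert pixel_to_spacing(600.0, geom) == pytest.approx(
            2 * pixel_to_spacing(1200.0, geom))

    def test_round_trip(self):
        geom = DetectorGeometry()
        for px in (100.0, 538.0, 910.5):
            assert spacing_to_pixel(pixel_to_spacing(px, geom, 7.0), geom,
                                    7.0) == pytest.approx(px, abs=1e-9)

    def test_zero_radius(self):
        with pytest.raises(ValueError):
            pixel_to_spacing(7.0, DetectorGeometry(), meridian_origin=7.0)


class TestSpacingChange:
    def _fits(self, c_rel, c_act, window=4):
        fr = fit_peak(subtract_background(_gauss_profile(c_rel)), window)
        fa = fit_peak(subtract_background(
            DiffractionProfile(_gauss_profile(c_act).intensity, "activated")), window)
        return fr, fa

    def test_identical_centers_zero_change(self):
        fr, fa = self._fits(538.0, 538.0)
        sc = spacing_change(fr, fa, DetectorGeometry())
        assert sc.percent_change == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention(self):
        # activated centre farther from the origin = smaller d = compression
        fr, fa = self._fits(538.0, 540.0)
        sc = spacing_change(fr, fa, DetectorGeometry())
        assert sc.percent_change < 0

    def test_intensity_rescaling_invariance(self):
        p = ProfileParams(seed=13, relative_shift=0.0034)
        rel, act = make_profile_pair(p)
        base = self._change(rel, act)
        scaled_rel = [DiffractionProfile(7.0 * q.intensity, q.state) for q in rel]
        scaled_act = [DiffractionProfile(7.0 * q.intensity, "activated") for q in act]
        assert self._change(scaled_rel, scaled_act) == pytest.approx(base, abs=1e-9)

    @staticmethod
    def _change(rel, act, window=4):
        fr = fit_peak(subtract_background(sum_profiles(rel)), window)
        fa = fit_peak(subtract_background(sum_profiles(act)), window)
        return spacing_change(fr, fa, DetectorGeometry()).percent_change

    def test_failure_propagates(self):
        fr, _ = self._fits(538.0, 538.0)
        bad = PeakFit(float("nan"), float("nan"), float("nan"), 4, None,
                      float("nan"), float("nan"), success=False, message="boom")
        sc = spacing_change(fr, bad, DetectorGeometry())
        assert not sc.success
        assert "boom" in sc.message

    def test_window_mismatch_rejected(self):
        fr, _ = self._fits(538.0, 538.0, window=4)
        _, fa = self._fits(538.0, 538.0, window=3)
        with pytest.raises(ValueError):
            spacing_change(fr, fa, DetectorGeometry())


class TestProfileIO:
    def test_round_trip(self, tmp_path):
        p = ProfileParams(seed=14, n_exposures=1)
        rel, _ = make_profile_pair(p)
        path = tmp_path / "p.dat"
        write_profile(rel[0], path)
        back = read_profile(path)
        np.testing.assert_allclose(back.intensity, rel[0].intensity, atol=1e-6)
        assert back.state == "relaxed"
        assert back.geometry == rel[0].geometry
        assert back.meridian_origin == rel[0].meridian_origin
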