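"""Medial-axis tracing, perpendicular scanning, calibration and binning."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from chromoband import (
    Band,
    BandModel,
    ChromImage,
    MeanProfile,
    MedialPath,
    WarpModel,
    WindowProfile,
    average_profiles,
    bin_profile,
    calibrate,
    correlate,
    locate_centromere,
    profile_to_track,
    render_chromatid,
    scan_profile,
    subtract_background,
    trace_medial_axis,
    truth_window_track,
)
from chromoband.errors import (
    CalibrationError,
    MarkerMissingError,
    SegmentationError,
    ValidationError,
)
from chromoband.scan import CalibratedScan, RawScan


def hausdorff(a, b):
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def make_raw(arc, green, red=None, blue=None, width=5.0):
    n = len(arc)
    return RawScan(
        arc_fraction=np.asarray(arc, dtype=float),
        mean_green=np.asarray(green, dtype=float),
        mean_red=np.asarray(red if red is not None else np.ones(n), dtype=float),
        mean_blue=np.asarray(blue if blue is not None else np.zeros(n), dtype=float),
        width_px=width,
    )


class TestTraceMedialAxis:
    def test_straight_chromatid_recovers_truth_axis(self, spec, five_band_model):
        img = render_chromatid(spec, five_band_model, noise_sd=0.0, bend_amplitude=0.0, seed=1)
        path = trace_medial_axis(img)
        t = img.truth.axis_rc
        assert np.linalg.norm(path.points_rc[0] - t[0]) <= 2.0
        assert np.linalg.norm(path.points_rc[-1] - t[-1]) <= 2.0
        assert hausdorff(path.points_rc, t) <= 2.0

    def test_bent_noisy_chromatid_still_close(self, spec, five_band_model):
        img = render_chromatid(spec, five_band_model, noise_sd=0.04, bend_amplitude=8.0, seed=3)
        path = trace_medial_axis(img)
        assert hausdorff(path.points_rc, img.truth.axis_rc) <= 2.0

    def test_provided_mode_returns_same_path(self, spec, five_band_model):
        img = render_chromatid(spec, five_band_model, noise_sd=0.0, seed=1)
        truth_path = MedialPath.from_points(img.truth.axis_rc)
        out = trace_medial_axis(img, mode="provided", provided_path=truth_path)
        assert np.array_equal(out.points_rc, truth_path.points_rc)

    def test_provided_path_outside_mask_rejected(self, spec, five_band_model):
        img = render_chromatid(spec, five_band_model, noise_sd=0.0, seed=1)
        bad = MedialPath.from_points(img.truth.axis_rc + 50.0)
        with pytest.raises(ValidationError):
            trace_medial_axis(img, mode="provided", provided_path=bad)

    def test_blank_image_raises_segmentation_error(self):
        z = np.zeros((40, 80), dtype=np.float32)
        img = ChromImage(green=z, red=z.copy(), blue=z.copy())
        with pytest.raises(SegmentationError):
            trace_medial_axis(img)

    def test_pter_end_orients_path(self, spec, five_band_model):
        img = render_chromatid(spec, five_band_model, noise_sd=0.0, seed=1)
        left = trace_medial_axis(img, pter_end="left")
        right = trace_medial_axis(img, pter_end="right")
        assert left.points_rc[0, 1] < left.points_rc[-1, 1]
        assert right.points_rc[0, 1] > right.points_rc[-1, 1]


class TestScanProfile:
    def test_uniform_chromatid_flat_profile(self, spec):
        model = BandModel(baseline=0.5, centromere_gap=False)
        img = render_chromatid(spec, model, noise_sd=0.0, seed=0)
        raw = scan_profile(img, trace_medial_axis(img))
        assert np.ptp(raw.mean_green) < 0.02
        assert raw.arc_fraction[0] == 0.0 and raw.arc_fraction[-1] == 1.0

    def test_single_band_argmax_at_expected_arc_fraction(self, spec):
        model = BandModel(bands=(Band(60.0, 6.0, 1.0),), baseline=0.0, centromere_gap=False)
        img = render_chromatid(spec, model, noise_sd=0.0, seed=0)
        raw = scan_profile(img, trace_medial_axis(img))
        frac = raw.arc_fraction[int(np.argmax(raw.mean_green))]
        seg = 1.0 / len(raw)
        assert abs(frac - 60.0 / 247.0) <= seg + 0.01

    def test_width_invariance_on_uniform_field(self, spec):
        model = BandModel(baseline=0.5, centromere_gap=False)
        img = render_chromatid(spec, model, noise_sd=0.0, seed=0)
        path = trace_medial_axis(img)
        w1 = scan_profile(img, path, width_px=1)
        w5 = scan_profile(img, path, width_px=5)
        assert np.allclose(w1.mean_green, w5.mean_green, atol=0.02)

    def test_marker_pixels_masked_from_green_mean(self, spec):
        model = BandModel(baseline=0.5, centromere_gap=False)
        img = render_chromatid(spec, model, noise_sd=0.0, seed=0)
        path = trace_medial_axis(img)
        raw = scan_profile(img, path)
        ci = locate_centromere(raw)
        # green mean at the marker stays near the uniform level
        assert raw.mean_green[ci] == pytest.approx(0.5, abs=0.05)


class TestLocateCentromere:
    def test_unique_argmax(self):
        raw = make_raw([0.0, 0.3, 0.7, 1.0], [1, 1, 1, 1], blue=[0, 0, 5, 0])
        assert locate_centromere(raw) == 2

    def test_tie_breaks_to_lowest_index(self):
        raw = make_raw([0.0, 0.3, 0.7, 1.0], [1, 1, 1, 1], blue=[0, 7, 7, 0])
        assert locate_centromere(raw) == 1

    def test_all_zero_blue_raises(self):
        raw = make_raw([0.0, 0.5, 1.0], [1, 1, 1], blue=[0, 0, 0])
        with pytest.raises(MarkerMissingError):
            locate_centromere(raw)

    def test_synthetic_centromere_near_120mb(self, spec, five_band_model):
        img = render_chromatid(spec, five_band_model, noise_sd=0.0, seed=1)
        raw = scan_profile(img, trace_medial_axis(img))
        ci = locate_centromere(raw)
        frac = raw.arc_fraction[ci]
        assert abs(frac - 120.0 / 247.0) <= 1.0 / len(raw) + 0.01


class TestCalibrate:
    def test_identity_anchor_gives_globally_linear_map(self, spec):
        arc = np.linspace(0.0, 1.0, 248)
        ci = int(np.argmin(np.abs(arc - 120.0 / 247.0)))
        arc[ci] = 120.0 / 247.0  # centromere segment exactly at its arc fraction
        raw = make_raw(arc, np.random.default_rng(0).uniform(0.1, 1, 248))
        cal = calibrate(raw, ci, spec)
        assert np.allclose(cal.position_mb, arc * 247.0, atol=1e-9)

    @pytest.mark.parametrize("stretch", [0.5, 1.0, 2.0])
    def test_centromere_maps_exactly_and_bands_recovered(self, spec, stretch):
        model = BandModel(
            bands=(Band(40.0, 8.0, 1.0), Band(180.0, 8.0, 0.9)),
            baseline=0.02,
            centromere_gap=True,
        )
        warp = WarpModel(spec, stretch_p=stretch, stretch_q=1.0)
        img = render_chromatid(spec, model, warp=warp, noise_sd=0.0, seed=0)
        raw = scan_profile(img, trace_medial_axis(img))
        ci = locate_centromere(raw)
        cal = calibrate(raw, ci, spec)
        assert cal.position_mb[ci] == 120.0
        w = spec.length_mb / spec.n_scan_windows
        for center in (40.0, 180.0):
            arm = cal.position_mb < 120.0 if center < 120.0 else cal.position_mb > 120.0
            seg = np.flatnonzero(arm)[np.argmax(cal.pct_green[arm])]
            assert abs(cal.position_mb[seg] - center) <= w  # within one window

    def test_channel_maxima_exactly_100(self, spec, rng):
        arc = np.sort(rng.uniform(0, 1, 100))
        arc[0], arc[-1] = 0.0, 1.0
        raw = make_raw(arc, rng.uniform(0.1, 3, 100), red=rng.uniform(0.1, 2, 100))
        cal = calibrate(raw, 50, spec)
        assert cal.pct_green.max() == 100.0
        assert cal.pct_red.max() == 100.0

    def test_centromere_at_endpoint_rejected(self, spec):
        raw = make_raw([0.0, 0.5, 1.0], [1, 2, 3])
        with pytest.raises(CalibrationError):
            calibrate(raw, 0, spec)


class TestBinProfile:
    def _cal(self, spec, pos, green):
        n = len(pos)
        return CalibratedScan(
            position_mb=np.asarray(pos, dtype=float),
            pct_green=np.asarray(green, dtype=float),
            pct_red=np.ones(n) * 50.0,
            centromere_index=n // 2,
            spec=spec,
        )

    def test_uniform_samples_give_equal_windows(self, spec):
        pos = np.linspace(0.0, 247.0, 2500)
        cal = self._cal(spec, pos, np.full(2500, 100.0))
        prof = bin_profile(cal, spec)
        assert prof.green.max() - prof.green.min() <= 100.0  # one sample's worth

    def test_single_sample_lands_in_window_6(self, spec):
        cal = self._cal(spec, [0.0, 60.0, 247.0], [0.0, 42.0, 0.0])
        prof = bin_profile(cal, spec)
        nz = np.flatnonzero(prof.green)
        assert list(nz) == [6]  # 60 / 9.88 -> 6
        assert prof.green[6] == 42.0

    def test_matches_per_sample_bruteforce(self, spec, rng):
        n, nw = 1000, spec.n_scan_windows
        pos = np.sort(rng.uniform(0, 247.0, n))
        green = rng.uniform(0, 100, n)
        cal = self._cal(spec, pos, green)
        prof = bin_profile(cal, spec)
        brute = np.zeros(nw)
        w = 247.0 / nw
        for p, g in zip(pos, green):
            j = min(int(p / w), nw - 1)
            brute[j] += g
        assert np.allclose(prof.green, brute, rtol=0, atol=1e-9)

    def test_mean_stat_option(self, spec):
        cal = self._cal(spec, [1.0, 2.0, 60.0], [10.0, 30.0, 5.0])
        prof = bin_profile(cal, spec, stat="mean")
        assert prof.green[0] == 20.0
        assert prof.green[6] == 5.0


class TestAverageProfiles:
    def _prof(self, spec, green):
        g = np.asarray(green, dtype=float)
        return WindowProfile(green=g, red=np.ones_like(g), spec=spec)

    def test_identical_profiles_mean_equal_sd_zero(self, spec, rng):
        g = rng.uniform(0, 100, spec.n_scan_windows)
        out = average_profiles([self._prof(spec, g)] * 24)
        assert np.allclose(out.mean_green, g)
        assert np.allclose(out.sd_green, 0.0)
        assert out.n_chromatids == 24

    def test_two_profile_closed_form(self, spec):
        a = np.arange(25, dtype=float)
        b = a + 4.0
        out = average_profiles([self._prof(spec, a), self._prof(spec, b)])
        assert np.allclose(out.mean_green, a + 2.0)
        assert np.allclose(out.sd_green, 4.0 / np.sqrt(2.0))

    def test_mixed_specs_rejected(self, spec):
        from chromoband import ChromSpec

        other = ChromSpec("chr2", 243.0, 93.0)
        with pytest.raises(ValidationError):
            average_profiles(
                [self._prof(spec, np.ones(25)), self._prof(other, np.ones(25))]
            )


class TestSubtractBackground:
    def _mp(self, spec, means):
        m = np.asarray(means, dtype=float)
        return MeanProfile(
            mean_green=m,
            sd_green=np.ones_like(m),
            mean_red=m.copy(),
            sd_red=np.ones_like(m),
            n_chromatids=3,
            spec=spec,
        )

    def test_zero_background_leaves_profile_unchanged(self, spec):
        m = np.arange(25, dtype=float)
        m[12] = 0.0  # centromere window
        out = subtract_background(self._mp(spec, m))
        assert np.allclose(out.mean_green, m)

    def test_arithmetic_with_explicit_window(self):
        from chromoband import ChromSpec

        spec3 = ChromSpec("toy", 30.0, 15.0, n_scan_windows=3)
        out = subtract_background(
            self._mp(spec3, [5.0, 2.0, 9.0]), background_window=1
        )
        assert list(out.mean_green) == [3.0, 0.0, 7.0]

    def test_background_window_zero_and_all_nonnegative(self, spec, rng):
        m = rng.uniform(0, 100, 25)
        out = subtract_background(self._mp(spec, m))
        bw = spec.scan_window_of(spec.centromere_mb)
        assert bw == 12
        assert out.mean_green[bw] == 0.0
        assert (out.mean_green >= 0).all()
        assert np.allclose(out.sd_green, 1.0)  # SD unchanged


class TestEndToEndRecovery:
    def test_24_chromatids_recover_truth_profile(self, spec, five_band_model):
        from chromoband.synth import substream

        warp_rng = substream(0, "warps")
        profiles = []
        for i in range(24):
            warp = WarpModel(
                spec,
                stretch_p=float(np.exp(warp_rng.normal(0, 0.1))),
                stretch_q=float(np.exp(warp_rng.normal(0, 0.1))),
            )
            img = render_chromatid(
                spec, five_band_model, warp=warp, noise_sd=0.02,
                bend_amplitude=6.0, seed=1009 + i,
            )
            raw = scan_profile(img, trace_medial_axis(img))
            cal = calibrate(raw, locate_centromere(raw), spec)
            profiles.append(bin_profile(cal, spec))
        mean = subtract_background(average_profiles(profiles))
        truth = truth_window_track(five_band_model, spec)
        res = correlate(profile_to_track(mean), truth)
        assert res.r >= 0.9
        # every truth band's window within +-1 of a local maximum
        vals = mean.mean_green
        w = spec.length_mb / spec.n_scan_windows
        for band in five_band_model.bands:
            bw = min(int(band.center_mb / w), spec.n_scan_windows - 1)
            assert any(
                _is_local_max(vals, j)
                for j in range(max(bw - 1, 0), min(bw + 2, spec.n_scan_windows))
            ), f"band at {band.center_mb} Mb has no nearby local maximum"

    def test_peak_broadening_under_warp_dispersion(self, spec):
        """Averaged peaks are no narrower than the dispersion-free peak."""
        model = BandModel(bands=(Band(155.0, 14.0, 1.0),), baseline=0.02, centromere_gap=True)

        def width_at_half_max(vals):
            j = int(np.argmax(vals))
            half = vals[j] / 2.0
            lo = j
            while lo > 0 and vals[lo - 1] >= half:
                lo -= 1
            hi = j
            while hi < len(vals) - 1 and vals[hi + 1] >= half:
                hi += 1
            return hi - lo + 1

        def profile_for(warps):
            profs = []
            for k, warp in enumerate(warps):
                img = render_chromatid(
                    spec, model, warp=warp, noise_sd=0.0, seed=500 + k
                )
                raw = scan_profile(img, trace_medial_axis(img))
                cal = calibrate(raw, locate_centromere(raw), spec)
                profs.append(bin_profile(cal, spec))
            return subtract_background(average_profiles(profs)).mean_green

        single = profile_for([WarpModel(spec)])
        rng = np.random.default_rng(77)
        dispersed = profile_for(
            [
                WarpModel(
                    spec,
                    stretch_p=float(np.exp(rng.normal(0, 0.35))),
                    stretch_q=float(np.exp(rng.normal(0, 0.35))),
                )
                for _ in range(8)
            ]
        )
        assert width_at_half_max(dispersed) >= width_at_half_max(single)


def _is_local_max(vals, j):
    lo = vals[j - 1] if j > 0 else -np.inf
    hi = vals[j + 1] if j < len(vals) - 1 else -np.inf
    return vals[j] >= lo and vals[j] >= hi
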