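"""Inverse pipeline: profiles, segmentation, strobe and lifetime recovery."""

import numpy as np
import pytest

import shutterlum as sl
from shutterlum.analysis import SegmentationPolicy, default_edge_exclusion


def make_profile(values, channel="R"):
    values = np.asarray(values, dtype=float)
    return sl.RowProfile(channel=channel, values=values, n_rows=len(values))


class TestSplitChannels:
    def test_pure_red_image(self):
        img = np.zeros((4, 5, 3), dtype=np.uint8)
        img[:, :, 0] = 200
        r, g, b = sl.split_channels(img)
        assert np.all(r == 200) and np.all(g == 0) and np.all(b == 0)

    def test_reassembly_is_bit_exact(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (6, 7, 3), dtype=np.uint8)
        r, g, b = sl.split_channels(img)
        np.testing.assert_array_equal(np.dstack([r, g, b]), img)

    def test_grayscale_rejected(self):
        with pytest.raises(sl.ChannelError):
            sl.split_channels(np.zeros((4, 5), dtype=np.uint8))

    def test_simulated_two_emitter_channels(self, solid_capture_nf):
        """Blue channel shows square-wave banding; red shows decaying
        (sawtooth-like) banding from the slow emitter."""
        r, g, b = sl.split_channels(solid_capture_nf.expected_signal)
        bp, rp = b.mean(axis=1), r.mean(axis=1)
        # blue: bimodal (square) - most rows near min or max
        lo, hi = bp.min(), bp.max()
        frac_extreme = np.mean((bp < lo + 0.2 * (hi - lo)) | (bp > hi - 0.2 * (hi - lo)))
        assert frac_extreme > 0.8
        # red: within an off band the profile decreases steadily
        seg = sl.segment_bands(make_profile(bp, "B"))
        s, e = seg.off_intervals()[1]
        band = rp[s + 2 : e - 2]
        assert np.all(np.diff(band) < 0)


class TestRowProfile:
    def test_constant_image(self):
        img = np.full((10, 8), 37.0)
        prof = sl.extract_row_profile(img, 0, 8)
        assert np.all(prof.values == 37.0)

    def test_single_column_range(self):
        img = np.arange(40, dtype=float).reshape(10, 4)
        prof = sl.extract_row_profile(img, 2, 3)
        np.testing.assert_array_equal(prof.values, img[:, 2])

    def test_empty_range_rejected(self):
        with pytest.raises(sl.InputError):
            sl.extract_row_profile(np.zeros((5, 5)), 3, 3)

    def test_default_is_middle_half(self):
        img = np.zeros((5, 8))
        img[:, 2:6] = 1.0  # middle 50%
        prof = sl.extract_row_profile(img)
        assert prof.col_range == (2, 6)
        assert np.all(prof.values == 1.0)

    def test_profile_matches_expected_signal(self, solid_capture_nf):
        exp = solid_capture_nf.expected_signal[:, :, 2]
        prof = sl.extract_row_profile(exp, 0, exp.shape[1])
        np.testing.assert_allclose(prof.values, exp.mean(axis=1), rtol=1e-12)

    def test_saturated_rows_flagged(self):
        img = np.zeros((6, 4), dtype=np.uint8)
        img[3, 1] = 255
        prof = sl.extract_row_profile(img, 0, 4)
        assert prof.saturated_rows == frozenset({3})


class TestSegmentBands:
    def test_ideal_square_interval_lengths(self):
        # alternating 166/167-row bands, as produced by 600.08 Hz at a
        # 10 us line time
        values = []
        state = []
        widths = [166, 167] * 6
        for i, w in enumerate(widths):
            on = i % 2 == 0
            values += [100.0 if on else 10.0] * w
            state += [on] * w
        seg = sl.segment_bands(make_profile(values))
        inner = seg.intervals[1:-1]
        assert all(e - s in (166, 167) for s, e, _ in inner)
        assert all(
            a[2] != b[2] for a, b in zip(seg.intervals, seg.intervals[1:])
        )

    def test_constant_profile_is_flat_verdict(self):
        with pytest.raises(sl.FlatProfileError):
            sl.segment_bands(make_profile(np.full(1000, 42.0)))

    def test_single_cycle_is_insufficient(self):
        values = [10.0] * 100 + [100.0] * 100 + [10.0] * 100
        with pytest.raises(sl.InsufficientCyclesError):
            sl.segment_bands(make_profile(values))

    def test_duty_from_band_widths(self, solid_capture_nf, solid_fixture_nf):
        prof = make_profile(
            solid_capture_nf.expected_signal[:, :, 2].mean(axis=1), "B"
        )
        seg = sl.segment_bands(prof)
        on = [e - s for s, e, st in seg.intervals[1:-1] if st == "on"]
        off = [e - s for s, e, st in seg.intervals[1:-1] if st == "off"]
        assert np.mean(on) / (np.mean(on) + np.mean(off)) == pytest.approx(
            0.5, abs=0.01
        )

    def test_short_runs_are_merged(self):
        values = np.array([10.0] * 50 + [100.0] * 50 + [10.0] * 50 + [100.0] * 50 + [10.0] * 50)
        values[25] = 100.0  # single-row glitch
        seg = sl.segment_bands(make_profile(values))
        assert len(seg.intervals) == 5


class TestEstimateStrobe:
    @pytest.mark.parametrize("freq", [100.0, 600.08, 2000.0])
    @pytest.mark.parametrize("duty", [0.2, 0.5, 0.8])
    def test_round_trip_noise_free(self, freq, duty):
        fix = sl.make_fixture(
            sl.FixtureSpec(
                "two_emitter_solid",
                {
                    "n_cols": 16,
                    "peak_snr": None,
                    "frequency": freq,
                    "duty_cycle": duty,
                    # interior first edge so 100 Hz still shows >= 2
                    # complete interior cycles within the 30 ms frame
                    "phase": 0.3 / freq,
                },
            )
        )
        cap = fix.capture(noise=False)
        prof = sl.extract_row_profile(cap.image[:, :, 2], channel="B")
        seg = sl.segment_bands(prof)
        est = sl.estimate_strobe(seg, fix.sensor)
        assert est.frequency == pytest.approx(freq, rel=0.005)
        assert est.duty_cycle == pytest.approx(duty, abs=0.02)

    def test_frequency_scales_inversely_with_line_time(self, solid_capture_nf, solid_fixture_nf):
        prof = sl.extract_row_profile(solid_capture_nf.image[:, :, 2], channel="B")
        seg = sl.segment_bands(prof)
        sensor = solid_fixture_nf.sensor
        f1 = sl.estimate_strobe(seg, sensor).frequency
        f2 = sl.estimate_strobe(seg, sensor.replace(line_time=2 * sensor.line_time)).frequency
        assert f2 == pytest.approx(f1 / 2, rel=1e-12)

    def test_insufficient_cycles_rejected(self):
        seg = sl.BandSegmentation(
            intervals=[(0, 50, "off"), (50, 100, "on"), (100, 150, "off"), (150, 200, "on")],
            threshold_used=50.0,
            rising_edges=np.array([49.5, 149.5]),
            falling_edges=np.array([99.5]),
        )
        sensor = sl.SensorConfig(n_rows=200, n_cols=4, line_time=1e-5, exposure_time=1e-5)
        with pytest.raises(sl.InsufficientCyclesError):
            sl.estimate_strobe(seg, sensor)


class TestRowsToTime:
    def test_window_center_convention(self):
        sensor = sl.SensorConfig(n_rows=100, n_cols=4, line_time=1e-5, exposure_time=1.4e-5)
        assert sl.rows_to_time(0, sensor) == pytest.approx(7e-6)
        t = sl.rows_to_time(np.array([0, 1]), sensor)
        assert t[1] - t[0] == pytest.approx(sensor.line_time)
        assert sl.rows_to_time(166.64, sensor) == pytest.approx(1.6664e-3 + 7e-6)


class TestFitDecay:
    def make_exp_profile(self, tau, n=80, a=500.0, b=20.0, line_time=1e-5, noise=None, seed=0):
        t = np.arange(n) * line_time
        y = a * np.exp(-t / tau) + b
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, n)
        return make_profile(y)

    def test_noise_free_exponential_recovered(self):
        sensor = sl.SensorConfig(n_rows=80, n_cols=4, line_time=1e-5, exposure_time=1e-5)
        prof = self.make_exp_profile(5e-4)
        fit = sl.fit_decay(prof, (0, 80), sensor, t0_row=0.0, edge_exclude=0)
        assert fit.tau == pytest.approx(5e-4, rel=1e-3)
        assert fit.r_squared > 0.999

    def test_flat_profile_unreliable(self):
        sensor = sl.SensorConfig(n_rows=80, n_cols=4, line_time=1e-5, exposure_time=1e-5)
        rng = np.random.default_rng(1)
        prof = make_profile(50.0 + rng.normal(0, 2.0, 80))
        with pytest.raises(sl.UnreliableFitError):
            sl.fit_decay(prof, (0, 80), sensor, edge_exclude=0)

    def test_too_few_rows_is_data_error(self):
        sensor = sl.SensorConfig(n_rows=80, n_cols=4, line_time=1e-5, exposure_time=1e-5)
        prof = self.make_exp_profile(5e-4)
        with pytest.raises(sl.DataError):
            sl.fit_decay(prof, (0, 5), sensor, edge_exclude=1)

    def test_closed_form_emission_fits_exponential_after_edge_exclusion(
        self, solid_capture_nf, solid_fixture_nf
    ):
        """Rows two or more past the falling edge decay purely
        exponentially despite the finite exposure window."""
        sensor = solid_fixture_nf.sensor
        prof = make_profile(
            solid_capture_nf.expected_signal[:, :, 0].mean(axis=1)
        )
        seg = sl.segment_bands(
            make_profile(solid_capture_nf.expected_signal[:, :, 2].mean(axis=1), "B")
        )
        assert default_edge_exclusion(sensor) == 2
        s, e = seg.off_intervals()[2]
        fit = sl.fit_decay(prof, (s, e), sensor, t0_row=float(s))
        assert fit.tau == pytest.approx(solid_fixture_nf.truth["tau_slow"], rel=0.01)


class TestEstimateLifetime:
    @pytest.fixture(scope="class")
    @classmethod
    def noisy_capture(cls):
        fix = sl.make_fixture(
            sl.FixtureSpec("two_emitter_solid", {"n_cols": 48, "peak_snr": 20.0})
        )
        return fix, fix.capture(seed=11)

    def seg_of(self, image):
        prof = sl.extract_row_profile(image[:, :, 2], channel="B")
        return sl.segment_bands(prof)

    def test_most_bands_accepted_and_tau_within_3pct(self, noisy_capture):
        fix, cap = noisy_capture
        est = sl.estimate_lifetime(cap.image, fix.sensor, self.seg_of(cap.image), "R")
        assert est.n_bands_used >= 15
        assert est.tau == pytest.approx(fix.truth["tau_slow"], rel=0.03)

    def test_fast_only_image_has_no_lifetime(self):
        # pure reflection (instantaneous response): off bands are dark
        fix = sl.make_fixture(
            sl.FixtureSpec("pulsed_led", {"n_cols": 48, "peak_snr": 20.0})
        )
        cap = fix.capture(seed=11)
        with pytest.raises(sl.NoLifetimeError):
            sl.estimate_lifetime(cap.image, fix.sensor, self.seg_of(cap.image), "R")

    def test_unresolvable_lifetime_flagged(self):
        """tau = 10x period: the off band covers 5% of a lifetime, so
        fits must be rejected rather than silently reported."""
        period = 1.0 / 600.08
        fix = sl.make_fixture(
            sl.FixtureSpec(
                "two_emitter_solid",
                {"n_cols": 32, "peak_snr": 50.0, "tau_slow": 10 * period},
            )
        )
        cap = fix.capture(seed=2)
        with pytest.raises(sl.NoLifetimeError):
            sl.estimate_lifetime(cap.image, fix.sensor, self.seg_of(cap.image), "R")

    def test_scaling_invariance(self, solid_capture_nf, solid_fixture_nf):
        """Multiplying a noise-free capture by c > 0 changes no estimate."""
        sensor = solid_fixture_nf.sensor
        base = solid_capture_nf.expected_signal
        results = []
        for c in (1.0, 7.3):
            img = base * c
            prof = sl.extract_row_profile(img[:, :, 2], channel="B")
            seg = sl.segment_bands(prof)
            strobe = sl.estimate_strobe(seg, sensor)
            est = sl.estimate_lifetime(img, sensor, seg, "R")
            results.append((strobe.frequency, strobe.duty_cycle, est.tau))
        f1, d1, t1 = results[0]
        f2, d2, t2 = results[1]
        assert f2 == pytest.approx(f1, rel=1e-9)
        assert d2 == pytest.approx(d1, rel=1e-9)
        assert t2 == pytest.approx(t1, rel=1e-6)


class TestIdentifySpecies:
    LIBRARY = [("Eu-complex", 5e-4, 0.10), ("Tb-complex", 1e-3, 0.10)]

    def test_match_unknown_and_ambiguous(self):
        assert sl.identify_species(5.1e-4, self.LIBRARY) == "Eu-complex"
        assert sl.identify_species(5e-5, self.LIBRARY) == "unknown"
        wide = [("a", 5e-4, 0.5), ("b", 7e-4, 0.5)]
        with pytest.raises(sl.AmbiguousMatchError):
            sl.identify_species(6e-4, wide)

    def test_empty_library_rejected(self):
        with pytest.raises(sl.InputError):
            sl.identify_species(5e-4, [])


class TestAuthenticateTag:
    @pytest.fixture(scope="class")
    @classmethod
    def tag(cls):
        fix = sl.make_fixture(
            sl.FixtureSpec("security_tag", {"n_cols": 240, "peak_snr": 30.0})
        )
        return fix, fix.capture(seed=5)

    def test_correct_template_passes(self, tag):
        fix, cap = tag
        report = sl.authenticate_tag(cap.image, fix.sensor, fix.truth["template"])
        assert report["passed"]
        assert len(report["regions"]) == 3

    def test_swapped_lifetimes_fail(self, tag):
        fix, cap = tag
        swapped = []
        for reg in fix.truth["template"]:
            if reg.kind == "slow":
                other = sl.TagRegion(
                    reg.name, reg.col_start, reg.col_end, reg.channel,
                    kind="slow",
                    tau_ref=(1e-3 if reg.tau_ref == 5e-4 else 5e-4),
                    tolerance=reg.tolerance,
                )
                swapped.append(other)
            else:
                swapped.append(reg)
        report = sl.authenticate_tag(cap.image, fix.sensor, swapped)
        assert not report["passed"]

    def test_steady_illumination_refuses(self):
        fix = sl.make_fixture(
            sl.FixtureSpec(
                "security_tag", {"n_cols": 240, "peak_snr": 30.0, "pulsed": False}
            )
        )
        cap = fix.capture(seed=5)
        with pytest.raises(sl.FlatProfileError):
            sl.authenticate_tag(cap.image, fix.sensor, fix.truth["template"])

    def test_region_outside_image_is_geometry_error(self, tag):
        fix, cap = tag
        bad = [sl.TagRegion("oops", 0, 10_000, "R", kind="slow", tau_ref=5e-4)]
        with pytest.raises(sl.GeometryError):
            sl.authenticate_tag(cap.image, fix.sensor, bad)
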