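"""Forward capture simulation: analytic integrals, noise, banding."""

import numpy as np
import pytest

import shutterlum as sl
from conftest import quad_emission_integral


def small_sensor(**kw):
    defaults = dict(
        n_rows=600, n_cols=8, line_time=1e-5, exposure_time=1.4e-5,
        bit_depth=16, photon_scale=1000.0, full_well=4000.0,
    )
    defaults.update(kw)
    return sl.SensorConfig(**defaults)


def uniform_scene(sensor, emitters, reflectance=0.0, background=(0, 0, 0)):
    shape = (sensor.n_rows, sensor.n_cols)
    return sl.Scene(
        shape=shape,
        emitters=emitters,
        amplitude_maps=[np.ones(shape) for _ in emitters],
        reflectance_map=np.full(shape, reflectance),
        background=background,
    )


FAST_BLUE = sl.Emitter("fast", 0.0, 1.0, (0, 0, 1), is_fast=True)


class TestIntegrateRowSignal:
    def test_fast_emitter_off_window_gives_background_only(self):
        sensor = small_sensor()
        # phase shifted so row 0's window [0, 14 us] sits inside OFF
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5, phase=1e-4)
        scene = uniform_scene(sensor, [FAST_BLUE], background=(5e5, 5e5, 5e5))
        counts = sl.integrate_row_signal(0, scene, sensor, pulse)
        expected_bg = 5e5 * sensor.exposure_time
        np.testing.assert_allclose(counts, expected_bg, rtol=1e-12)

    @pytest.mark.parametrize("phase", [0.0, 3.7e-4, 1.1e-3])
    def test_full_period_window_is_phase_invariant(self, phase):
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5, phase=phase)
        sensor = small_sensor(exposure_time=pulse.period, line_time=1e-5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        counts = sl.integrate_row_signal(3, scene, sensor, pulse)
        expected = (
            sensor.photon_scale * pulse.duty_cycle * pulse.period
        )  # brightness 1, blue channel
        assert counts[0, 2] == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("row", [0, 17, 333])
    @pytest.mark.parametrize("ratio", [0.1, 0.3, 1.0])
    def test_analytic_integral_matches_quadrature(self, row, ratio):
        sensor = small_sensor()
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5, phase=2e-4)
        slow = sl.Emitter("slow", ratio / pulse.frequency, 1.0 / (ratio / pulse.frequency), (1, 0, 0))
        a, b = sl.row_exposure_window(row, sensor)
        for em in (slow, FAST_BLUE):
            analytic = sl.emission_integral(a, b, em, pulse)
            oracle = quad_emission_integral(a, b, em, pulse)
            assert analytic == pytest.approx(oracle, rel=1e-6)


class TestSimulateCapture:
    def test_noise_free_image_is_quantized_expectation(self):
        sensor = small_sensor()
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
        gain = sensor.max_code / sensor.full_well
        expected = np.clip(
            np.rint(np.clip(cap.expected_signal, 0, sensor.full_well) * gain),
            0, sensor.max_code,
        )
        np.testing.assert_array_equal(cap.image, expected.astype(np.uint16))

    def test_seed_determinism(self):
        sensor = small_sensor(read_noise_sigma=2.0)
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        a = sl.simulate_capture(scene, sensor, pulse, seed=42)
        b = sl.simulate_capture(scene, sensor, pulse, seed=42)
        c = sl.simulate_capture(scene, sensor, pulse, seed=43)
        np.testing.assert_array_equal(a.image, b.image)
        assert np.any(a.image != c.image)

    def test_symmetric_banding_at_half_duty(self):
        """On and off bands occupy equal row counts when duty is 50%."""
        sensor = small_sensor(n_rows=2000)
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
        profile = cap.expected_signal[:, 0, 2]
        thr = (profile.max() + profile.min()) / 2
        on_rows = int(np.sum(profile > thr))
        assert on_rows == pytest.approx(sensor.n_rows / 2, abs=0.02 * sensor.n_rows)

    def test_band_count_tracks_frequency(self):
        """The number of on->off transitions equals frequency * frame time."""
        for freq in (300.0, 600.08, 1200.0):
            sensor = small_sensor(n_rows=3000)
            pulse = sl.ExcitationPulse(frequency=freq, duty_cycle=0.5)
            scene = uniform_scene(sensor, [FAST_BLUE])
            cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
            profile = cap.expected_signal[:, 0, 2]
            thr = (profile.max() + profile.min()) / 2
            state = profile > thr
            n_falling = int(np.sum(state[:-1] & ~state[1:]))
            expected = freq * sensor.n_rows * sensor.line_time
            assert abs(n_falling - expected) <= 1

    def test_band_contrast_decreases_with_exposure(self):
        """Banding contrast falls as the exposure window approaches the
        strobe period and vanishes at integer multiples of it (between
        integer multiples a reduced ripple survives)."""
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)

        def contrast(exposure_periods):
            sensor = small_sensor(
                n_rows=1500, exposure_time=exposure_periods * pulse.period
            )
            scene = uniform_scene(sensor, [FAST_BLUE])
            cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
            p = cap.expected_signal[:, 0, 2]
            return (p.max() - p.min()) / (p.max() + p.min())

        ramp = [contrast(x) for x in (0.1, 0.4, 0.7, 0.9, 1.0)]
        # non-increasing up to row-sampling granularity
        assert all(a >= b - 0.02 for a, b in zip(ramp, ramp[1:]))
        assert ramp[0] > 0.9
        for k in (1.0, 2.0):
            assert contrast(k) == pytest.approx(0.0, abs=1e-9)

    def test_slow_channel_decays_within_off_band(self):
        sensor = small_sensor(n_rows=1200)
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        slow = sl.Emitter("slow", 5e-4, 2000.0, (1, 0, 0))
        scene = uniform_scene(sensor, [slow])
        cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
        profile = cap.expected_signal[:, 0, 0]
        # second full off band: rows ~252..416 (after 1.5 cycles)
        period_rows = pulse.period / sensor.line_time
        start = int(1.5 * period_rows) + 3
        end = int(2.0 * period_rows) - 3
        band = profile[start:end]
        assert np.all(np.diff(band) < 0)

    def test_steady_illumination_has_no_banding(self):
        sensor = small_sensor(n_rows=1500)
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5, enabled=False)
        slow = sl.Emitter("slow", 5e-4, 2000.0, (1, 0, 0))
        scene = uniform_scene(sensor, [slow, FAST_BLUE], reflectance=0.3)
        cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
        for ch in range(3):
            p = cap.expected_signal[:, 0, ch]
            assert p.std() == pytest.approx(0.0, abs=1e-9 * max(p.mean(), 1))

    def test_saturation_clips_at_max_code(self):
        sensor = small_sensor(full_well=10.0, photon_scale=1e7)  # saturates
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
        assert cap.image.max() == sensor.max_code
        assert cap.saturated_fraction > 0

    def test_shape_mismatch_raises(self):
        sensor = small_sensor()
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        other = small_sensor(n_rows=700)
        scene = uniform_scene(other, [FAST_BLUE])
        with pytest.raises(sl.ShapeError):
            sl.simulate_capture(scene, sensor, pulse)


class TestCaptureIO:
    @pytest.mark.parametrize("bit_depth,ext", [(8, "img.png"), (16, "img.tif")])
    def test_save_load_roundtrip(self, tmp_path, bit_depth, ext):
        sensor = small_sensor(bit_depth=bit_depth, full_well=255.0 if bit_depth == 8 else 4000.0)
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        cap = sl.simulate_capture(scene, sensor, pulse, seed=7)
        path = tmp_path / ext
        sidecar = sl.save_capture(cap, path)
        loaded = sl.load_image(path)
        np.testing.assert_array_equal(loaded, cap.image)
        from shutterlum.simulate import load_metadata

        sensor2, pulse2, meta = load_metadata(sidecar)
        assert sensor2 == sensor
        assert pulse2 == pulse
        assert meta["seed"] == 7

    def test_png_requires_8_bit(self, tmp_path):
        sensor = small_sensor(bit_depth=16)
        pulse = sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)
        scene = uniform_scene(sensor, [FAST_BLUE])
        cap = sl.simulate_capture(scene, sensor, pulse, noise=False)
        with pytest.raises(sl.InputError):
            sl.save_capture(cap, tmp_path / "img.png")
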