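"""Render noisy, quantized RGB rolling-shutter captures of a scene.

The expected (noise-free) signal of each pixel is the exact time
integral of the scene's emission over that row's exposure window,
evaluated analytically from the closed-form strobe kinetics — no time
stepping.  Noise follows the standard CMOS model: Poisson shot noise on
the expected electron counts, additive Gaussian read noise, clipping at
full well, then linear quantization to the sensor bit depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError, ShapeError
from .physics import (
    WHITE_WEIGHTS,
    ExcitationPulse,
    Scene,
    SensorConfig,
    emission_integral,
    excitation_on_time,
    row_exposure_window,
)

__all__ = [
    "CaptureResult",
    "integrate_row_signal",
    "render_expected",
    "add_noise",
    "quantize",
    "simulate_capture",
    "save_capture",
    "load_image",
    "load_metadata",
]


@dataclass
class CaptureResult:
    """A simulated capture: quantized image, noise-free expectation and
    the full configuration needed to reproduce it."""

    image: np.ndarray  # (n_rows, n_cols, 3) uint8/uint16
    expected_signal: np.ndarray  # same shape, float electrons
    sensor: SensorConfig
    pulse: ExcitationPulse
    seed: int | None
    noise: bool = True

    @property
    def saturated_fraction(self) -> float:
        return float(np.mean(self.image == self.sensor.max_code))

    def metadata(self) -> dict:
        return {
            "sensor": self.sensor.to_dict(),
            "pulse": self.pulse.to_dict(),
            "seed": self.seed,
            "noise": self.noise,
        }


def _row_integrals(scene: Scene, sensor: SensorConfig, pulse: ExcitationPulse):
    """Per-row emission integrals (one scalar per emitter per row) and
    per-row LED-on overlap.  Column structure enters only through the
    amplitude maps, so these are shared across columns."""
    n_rows = sensor.n_rows
    em_int = np.empty((len(scene.emitters), n_rows))
    x_int = np.empty(n_rows)
    for r in range(n_rows):
        a, b = row_exposure_window(r, sensor)
        x_int[r] = excitation_on_time(a, b, pulse)
        for i, em in enumerate(scene.emitters):
            em_int[i, r] = emission_integral(a, b, em, pulse)
    x_int *= pulse.amplitude
    return em_int, x_int


def integrate_row_signal(
    row: int, scene: Scene, sensor: SensorConfig, pulse: ExcitationPulse
) -> np.ndarray:
    """Expected electron counts of one row, shape ``(n_cols, 3)``."""
    _check_shapes(scene, sensor)
    a, b = row_exposure_window(row, sensor)
    out = np.zeros((sensor.n_cols, 3))
    for em, amap in zip(scene.emitters, scene.amplitude_maps):
        integral = emission_integral(a, b, em, pulse)
        out += np.outer(amap[row], em.weights) * integral
    x = excitation_on_time(a, b, pulse) * pulse.amplitude
    out += np.outer(scene.reflectance_map[row], WHITE_WEIGHTS) * x
    out *= sensor.photon_scale
    out += np.asarray(scene.background) * sensor.exposure_time
    return out


def render_expected(
    scene: Scene, sensor: SensorConfig, pulse: ExcitationPulse
) -> np.ndarray:
    """Noise-free expected electron counts, shape ``(n_rows, n_cols, 3)``."""
    _check_shapes(scene, sensor)
    em_int, x_int = _row_integrals(scene, sensor, pulse)
    expected = np.zeros((sensor.n_rows, sensor.n_cols, 3))
    for i, em in enumerate(scene.emitters):
        expected += (
            (scene.amplitude_maps[i] * em_int[i][:, None])[:, :, None]
            * em.weights[None, None, :]
        )
    expected += (
        (scene.reflectance_map * x_int[:, None])[:, :, None]
        * WHITE_WEIGHTS[None, None, :]
    )
    expected *= sensor.photon_scale
    expected += (
        np.asarray(scene.background)[None, None, :] * sensor.exposure_time
    )
    return expected


def quantize(electrons: np.ndarray, sensor: SensorConfig) -> np.ndarray:
    """Clip at full well and map linearly onto the output code range."""
    e = np.clip(electrons, 0.0, sensor.full_well)
    codes = np.rint(e * (sensor.max_code / sensor.full_well))
    dtype = np.uint8 if sensor.bit_depth == 8 else np.uint16
    return np.clip(codes, 0, sensor.max_code).astype(dtype)


def add_noise(
    expected: np.ndarray,
    sensor: SensorConfig,
    rng: np.random.Generator | int | None,
) -> np.ndarray:
    """Apply shot noise, read noise, clipping and quantization."""
    rng = np.random.default_rng(rng)
    electrons = rng.poisson(expected).astype(float)
    if sensor.read_noise_sigma > 0:
        electrons += rng.normal(0.0, sensor.read_noise_sigma, expected.shape)
    return quantize(electrons, sensor)


def simulate_capture(
    scene: Scene,
    sensor: SensorConfig,
    pulse: ExcitationPulse,
    seed: int | None = 0,
    noise: bool = True,
) -> CaptureResult:
    """Full forward simulation.  Same seed ⇒ bit-identical output."""
    expected = render_expected(scene, sensor, pulse)
    if noise:
        image = add_noise(expected, sensor, seed)
    else:
        image = quantize(expected, sensor)
    return CaptureResult(
        image=image,
        expected_signal=expected,
        sensor=sensor,
        pulse=pulse,
        seed=seed,
        noise=noise,
    )


def _check_shapes(scene: Scene, sensor: SensorConfig) -> None:
    if scene.shape != (sensor.n_rows, sensor.n_cols):
        raise ShapeError(
            f"scene shape {scene.shape} != sensor "
            f"({sensor.n_rows}, {sensor.n_cols})"
        )


# ---------------------------------------------------------------------------
# file IO


def save_capture(result: CaptureResult, path: str | Path) -> Path:
    """Write the image (8-bit PNG or 16-bit TIFF, by extension) and a
    sidecar ``.json`` with the full configuration.  Returns the sidecar
    path."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        if result.sensor.bit_depth != 8:
            raise InputError("PNG output supports bit_depth 8 only; use TIFF")
        Image.fromarray(result.image, mode="RGB").save(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, result.image)
    else:
        raise InputError(f"unsupported image format {suffix!r}")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(result.metadata(), indent=2))
    return sidecar


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF capture back as an array."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        return np.asarray(Image.open(path))
    if suffix in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    raise InputError(f"unsupported image format {suffix!r}")


def load_metadata(path: str | Path) -> tuple[SensorConfig, ExcitationPulse, dict]:
    """Read a sidecar JSON back into typed configuration objects."""
    raw = json.loads(Path(path).read_text())
    return (
        SensorConfig.from_dict(raw["sensor"]),
        ExcitationPulse.from_dict(raw["pulse"]),
        raw,
    )
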