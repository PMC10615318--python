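"""Sensor, excitation and emitter models with closed-form strobe kinetics.

A rolling-shutter CMOS sensor exposes its rows sequentially: row ``r``
starts integrating at ``r * line_time`` and integrates for
``exposure_time``.  When the scene is lit by a square-wave strobe whose
period is shorter than the frame traversal time, successive rows sample
different phases of the strobe cycle and the image shows horizontal
banding.  A luminophore with lifetime tau driven by the strobe reaches a
periodic steady state of the linear kinetics

    dE/dt = b * x(t) - E / tau

where ``x(t)`` is the excitation waveform and ``b`` the emission rate
coefficient.  Over one cycle with on-time ``T_on`` and off-time ``T_off``
the solution is piecewise exponential; the boundary levels are

    E2 = b*tau * (1 - exp(-T_on/tau)) / (1 - exp(-period/tau))   (end of ON)
    E1 = E2 * exp(-T_off/tau)                                    (end of OFF)

which this module evaluates in closed form, together with the exact time
integrals the capture simulator needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "SensorConfig",
    "ExcitationPulse",
    "Emitter",
    "Scene",
    "excitation_state",
    "excitation_on_time",
    "periodic_boundary_levels",
    "emission_rate",
    "emission_integral",
    "average_emission",
    "row_exposure_window",
]

_CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class SensorConfig:
    """Rolling-shutter timing and noise parameters.

    Parameters
    ----------
    n_rows, n_cols
        Sensor geometry.
    line_time
        Seconds between exposure starts of consecutive rows; the
        conversion factor from row index to time.
    exposure_time
        Seconds each row integrates.
    bit_depth
        8 or 16; output codes lie in ``[0, 2**bit_depth - 1]``.
    photon_scale
        Expected photoelectrons per unit radiant exposure (gain surrogate).
    read_noise_sigma
        Read noise, electrons RMS.
    full_well
        Electrons at saturation; electrons are mapped linearly onto the
        output code range.
    readout_reversed
        If True the last row is read first (sensor orientation flag).
    """

    n_rows: int
    n_cols: int
    line_time: float
    exposure_time: float
    bit_depth: int = 8
    photon_scale: float = 1.0
    read_noise_sigma: float = 0.0
    full_well: float = 255.0
    readout_reversed: bool = False

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise InputError("n_rows must be >= 2")
        if self.n_cols < 1:
            raise InputError("n_cols must be >= 1")
        if self.line_time <= 0:
            raise InputError("line_time must be positive")
        if self.exposure_time <= 0:
            raise InputError("exposure_time must be positive")
        if self.bit_depth not in (8, 16):
            raise InputError("bit_depth must be 8 or 16")
        if self.photon_scale <= 0:
            raise InputError("photon_scale must be positive")
        if self.read_noise_sigma < 0:
            raise InputError("read_noise_sigma must be >= 0")
        if self.full_well <= 0:
            raise InputError("full_well must be positive")

    @property
    def max_code(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def frame_time(self) -> float:
        """Time from the first row's exposure start to the last row's."""
        return (self.n_rows - 1) * self.line_time

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "line_time": self.line_time,
            "exposure_time": self.exposure_time,
            "bit_depth": self.bit_depth,
            "photon_scale": self.photon_scale,
            "read_noise_sigma": self.read_noise_sigma,
            "full_well": self.full_well,
            "readout_reversed": self.readout_reversed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorConfig":
        return cls(**d)

    def replace(self, **kw) -> "SensorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class ExcitationPulse:
    """Ideal square-wave strobe.

    ``phase`` is the time of the first rising edge relative to row 0's
    exposure start.  ``enabled=False`` models steady (constant)
    illumination at ``amplitude`` — the control condition in which
    rolling-shutter time gating cannot operate.
    """

    frequency: float
    duty_cycle: float
    phase: float = 0.0
    amplitude: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InputError("frequency must be positive")
        if not 0.0 < self.duty_cycle < 1.0:
            raise InputError("duty_cycle must lie in (0, 1)")
        if self.amplitude < 0:
            raise InputError("amplitude must be >= 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def t_on(self) -> float:
        return self.duty_cycle * self.period

    @property
    def t_off(self) -> float:
        return self.period - self.t_on

    def to_dict(self) -> dict:
        return {
            "frequency": self.frequency,
            "duty_cycle": self.duty_cycle,
            "phase": self.phase,
            "amplitude": self.amplitude,
            "enabled": self.enabled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExcitationPulse":
        return cls(**d)

    def replace(self, **kw) -> "ExcitationPulse":
        return replace(self, **kw)


@dataclass(frozen=True)
class Emitter:
    """A single-exponential luminophore.

    ``is_fast`` marks emitters whose lifetime is far below the line time
    (sub-nanosecond fluorophores against a ~10 µs line time): their
    emission tracks the excitation instantaneously and ``lifetime`` is
    ignored.  ``rgb_weights`` are normalized channel fractions of the
    emission.
    """

    name: str
    lifetime: float
    brightness: float
    rgb_weights: tuple[float, float, float]
    is_fast: bool = False

    def __post_init__(self) -> None:
        if not self.is_fast and self.lifetime <= 0:
            raise InputError(
                f"emitter {self.name!r}: lifetime must be positive "
                "unless is_fast"
            )
        if self.brightness < 0:
            raise InputError("brightness must be >= 0")
        w = np.asarray(self.rgb_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
            raise InputError("rgb_weights must be 3 nonnegative values")
        object.__setattr__(
            self, "rgb_weights", tuple((w / w.sum()).tolist())
        )

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.rgb_weights, dtype=float)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lifetime": self.lifetime,
            "brightness": self.brightness,
            "rgb_weights": list(self.rgb_weights),
            "is_fast": self.is_fast,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Emitter":
        d = dict(d)
        d["rgb_weights"] = tuple(d["rgb_weights"])
        return cls(**d)


# LED reflection is treated as spectrally white in the visible channels.
WHITE_WEIGHTS = np.full(3, 1.0 / 3.0)


@dataclass
class Scene:
    """Spatial layout of luminophores plus direct LED reflection.

    ``amplitude_maps[i]`` gives the local coverage of ``emitters[i]``;
    ``reflectance_map`` the instantaneous LED reflection (white);
    ``background`` a constant ambient electron rate per channel
    (electrons/second, added as ``background * exposure_time`` counts).
    """

    shape: tuple[int, int]
    emitters: list[Emitter]
    amplitude_maps: list[np.ndarray]
    reflectance_map: np.ndarray | None = None
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = (int(self.shape[0]), int(self.shape[1]))
        if len(self.amplitude_maps) != len(self.emitters):
            raise InputError("one amplitude map per emitter required")
        maps = []
        for m in self.amplitude_maps:
            m = np.asarray(m, dtype=float)
            if m.shape != self.shape:
                raise InputError(
                    f"amplitude map shape {m.shape} != scene {self.shape}"
                )
            if np.any(m < 0):
                raise InputError("amplitude maps must be nonnegative")
            maps.append(m)
        self.amplitude_maps = maps
        if self.reflectance_map is None:
            self.reflectance_map = np.zeros(self.shape)
        else:
            r = np.asarray(self.reflectance_map, dtype=float)
            if r.shape != self.shape:
                raise InputError("reflectance map shape mismatch")
            if np.any(r < 0):
                raise InputError("reflectance must be nonnegative")
            self.reflectance_map = r
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (3,) or np.any(bg < 0):
            raise InputError("background must be 3 nonnegative rates")
        self.background = tuple(bg.tolist())


# ---------------------------------------------------------------------------
# excitation waveform


def excitation_state(t, pulse: ExcitationPulse):
    """Instantaneous excitation ``x(t)``: ``amplitude`` while the LED is
    on, 0 while off.  Vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    if not pulse.enabled:
        out = np.full_like(t, pulse.amplitude)
        return out if out.ndim else float(out)
    s = np.mod(t - pulse.phase, pulse.period)
    out = np.where(s < pulse.t_on, pulse.amplitude, 0.0)
    return out if out.ndim else float(out)


def _on_time_from_origin(t: float, pulse: ExcitationPulse) -> float:
    """Lebesgue measure of {s in [0, t) : LED on}, t relative to phase."""
    p, t_on = pulse.period, pulse.t_on
    k, frac = divmod(t, p)
    return k * t_on + min(frac, t_on)


def excitation_on_time(a: float, b: float, pulse: ExcitationPulse) -> float:
    """Total LED-on time within the interval ``[a, b]``."""
    if b < a:
        raise InputError("interval end before start")
    if not pulse.enabled:
        return b - a
    return _on_time_from_origin(b - pulse.phase, pulse) - _on_time_from_origin(
        a - pulse.phase, pulse
    )


# ---------------------------------------------------------------------------
# periodic steady-state kinetics


def periodic_boundary_levels(
    emitter: Emitter, pulse: ExcitationPulse
) -> tuple[float, float]:
    """Cycle-boundary emission levels ``(E1, E2)`` of the periodic steady
    state: ``E1`` at the rising edge (start of ON), ``E2`` at the falling
    edge (end of ON).

    Uses ``expm1`` so the tau >> period regime keeps full precision.
    """
    if emitter.is_fast:
        raise InputError("fast emitters have no periodic transient")
    tau = emitter.lifetime
    ba = emitter.brightness * pulse.amplitude
    # (1 - e^-x) / (1 - e^-y) computed as expm1(-x)/expm1(-y)
    e2 = ba * tau * math.expm1(-pulse.t_on / tau) / math.expm1(
        -pulse.period / tau
    )
    e1 = e2 * math.exp(-pulse.t_off / tau)
    return e1, e2


def emission_rate(t, emitter: Emitter, pulse: ExcitationPulse):
    """Emission radiance ``E(t)`` in the periodic steady state.

    Fast emitters track the excitation; slow emitters follow the
    closed-form piecewise-exponential cycle solution.  Vectorized over
    ``t``.
    """
    t = np.asarray(t, dtype=float)
    ba = emitter.brightness * pulse.amplitude
    if emitter.is_fast:
        if not pulse.enabled:
            out = np.full_like(t, ba)
        else:
            s = np.mod(t - pulse.phase, pulse.period)
            out = np.where(s < pulse.t_on, ba, 0.0)
        return out if out.ndim else float(out)
    tau = emitter.lifetime
    if not pulse.enabled:
        out = np.full_like(t, ba * tau)
        return out if out.ndim else float(out)
    e1, e2 = periodic_boundary_levels(emitter, pulse)
    s = np.mod(t - pulse.phase, pulse.period)
    on = s < pulse.t_on
    sat = ba * tau
    out_on = sat + (e1 - sat) * np.exp(-np.minimum(s, pulse.t_on) / tau)
    out_off = e2 * np.exp(-np.maximum(s - pulse.t_on, 0.0) / tau)
    out = np.where(on, out_on, out_off)
    return out if out.ndim else float(out)


def average_emission(emitter: Emitter, pulse: ExcitationPulse) -> float:
    """Time-averaged emission over one strobe cycle.

    Fast: ``b * amplitude * duty``.  Slow: ``b * amplitude * tau * duty``
    (the linear kinetics conserve the absorbed-to-emitted budget).
    """
    ba = emitter.brightness * pulse.amplitude
    duty = 1.0 if not pulse.enabled else pulse.duty_cycle
    if emitter.is_fast:
        return ba * duty
    return ba * emitter.lifetime * duty


def emission_integral(
    a: float, b: float, emitter: Emitter, pulse: ExcitationPulse
) -> float:
    """Exact ``∫_a^b E(t) dt`` of the periodic steady-state emission.

    Evaluated analytically segment by segment (ON/OFF) across the strobe
    cycles that intersect ``[a, b]``.
    """
    if b < a:
        raise InputError("interval end before start")
    if b == a:
        return 0.0
    ba = emitter.brightness * pulse.amplitude
    if emitter.is_fast:
        return ba * excitation_on_time(a, b, pulse)
    tau = emitter.lifetime
    if not pulse.enabled:
        return ba * tau * (b - a)
    e1, e2 = periodic_boundary_levels(emitter, pulse)
    sat = ba * tau
    p, t_on = pulse.period, pulse.t_on

    total = 0.0
    k0 = math.floor((a - pulse.phase) / p)
    k1 = math.floor((b - pulse.phase) / p)
    for k in range(k0, k1 + 1):
        cyc = pulse.phase + k * p
        # ON segment [cyc, cyc + t_on)
        u = max(a, cyc) - cyc
        v = min(b, cyc + t_on) - cyc
        if v > u:
            total += sat * (v - u) + (e1 - sat) * tau * (
                math.exp(-u / tau) - math.exp(-v / tau)
            )
        # OFF segment [cyc + t_on, cyc + p)
        u = max(a, cyc + t_on) - (cyc + t_on)
        v = min(b, cyc + p) - (cyc + t_on)
        if v > u:
            total += e2 * tau * (math.exp(-u / tau) - math.exp(-v / tau))
    return total


# ---------------------------------------------------------------------------
# rolling-shutter row timing


def row_exposure_window(row: int, sensor: SensorConfig) -> tuple[float, float]:
    """Exposure window ``(t_start, t_end)`` of a sensor row.

    Row 0 starts at t = 0 (or the last row, if readout is reversed).
    """
    if not 0 <= row < sensor.n_rows:
        raise IndexError(f"row {row} outside [0, {sensor.n_rows})")
    r = sensor.n_rows - 1 - row if sensor.readout_reversed else row
    t0 = r * sensor.line_time
    return t0, t0 + sensor.exposure_time
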