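"""Sensing calibrations: oxygen/pressure quenching and thermal response.

Molecular oxygen quenches long-lived excited states; with ambient
pressure P as the quencher proxy the Stern–Volmer relation

    I0 / I = 1 + K_sv * P        (equivalently  tau0 / tau = 1 + K_sv * P)

links the measured intensity or lifetime to pressure.  Thermal
quenching of a lanthanide complex is modelled with a single-barrier
(Mott–Seitz) form

    tau(T) = tau_ref / (1 + prefactor * exp(-activation_scale / T))

which is strictly decreasing in T for positive parameters.  Both models
are exposed as small estimator-style classes with ``fit``, ``predict``
(condition -> observable) and ``invert`` (observable -> condition with a
delta-method interval), plus thin module-level function wrappers.  A
nonparametric monotone-spline fallback is provided for response shapes
the parametric forms do not capture.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit

from .errors import (
    DataError,
    ExtrapolationError,
    InputError,
    ModelMisfitError,
    ModelMisfitWarning,
)

__all__ = [
    "QuenchCalibration",
    "ThermalCalibration",
    "SternVolmerModel",
    "ThermalQuenchModel",
    "MonotoneSplineModel",
    "fit_stern_volmer",
    "fit_thermal_response",
    "predict_condition",
    "ambient_robustness_check",
]


@dataclass
class Prediction:
    """An inverted condition value with a delta-method interval."""

    value: float
    se: float
    interval: tuple[float, float]


# ---------------------------------------------------------------------------
# Stern-Volmer


@dataclass
class QuenchCalibration:
    """Fitted Stern–Volmer quenching model.

    ``I0`` is the unquenched observable (intensity, or lifetime when
    ``model_form == "lifetime"``); ``tau0`` duplicates it for lifetime
    fits.  ``K_sv`` is per pressure unit (mbar^-1 when pressures are in
    mbar).
    """

    model_form: str
    K_sv: float
    I0: float
    tau0: float | None
    K_sv_se: float
    I0_se: float
    residual_sd: float
    condition_range: tuple[float, float]
    observable_range: tuple[float, float]

    def observable(self, condition):
        return self.I0 / (1.0 + self.K_sv * np.asarray(condition, dtype=float))

    def to_dict(self) -> dict:
        return {
            "model": "stern_volmer",
            "model_form": self.model_form,
            "K_sv": self.K_sv,
            "I0": self.I0,
            "tau0": self.tau0,
            "K_sv_se": self.K_sv_se,
            "I0_se": self.I0_se,
            "residual_sd": self.residual_sd,
            "condition_range": list(self.condition_range),
            "observable_range": list(self.observable_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuenchCalibration":
        d = {k: v for k, v in d.items() if k != "model"}
        d["condition_range"] = tuple(d["condition_range"])
        d["observable_range"] = tuple(d["observable_range"])
        return cls(**d)


class SternVolmerModel:
    """Estimator-style wrapper: ``fit(P, observable)`` then ``invert``."""

    def __init__(self, model_form: str = "intensity"):
        if model_form not in ("intensity", "lifetime"):
            raise InputError("model_form must be 'intensity' or 'lifetime'")
        self.model_form = model_form

    def get_params(self) -> dict:
        return {"model_form": self.model_form}

    def set_params(self, **params) -> "SternVolmerModel":
        for k, v in params.items():
            if k != "model_form":
                raise InputError(f"unknown parameter {k!r}")
            self.model_form = v
        return self

    def fit(self, condition, observable) -> "SternVolmerModel":
        p = np.asarray(condition, dtype=float)
        y = np.asarray(observable, dtype=float)
        if p.shape != y.shape or p.ndim != 1:
            raise InputError("condition and observable must be equal-length 1-D")
        if len(np.unique(p)) < 3:
            raise DataError("need >= 3 distinct condition values")
        if np.any(y <= 0):
            raise DataError("observables must be positive")

        i_lo, i_hi = np.argmin(p), np.argmax(p)
        i0_guess = float(y[i_lo])
        span = float(p[i_hi] - p[i_lo])
        # two-point slope guess; may legitimately be negative (the fit
        # then confirms or refutes quenching)
        k_guess = (y[i_lo] / y[i_hi] - 1.0) / span if span > 0 else 1e-3
        if abs(k_guess) < 1e-6 / span:
            k_guess = 1e-6 / span

        def model(pp, i0, k):
            return i0 / (1.0 + k * pp)

        popt, pcov = curve_fit(
            model, p, y, p0=[i0_guess, k_guess], maxfev=10000
        )
        i0, k = (float(v) for v in popt)
        i0_se, k_se = (float(v) for v in np.sqrt(np.diag(pcov)))
        if k < 0 and k_se > 0 and abs(k) > 2 * k_se:
            warnings.warn(
                f"fitted K_sv = {k:.3g} is negative beyond 2 SE: "
                "quenching model misfit",
                ModelMisfitWarning,
                stacklevel=2,
            )
        resid = y - model(p, i0, k)
        dof = max(len(y) - 2, 1)
        residual_sd = float(math.sqrt(np.sum(resid**2) / dof))
        self.calibration_ = QuenchCalibration(
            model_form=self.model_form,
            K_sv=k,
            I0=i0,
            tau0=i0 if self.model_form == "lifetime" else None,
            K_sv_se=k_se,
            I0_se=i0_se,
            residual_sd=residual_sd,
            condition_range=(float(p.min()), float(p.max())),
            observable_range=(float(model(p.max(), i0, k)), i0),
        )
        return self

    def predict(self, condition):
        return self.calibration_.observable(condition)

    def invert(self, observable: float) -> Prediction:
        return predict_condition(self.calibration_, observable)


def fit_stern_volmer(
    series, model_form: str = "intensity"
) -> QuenchCalibration:
    """Fit I0/I = 1 + K_sv * P (or tau0/tau) by least squares.

    ``series`` is an iterable of ``(condition, observable)`` pairs or a
    pair of arrays.
    """
    cond, obs = _split_series(series)
    return SternVolmerModel(model_form).fit(cond, obs).calibration_


# ---------------------------------------------------------------------------
# thermal response


@dataclass
class ThermalCalibration:
    """Fitted single-barrier thermal-quenching model (temperatures in K)."""

    tau_ref: float
    activation_scale: float
    prefactor: float
    valid_range: tuple[float, float]
    residual_sd: float
    param_se: dict = field(default_factory=dict)

    def observable(self, temperature):
        t = np.asarray(temperature, dtype=float)
        return self.tau_ref / (
            1.0 + self.prefactor * np.exp(-self.activation_scale / t)
        )

    def to_dict(self) -> dict:
        return {
            "model": "thermal_quench",
            "tau_ref": self.tau_ref,
            "activation_scale": self.activation_scale,
            "prefactor": self.prefactor,
            "valid_range": list(self.valid_range),
            "residual_sd": self.residual_sd,
            "param_se": self.param_se,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThermalCalibration":
        d = {k: v for k, v in d.items() if k != "model"}
        d["valid_range"] = tuple(d["valid_range"])
        return cls(**d)


class ThermalQuenchModel:
    """Estimator-style wrapper around the Mott–Seitz thermal fit."""

    def get_params(self) -> dict:
        return {}

    def set_params(self) -> "ThermalQuenchModel":
        return self

    def fit(self, temperature, observable) -> "ThermalQuenchModel":
        t = np.asarray(temperature, dtype=float)
        y = np.asarray(observable, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise InputError("temperature and observable must be equal-length 1-D")
        if len(np.unique(t)) < 4:
            raise DataError("need >= 4 distinct temperatures")
        if np.any(t <= 0):
            raise InputError("temperatures must be in kelvin (> 0)")
        if np.any(y <= 0):
            raise DataError("observables must be positive")

        order = np.argsort(t)
        t, y = t[order], y[order]
        tau_ref0 = float(y[0] * 1.02)
        # linearize: tau_ref/tau - 1 = prefactor * exp(-a/T)
        ratio = np.clip(tau_ref0 / y - 1.0, 1e-9, None)
        coef = np.polyfit(1.0 / t, np.log(ratio), 1)
        a0 = max(-float(coef[0]), 1.0)
        c0 = math.exp(float(coef[1]))

        # fit with log-prefactor and explicit parameter scales: the raw
        # parameters span ~7 orders of magnitude and are strongly
        # correlated, which defeats an unscaled optimizer
        def model_log(tt, tau_ref, a, log_c):
            return tau_ref / (1.0 + np.exp(log_c - a / tt))

        popt, pcov = curve_fit(
            model_log,
            t,
            y,
            p0=[tau_ref0, a0, math.log(max(c0, 1e-12))],
            bounds=([0.0, 0.0, -np.inf], [np.inf] * 3),
            x_scale=[tau_ref0, max(a0, 1.0), 1.0],
            maxfev=20000,
        )
        tau_ref, a, log_c = (float(v) for v in popt)
        c = math.exp(log_c)
        perr = np.sqrt(np.diag(pcov))
        perr[2] = c * perr[2]  # delta method: SE of exp(log_c)

        def model(tt, tau_ref, a, c):
            return tau_ref / (1.0 + c * np.exp(-a / tt))
        grid = np.linspace(t.min(), t.max(), 256)
        curve = model(grid, *popt)
        if not np.all(np.diff(curve) < 0):
            raise ModelMisfitError(
                "fitted thermal response is not strictly decreasing"
            )
        resid = y - model(t, *popt)
        dof = max(len(y) - 3, 1)
        self.calibration_ = ThermalCalibration(
            tau_ref=tau_ref,
            activation_scale=a,
            prefactor=c,
            valid_range=(float(t.min()), float(t.max())),
            residual_sd=float(math.sqrt(np.sum(resid**2) / dof)),
            param_se={
                "tau_ref": float(perr[0]),
                "activation_scale": float(perr[1]),
                "prefactor": float(perr[2]),
            },
        )
        return self

    def predict(self, temperature):
        return self.calibration_.observable(temperature)

    def invert(self, observable: float) -> Prediction:
        return predict_condition(self.calibration_, observable)


def fit_thermal_response(series) -> ThermalCalibration:
    """Fit tau(T) = tau_ref / (1 + prefactor * exp(-activation/T))."""
    t, y = _split_series(series)
    return ThermalQuenchModel().fit(t, y).calibration_


# ---------------------------------------------------------------------------
# monotone-spline fallback


class MonotoneSplineModel:
    """Shape-preserving (PCHIP) monotone interpolation of a response.

    A fallback when neither parametric form fits real data; requires the
    calibration series itself to be strictly monotone in the condition.
    """

    def fit(self, condition, observable) -> "MonotoneSplineModel":
        x = np.asarray(condition, dtype=float)
        y = np.asarray(observable, dtype=float)
        order = np.argsort(x)
        x, y = x[order], y[order]
        if len(np.unique(x)) < 3:
            raise DataError("need >= 3 distinct condition values")
        dy = np.diff(y)
        if not (np.all(dy < 0) or np.all(dy > 0)):
            raise ModelMisfitError("series is not strictly monotone")
        self.spline_ = PchipInterpolator(x, y)
        self.condition_range_ = (float(x.min()), float(x.max()))
        self.observable_range_ = (
            float(min(y[0], y[-1])),
            float(max(y[0], y[-1])),
        )
        return self

    def predict(self, condition):
        return self.spline_(condition)

    def invert(self, observable: float) -> Prediction:
        lo, hi = self.observable_range_
        if not lo <= observable <= hi:
            raise ExtrapolationError(
                f"observable {observable:.4g} outside calibrated "
                f"range [{lo:.4g}, {hi:.4g}]"
            )
        a, b = self.condition_range_
        value = brentq(lambda c: float(self.spline_(c)) - observable, a, b)
        return Prediction(value=float(value), se=0.0, interval=(value, value))


# ---------------------------------------------------------------------------
# inverse prediction


def predict_condition(cal, observable: float) -> Prediction:
    """Invert a fitted monotone calibration model.

    The interval is the delta-method 95% band propagated from the fit's
    residual scale through the local slope of the response.
    """
    if isinstance(cal, QuenchCalibration):
        i0, k = cal.I0, cal.K_sv
        if k <= 0:
            raise ModelMisfitError("cannot invert a non-quenching model (K_sv <= 0)")
        if observable <= 0:
            raise InputError("observable must be positive")
        if observable > i0 * (1.0 + 1e-12):
            raise ExtrapolationError(
                f"observable {observable:.4g} exceeds unquenched level "
                f"I0 = {i0:.4g}"
            )
        obs_lo = cal.observable_range[0]
        if observable < obs_lo - 2 * cal.residual_sd:
            raise ExtrapolationError(
                f"observable {observable:.4g} below calibrated range "
                f"(min {obs_lo:.4g})"
            )
        value = (i0 / observable - 1.0) / k
        slope = i0 / (k * observable**2)  # |dP/dobservable|
        se = slope * cal.residual_sd
    elif isinstance(cal, ThermalCalibration):
        t_lo, t_hi = cal.valid_range
        y_lo = float(cal.observable(t_hi))
        y_hi = float(cal.observable(t_lo))
        if not y_lo <= observable <= y_hi:
            raise ExtrapolationError(
                f"observable {observable:.4g} outside calibrated "
                f"range [{y_lo:.4g}, {y_hi:.4g}]"
            )
        value = brentq(
            lambda t: float(cal.observable(t)) - observable, t_lo, t_hi
        )
        eps = (t_hi - t_lo) * 1e-6
        slope = abs(
            (float(cal.observable(value + eps)) - float(cal.observable(value - eps)))
            / (2 * eps)
        )
        se = cal.residual_sd / slope if slope > 0 else float("inf")
    else:
        raise InputError(f"unknown calibration type {type(cal).__name__}")
    return Prediction(
        value=float(value),
        se=float(se),
        interval=(float(value - 1.96 * se), float(value + 1.96 * se)),
    )


# ---------------------------------------------------------------------------
# ambient-vs-dark robustness


def ambient_robustness_check(estimate_a, estimate_b, *, label_a="ambient", label_b="dark") -> dict:
    """Compare lifetime estimates from two captures of the same scene
    under different ambient backgrounds.

    Lifetime should agree within the joint uncertainty (it is invariant
    to additive background); intensities are reported but not asserted.
    """
    pooled_se = math.sqrt(estimate_a.tau_se**2 + estimate_b.tau_se**2)
    delta = estimate_a.tau - estimate_b.tau
    report = {
        label_a: {"tau_s": estimate_a.tau, "tau_se_s": estimate_a.tau_se},
        label_b: {"tau_s": estimate_b.tau, "tau_se_s": estimate_b.tau_se},
        "delta_tau_s": delta,
        "pooled_se_s": pooled_se,
        "lifetimes_agree": bool(abs(delta) <= 2.0 * pooled_se),
    }
    if estimate_a.mean_intensity is not None and estimate_b.mean_intensity is not None:
        report["intensity_ratio"] = (
            estimate_a.mean_intensity / estimate_b.mean_intensity
            if estimate_b.mean_intensity
            else float("inf")
        )
    return report


# ---------------------------------------------------------------------------
# helpers / serialization


def _split_series(series):
    arr = np.asarray(list(series) if not isinstance(series, np.ndarray) else series, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    if arr.ndim == 2 and arr.shape[0] == 2:
        return arr[0], arr[1]
    raise InputError("series must be (condition, observable) pairs")


def save_calibration(cal, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(cal.to_dict(), indent=2))


def load_calibration(path):
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    if d.get("model") == "stern_volmer":
        return QuenchCalibration.from_dict(d)
    if d.get("model") == "thermal_quench":
        return ThermalCalibration.from_dict(d)
    raise InputError(f"unknown calibration model {d.get('model')!r}")
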