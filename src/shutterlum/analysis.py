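"""Inverse pipeline: from a banded rolling-shutter image to strobe
parameters, emissive lifetimes and species identity.

The pipeline mirrors a manual workflow in image-analysis software:
separate RGB channels, average a column range into a per-row intensity
profile, threshold the profile into on/off bands, convert band geometry
into strobe frequency/duty, map rows to time through the line time, and
fit single-exponential decays to the off-band intervals of the
slow-emitter channel.

Row-to-time convention: row ``r`` is assigned the *center* of its
exposure window, ``t = r * line_time + exposure_time / 2``.  Averaging a
pure exponential over a fixed-length window rescales its amplitude but
leaves it exactly exponential in the window-center time, so the
convention makes sampled decays exactly single-exponential with the true
time constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    AmbiguousMatchError,
    ChannelError,
    DataError,
    FlatProfileError,
    GeometryError,
    InputError,
    InsufficientCyclesError,
    NoLifetimeError,
    QCError,
    UnreliableFitError,
)
from .physics import SensorConfig

__all__ = [
    "RowProfile",
    "BandSegmentation",
    "StrobeEstimate",
    "DecayFit",
    "LifetimeEstimate",
    "SegmentationPolicy",
    "split_channels",
    "extract_row_profile",
    "segment_bands",
    "estimate_strobe",
    "rows_to_time",
    "fit_decay",
    "estimate_lifetime",
    "identify_species",
    "TagRegion",
    "authenticate_tag",
    "analyze_image",
]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


# ---------------------------------------------------------------------------
# containers


@dataclass
class RowProfile:
    """Per-row mean intensity of one channel over a column range."""

    channel: str
    values: np.ndarray
    n_rows: int
    saturated_rows: frozenset[int] = frozenset()
    col_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.n_rows:
            raise InputError("profile length must equal n_rows")


@dataclass
class BandSegmentation:
    """Alternating on/off row intervals plus sub-row edge positions.

    ``intervals`` are half-open ``(start_row, end_row, state)`` covering
    the profile contiguously.  ``rising_edges``/``falling_edges`` are
    fractional row indices of the threshold crossings; under the
    window-center time convention a crossing row maps exactly onto the
    LED edge time.
    """

    intervals: list[tuple[int, int, str]]
    threshold_used: float
    rising_edges: np.ndarray = field(default_factory=lambda: np.empty(0))
    falling_edges: np.ndarray = field(default_factory=lambda: np.empty(0))

    def off_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, st in self.intervals if st == "off"]


@dataclass
class StrobeEstimate:
    """Strobe parameters recovered from band geometry."""

    frequency: float
    duty_cycle: float
    phase_row: float
    period_rows: float
    frequency_se: float
    duty_cycle_se: float
    period_rows_se: float
    n_cycles: int


@dataclass
class DecayFit:
    """Single-exponential fit ``I(t) = A exp(-t/tau) + b`` to one off band."""

    tau: float
    amplitude: float
    baseline: float
    r_squared: float
    tau_se: float
    n_points: int
    t0_row: float | None = None


@dataclass
class LifetimeEstimate:
    """Inverse-variance-weighted aggregate over interior off bands."""

    tau: float
    tau_se: float
    dispersion: float
    n_bands_used: int
    n_bands_total: int
    fits: list[DecayFit]
    rejected: list[str]
    mean_intensity: float | None = None


@dataclass(frozen=True)
class SegmentationPolicy:
    """Thresholding policy for 1-D band segmentation.

    The threshold is the midpoint of robust low/high percentiles — more
    stable than Otsu when the off bands carry decaying slow emission.
    Runs shorter than ``min_run`` rows are merged into their neighbors.
    """

    low_pct: float = 5.0
    high_pct: float = 95.0
    min_run: int = 3
    contrast_floor: float = 0.05
    min_cycles: int = 2
    threshold: float | None = None


# ---------------------------------------------------------------------------
# channel and profile extraction


def split_channels(image: np.ndarray):
    """Lossless split of an RGB image into (R, G, B) grayscale arrays."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ChannelError(
            f"expected (rows, cols, 3) RGB image, got shape {image.shape}"
        )
    return image[:, :, 0], image[:, :, 1], image[:, :, 2]


def extract_row_profile(
    channel_image: np.ndarray,
    col_start: int | None = None,
    col_end: int | None = None,
    *,
    channel: str = "R",
    max_code: float | None = None,
) -> RowProfile:
    """Mean intensity per row over ``[col_start, col_end)``.

    Defaults to the middle 50% of columns.  Rows containing any pixel at
    the maximum code value are flagged as saturated.
    """
    img = np.asarray(channel_image, dtype=float)
    if img.ndim != 2:
        raise InputError("channel image must be 2-D")
    n_rows, n_cols = img.shape
    if col_start is None and col_end is None:
        col_start, col_end = n_cols // 4, n_cols - n_cols // 4
    col_start = 0 if col_start is None else int(col_start)
    col_end = n_cols if col_end is None else int(col_end)
    if not 0 <= col_start < col_end <= n_cols:
        raise InputError(
            f"invalid column range [{col_start}, {col_end}) for {n_cols} cols"
        )
    block = img[:, col_start:col_end]
    if max_code is None:
        dt = np.asarray(channel_image).dtype
        max_code = float(np.iinfo(dt).max) if np.issubdtype(
            dt, np.integer
        ) else float("inf")
    saturated = frozenset(np.nonzero((block >= max_code).any(axis=1))[0].tolist())
    return RowProfile(
        channel=channel,
        values=block.mean(axis=1),
        n_rows=n_rows,
        saturated_rows=saturated,
        col_range=(col_start, col_end),
    )


# ---------------------------------------------------------------------------
# band segmentation


def _run_length_encode(state: np.ndarray):
    edges = np.flatnonzero(np.diff(state.astype(np.int8))) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [len(state)]))
    return [(int(s), int(e), bool(state[s])) for s, e in zip(starts, ends)]


def segment_bands(
    profile: RowProfile, policy: SegmentationPolicy | None = None
) -> BandSegmentation:
    """Threshold a row profile into alternating on/off bands.

    Raises :class:`FlatProfileError` when the robust contrast falls
    below the policy floor — the verdict that the capture was taken
    under steady illumination (or without banding) and carries no
    time-resolved information.
    """
    policy = policy or SegmentationPolicy()
    v = profile.values
    lo, hi = np.percentile(v, [policy.low_pct, policy.high_pct])
    denom = hi + lo
    contrast = (hi - lo) / denom if denom > 0 else 0.0
    if contrast < policy.contrast_floor:
        raise FlatProfileError(
            f"robust contrast {contrast:.4f} below floor "
            f"{policy.contrast_floor}: no banding detected"
        )
    thr = policy.threshold if policy.threshold is not None else (lo + hi) / 2.0

    state = v >= thr
    runs = _run_length_encode(state)
    # merge runs shorter than min_run into their surroundings
    while len(runs) > 1:
        lengths = [e - s for s, e, _ in runs]
        # interior short runs first; endpoints only if still short
        short = [
            i
            for i, ln in enumerate(lengths)
            if ln < policy.min_run and 0 < i < len(runs) - 1
        ]
        if not short:
            break
        i = min(short, key=lambda j: lengths[j])
        s, e, st = runs[i]
        state[s:e] = not st
        runs = _run_length_encode(state)

    intervals = [
        (s, e, "on" if st else "off") for s, e, st in _run_length_encode(state)
    ]
    if len(intervals) < 4:
        raise InsufficientCyclesError(
            f"only {len(intervals)} bands found; need at least 2 full cycles"
        )

    rising, falling = [], []
    for s, e, st in intervals[1:]:  # transition at each interior start
        i = s
        dv = v[i] - v[i - 1]
        frac = (thr - v[i - 1]) / dv if dv != 0 else 0.5
        edge = (i - 1) + float(np.clip(frac, 0.0, 1.0))
        (rising if st == "on" else falling).append(edge)
    rising_arr = np.asarray(rising)
    falling_arr = np.asarray(falling)
    if len(rising_arr) < 2 or len(falling_arr) < 2:
        raise InsufficientCyclesError(
            "fewer than 2 complete on/off cycles in the profile"
        )
    return BandSegmentation(
        intervals=intervals,
        threshold_used=float(thr),
        rising_edges=rising_arr,
        falling_edges=falling_arr,
    )


def estimate_strobe(
    seg: BandSegmentation, sensor: SensorConfig
) -> StrobeEstimate:
    """Strobe frequency, duty cycle and phase from band geometry.

    The period in rows is the mean spacing of successive rising-edge
    threshold crossings (sub-row interpolated); frequency follows from
    the line time.  Duty is the mean on-width over the mean period,
    using complete interior on bands only.
    """
    rising = np.sort(seg.rising_edges)
    if len(rising) < 3:
        raise InsufficientCyclesError(
            f"{len(rising)} rising edges: need >= 3 (2 complete cycles)"
        )
    spacings = np.diff(rising)
    period_rows = float(spacings.mean())
    period_se = (
        float(spacings.std(ddof=1) / math.sqrt(len(spacings)))
        if len(spacings) > 1
        else 0.0
    )
    frequency = 1.0 / (period_rows * sensor.line_time)
    frequency_se = frequency * period_se / period_rows

    falling = np.sort(seg.falling_edges)
    on_widths = []
    for r in rising:
        later = falling[falling > r]
        if len(later) and (later[0] - r) < 1.5 * period_rows:
            on_widths.append(later[0] - r)
    if not on_widths:
        raise InsufficientCyclesError("no complete on bands for duty estimate")
    on_widths = np.asarray(on_widths)
    duty = float(on_widths.mean() / period_rows)
    duty_se = (
        float(on_widths.std(ddof=1) / math.sqrt(len(on_widths)) / period_rows)
        if len(on_widths) > 1
        else 0.0
    )
    return StrobeEstimate(
        frequency=frequency,
        duty_cycle=duty,
        phase_row=float(rising[0] % period_rows),
        period_rows=period_rows,
        frequency_se=frequency_se,
        duty_cycle_se=duty_se,
        period_rows_se=period_se,
        n_cycles=len(spacings),
    )


def rows_to_time(rows, sensor: SensorConfig):
    """Window-center time of (possibly fractional) row indices."""
    rows = np.asarray(rows, dtype=float)
    t = rows * sensor.line_time + sensor.exposure_time / 2.0
    return t if t.ndim else float(t)


# ---------------------------------------------------------------------------
# decay fitting


def _decay_model(t, amplitude, tau, baseline):
    return amplitude * np.exp(-t / tau) + baseline


def default_edge_exclusion(sensor: SensorConfig) -> int:
    """Rows adjacent to a band edge whose exposure window straddles it."""
    return math.ceil(sensor.exposure_time / sensor.line_time)


def fit_decay(
    profile: RowProfile,
    interval: tuple[int, int],
    sensor: SensorConfig,
    *,
    t0_row: float | None = None,
    edge_exclude: int | None = None,
) -> DecayFit:
    """Fit ``I(t) = A exp(-t/tau) + b`` to one off-band interval.

    ``t0_row`` (fractional) anchors t = 0 at the falling-edge crossing
    so amplitudes are comparable across bands; it defaults to the
    interval start.  ``edge_exclude`` rows at both interval ends are
    dropped because their exposure windows straddle the LED edges
    (default ``ceil(exposure_time / line_time)``).
    """
    start, end = int(interval[0]), int(interval[1])
    if not 0 <= start < end <= profile.n_rows:
        raise InputError(f"interval [{start}, {end}) outside profile")
    if edge_exclude is None:
        edge_exclude = default_edge_exclusion(sensor)
    rows = np.arange(start + edge_exclude, end - edge_exclude)
    rows = rows[[r not in profile.saturated_rows for r in rows]]
    if len(rows) < 4:
        raise DataError(
            f"only {len(rows)} usable rows in off band after edge exclusion"
        )
    if t0_row is None:
        t0_row = float(start)
    t = (rows - t0_row) * sensor.line_time
    y = profile.values[rows]

    n_tail = max(3, len(rows) // 4)
    tail = y[-n_tail:]
    b0 = float(np.median(tail))
    noise = float(1.4826 * np.median(np.abs(tail - np.median(tail))))
    noise = max(noise, 1e-12)
    if np.count_nonzero(y > b0 + 2 * noise) < 4:
        raise UnreliableFitError(
            "fewer than 4 rows above baseline + 2*noise: no decaying signal"
        )

    # log-linear initialization on the baseline-subtracted leading rows
    pos = y - b0 > noise
    if np.count_nonzero(pos) >= 2:
        coef = np.polyfit(t[pos], np.log(y[pos] - b0), 1)
        tau0 = -1.0 / coef[0] if coef[0] < 0 else (t[-1] - t[0])
        a0 = math.exp(coef[1])
    else:
        tau0 = (t[-1] - t[0]) / 2
        a0 = max(float(y.max() - b0), noise)
    tau0 = float(np.clip(tau0, sensor.line_time / 10, 1e4 * (t[-1] + 1e-12)))

    try:
        popt, pcov = curve_fit(
            _decay_model,
            t,
            y,
            p0=[a0, tau0, b0],
            bounds=([0.0, sensor.line_time / 100, -np.inf], [np.inf] * 3),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise UnreliableFitError(f"decay fit failed to converge: {exc}") from exc
    amplitude, tau, baseline = (float(p) for p in popt)
    perr = np.sqrt(np.diag(pcov))
    tau_se = float(perr[1])
    if not np.isfinite(tau_se) or tau_se > tau:
        raise UnreliableFitError(
            f"tau = {tau:.3g} s with SE {tau_se:.3g} s: unreliable"
        )
    if amplitude < 3 * noise:
        raise UnreliableFitError(
            f"amplitude {amplitude:.3g} below 3x noise ({noise:.3g}): "
            "no significant decaying signal"
        )
    if tau > 100.0 * (t[-1] - t[0]):
        raise UnreliableFitError(
            f"tau = {tau:.3g} s far exceeds the fitted window: unresolvable"
        )
    resid = y - _decay_model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return DecayFit(
        tau=tau,
        amplitude=amplitude,
        baseline=baseline,
        r_squared=r_squared,
        tau_se=tau_se,
        n_points=len(rows),
        t0_row=t0_row,
    )


def _joint_shared_baseline_refit(
    fits: list[DecayFit],
    band_data: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[list[DecayFit], np.ndarray] | None:
    """Refine per-band fits with one baseline shared across bands.

    The ambient baseline is physically band-independent, and when tau
    approaches the strobe period an off band covers too little decay to
    identify its own baseline — per-band fits then acquire a several-
    percent bias.  A single least-squares over all bands with per-band
    (A_i, tau_i) and a shared baseline removes it.  Returns None if the
    refinement fails, leaving the independent fits in force.
    """
    from scipy.optimize import least_squares

    n = len(fits)
    x0 = np.concatenate(
        (
            [np.mean([f.baseline for f in fits])],
            [f.amplitude for f in fits],
            [f.tau for f in fits],
        )
    )

    def resid(x):
        b, amps, taus = x[0], x[1 : 1 + n], x[1 + n :]
        return np.concatenate(
            [
                y - (amps[i] * np.exp(-t / np.abs(taus[i])) + b)
                for i, (t, y) in enumerate(band_data)
            ]
        )

    try:
        res = least_squares(resid, x0, method="lm", max_nfev=20000)
        jtj = res.jac.T @ res.jac
        dof = max(len(res.fun) - len(res.x), 1)
        cov = np.linalg.pinv(jtj) * (np.sum(res.fun**2) / dof)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not res.success or not np.all(np.isfinite(ses)):
        return None
    b = float(res.x[0])
    refined = []
    for i, f in enumerate(fits):
        tau_i = float(abs(res.x[1 + n + i]))
        se_i = float(ses[1 + n + i])
        t, y = band_data[i]
        pred = res.x[1 + i] * np.exp(-t / tau_i) + b
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
        refined.append(
            DecayFit(
                tau=tau_i,
                amplitude=float(res.x[1 + i]),
                baseline=b,
                r_squared=r2,
                tau_se=se_i,
                n_points=f.n_points,
                t0_row=f.t0_row,
            )
        )
    keep = [i for i, f in enumerate(refined) if f.tau_se < f.tau]
    if not keep:
        return None
    tau_idx = [1 + n + i for i in keep]
    # full covariance of the kept taus: the shared baseline correlates
    # band estimates, so the weighted mean's SE needs the off-diagonals
    tau_cov = cov[np.ix_(tau_idx, tau_idx)]
    return [refined[i] for i in keep], tau_cov


def estimate_lifetime(
    image: np.ndarray,
    sensor: SensorConfig,
    segmentation: BandSegmentation,
    channel: str,
    *,
    col_range: tuple[int, int] | None = None,
    edge_exclude: int | None = None,
    shared_baseline: bool = True,
    qc_max_rel_se: float = 0.5,
) -> LifetimeEstimate:
    """Aggregate lifetime of one channel over all interior off bands.

    Each interior off band is first fitted independently with its t = 0
    at the interpolated falling edge; fits failing quality control are
    rejected.  The survivors are then jointly refined with a single
    shared baseline (disable with ``shared_baseline=False``) and
    combined by inverse-variance weighting.  Raises
    :class:`NoLifetimeError` when every band is rejected (a fast-only
    channel, or a lifetime far beyond the band width).
    """
    if channel not in _CHANNEL_INDEX:
        raise InputError(f"unknown channel {channel!r}")
    chan_img = np.asarray(image)[:, :, _CHANNEL_INDEX[channel]]
    cs, ce = (None, None) if col_range is None else col_range
    profile = extract_row_profile(
        chan_img, cs, ce, channel=channel,
        max_code=float(np.iinfo(np.asarray(image).dtype).max)
        if np.issubdtype(np.asarray(image).dtype, np.integer)
        else None,
    )
    if edge_exclude is None:
        edge_exclude = default_edge_exclusion(sensor)

    # interior off bands: skip the first and last intervals entirely
    interior = segmentation.intervals[1:-1]
    off_bands = [(s, e) for s, e, st in interior if st == "off"]
    fits: list[DecayFit] = []
    band_data: list[tuple[np.ndarray, np.ndarray]] = []
    rejected: list[str] = []
    for s, e in off_bands:
        near = segmentation.falling_edges[
            (segmentation.falling_edges > s - 2)
            & (segmentation.falling_edges < s + 2)
        ]
        t0_row = float(near[0]) if len(near) else float(s)
        try:
            fit = fit_decay(
                profile,
                (s, e),
                sensor,
                t0_row=t0_row,
                edge_exclude=edge_exclude,
            )
        except (QCError, DataError) as exc:
            rejected.append(f"band [{s},{e}): {exc}")
            continue
        if fit.tau_se > qc_max_rel_se * fit.tau:
            rejected.append(
                f"band [{s},{e}): relative tau SE "
                f"{fit.tau_se / fit.tau:.2f} above {qc_max_rel_se}"
            )
            continue
        fits.append(fit)
        rows = np.arange(s + edge_exclude, e - edge_exclude)
        rows = rows[[r not in profile.saturated_rows for r in rows]]
        band_data.append(
            ((rows - t0_row) * sensor.line_time, profile.values[rows])
        )
    if not fits:
        raise NoLifetimeError(
            f"all {len(off_bands)} off bands rejected; "
            + ("; ".join(rejected[:3]) if rejected else "no off bands")
        )
    tau_cov = None
    if shared_baseline and len(fits) >= 2:
        refined = _joint_shared_baseline_refit(fits, band_data)
        if refined is not None:
            fits, tau_cov = refined
    ok = [i for i, f in enumerate(fits) if f.tau_se <= qc_max_rel_se * f.tau]
    if not ok:
        raise NoLifetimeError(
            "no off-band fit met the relative-uncertainty criterion "
            f"(tau SE <= {qc_max_rel_se} tau): lifetime unresolvable"
        )
    if len(ok) < len(fits):
        rejected += [f"refined band {i}: relative tau SE too large" for i in range(len(fits)) if i not in ok]
        fits = [fits[i] for i in ok]
        if tau_cov is not None:
            tau_cov = tau_cov[np.ix_(ok, ok)]
    taus = np.array([f.tau for f in fits])
    ses = np.array([max(f.tau_se, 1e-9 * abs(f.tau)) for f in fits])
    w = 1.0 / ses**2
    tau_w = float(np.sum(w * taus) / np.sum(w))
    if tau_cov is not None:
        se_w = float(math.sqrt(max(w @ tau_cov @ w, 0.0)) / np.sum(w))
    else:
        se_w = float(math.sqrt(1.0 / np.sum(w)))
    dispersion = float(
        math.sqrt(np.sum(w * (taus - tau_w) ** 2) / np.sum(w))
    )
    baseline = float(np.mean([f.baseline for f in fits]))
    mean_intensity = float(profile.values.mean() - baseline)
    return LifetimeEstimate(
        tau=tau_w,
        tau_se=max(se_w, dispersion / math.sqrt(len(fits))),
        dispersion=dispersion,
        n_bands_used=len(fits),
        n_bands_total=len(off_bands),
        fits=fits,
        rejected=rejected,
        mean_intensity=mean_intensity,
    )


# ---------------------------------------------------------------------------
# species identification and tag authentication


def identify_species(
    fit: "DecayFit | LifetimeEstimate | float",
    library: list[tuple[str, float, float]],
) -> str:
    """Match an estimated lifetime against a reference library.

    ``library`` entries are ``(name, tau_ref, relative_tolerance)``.
    Returns the unique matching name, ``"unknown"`` if none match, and
    raises :class:`AmbiguousMatchError` if several do.
    """
    if not library:
        raise InputError("species library is empty")
    tau = fit if isinstance(fit, (int, float)) else fit.tau
    matches = [
        name
        for name, tau_ref, tol in library
        if abs(tau - tau_ref) / tau_ref <= tol
    ]
    if not matches:
        return "unknown"
    if len(matches) > 1:
        raise AmbiguousMatchError(matches)
    return matches[0]


@dataclass(frozen=True)
class TagRegion:
    """One region of an authentication template.

    ``kind`` is ``"slow"`` (must show an off-band lifetime matching
    ``tau_ref`` within ``tolerance``) or ``"fast"`` (must show on-band
    signal and *no* off-band lifetime).
    """

    name: str
    col_start: int
    col_end: int
    channel: str
    kind: str = "slow"
    tau_ref: float | None = None
    tolerance: float = 0.1


def authenticate_tag(
    image: np.ndarray,
    sensor: SensorConfig,
    template: list[TagRegion],
    *,
    policy: SegmentationPolicy | None = None,
) -> dict:
    """Verify a luminescent security tag against a lifetime template.

    Band segmentation is derived once from a fast region (bands are
    horizontal and image-wide), then each region's columns are analyzed
    independently.  Under steady illumination segmentation raises
    :class:`FlatProfileError`: constant light cannot reveal the
    time-resolved pattern, so authentication refuses rather than fails.
    """
    image = np.asarray(image)
    n_rows, n_cols = image.shape[:2]
    for reg in template:
        if not 0 <= reg.col_start < reg.col_end <= n_cols:
            raise GeometryError(
                f"region {reg.name!r} columns [{reg.col_start}, "
                f"{reg.col_end}) outside image width {n_cols}"
            )
        if reg.kind not in ("slow", "fast"):
            raise InputError(f"region kind {reg.kind!r} unknown")

    seg_region = next((r for r in template if r.kind == "fast"), template[0])
    seg_profile = extract_row_profile(
        image[:, :, _CHANNEL_INDEX[seg_region.channel]],
        seg_region.col_start,
        seg_region.col_end,
        channel=seg_region.channel,
    )
    seg = segment_bands(seg_profile, policy)  # FlatProfileError propagates

    regions = []
    for reg in template:
        entry: dict = {"name": reg.name, "kind": reg.kind, "channel": reg.channel}
        try:
            est = estimate_lifetime(
                image,
                sensor,
                seg,
                reg.channel,
                col_range=(reg.col_start, reg.col_end),
            )
        except NoLifetimeError:
            est = None
        if reg.kind == "slow":
            if est is None:
                entry.update(passed=False, reason="no off-band lifetime found")
            else:
                rel = abs(est.tau - reg.tau_ref) / reg.tau_ref
                entry.update(
                    tau=est.tau,
                    tau_se=est.tau_se,
                    relative_error=rel,
                    passed=bool(rel <= reg.tolerance),
                )
                if not entry["passed"]:
                    entry["reason"] = (
                        f"tau {est.tau:.3g} s off reference "
                        f"{reg.tau_ref:.3g} s by {rel:.1%}"
                    )
        else:  # fast: on-band signal, no off-band lifetime
            prof = extract_row_profile(
                image[:, :, _CHANNEL_INDEX[reg.channel]],
                reg.col_start,
                reg.col_end,
                channel=reg.channel,
            )
            on_mean = np.mean(
                [prof.values[s:e].mean() for s, e, st in seg.intervals[1:-1] if st == "on"]
            )
            off_mean = np.mean(
                [prof.values[s:e].mean() for s, e, st in seg.intervals[1:-1] if st == "off"]
            )
            has_contrast = on_mean > off_mean and (on_mean - off_mean) > 0.1 * on_mean
            if est is not None:
                entry.update(
                    passed=False,
                    reason=f"unexpected off-band lifetime {est.tau:.3g} s",
                )
            elif not has_contrast:
                entry.update(passed=False, reason="no on-band signal")
            else:
                entry.update(passed=True, on_mean=float(on_mean), off_mean=float(off_mean))
        regions.append(entry)
    return {"passed": all(r["passed"] for r in regions), "regions": regions}


# ---------------------------------------------------------------------------
# high-level report


def analyze_image(
    image: np.ndarray,
    sensor: SensorConfig,
    *,
    channel: str = "R",
    seg_channel: str | None = None,
    col_range: tuple[int, int] | None = None,
    policy: SegmentationPolicy | None = None,
    species_library: list[tuple[str, float, float]] | None = None,
) -> dict:
    """One-stop analysis: segmentation, strobe estimate, lifetime, ID.

    ``seg_channel`` (default: the channel with the highest robust band
    contrast) drives segmentation; ``channel`` is fitted for a lifetime.
    """
    image = np.asarray(image)
    chans = dict(zip("RGB", split_channels(image)))
    if seg_channel is None:
        contrasts = {}
        for name, arr in chans.items():
            p = extract_row_profile(arr, *(col_range or (None, None)), channel=name)
            lo, hi = np.percentile(p.values, [5, 95])
            contrasts[name] = (hi - lo) / (hi + lo) if hi + lo > 0 else 0.0
        seg_channel = max(contrasts, key=contrasts.get)
    seg_profile = extract_row_profile(
        chans[seg_channel], *(col_range or (None, None)), channel=seg_channel
    )
    seg = segment_bands(seg_profile, policy)
    strobe = estimate_strobe(seg, sensor)
    report: dict = {
        "seg_channel": seg_channel,
        "strobe": {
            "frequency_hz": strobe.frequency,
            "frequency_se_hz": strobe.frequency_se,
            "duty_cycle": strobe.duty_cycle,
            "duty_cycle_se": strobe.duty_cycle_se,
            "period_rows": strobe.period_rows,
            "phase_row": strobe.phase_row,
            "n_cycles": strobe.n_cycles,
        },
        "saturated_rows": sorted(seg_profile.saturated_rows),
    }
    try:
        est = estimate_lifetime(
            image, sensor, seg, channel, col_range=col_range
        )
        report["lifetime"] = {
            "channel": channel,
            "tau_s": est.tau,
            "tau_se_s": est.tau_se,
            "dispersion_s": est.dispersion,
            "n_bands_used": est.n_bands_used,
            "n_bands_total": est.n_bands_total,
            "mean_intensity": est.mean_intensity,
        }
        if species_library:
            try:
                report["species"] = identify_species(est, species_library)
            except AmbiguousMatchError as exc:
                report["species"] = {"ambiguous": exc.candidates}
        report["_lifetime_estimate"] = est
    except NoLifetimeError as exc:
        report["lifetime"] = None
        report["lifetime_error"] = str(exc)
    report["_strobe_estimate"] = strobe
    report["_segmentation"] = seg
    return report
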