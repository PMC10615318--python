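# Methods

## Forward model

### Sensor

The rolling shutter is modelled as a row-time mapping: row *r* exposes
over the window `[r·t_line, r·t_line + t_exp]` (row 0 first; a
`readout_reversed` flag flips the direction for sensors that scan
bottom-up). Geometric distortion, reset time and demosaicing are not
modelled. Defaults mirror the reference experiment where published:
exposure `t_exp = 14 µs` (≈ the printed 1/71429 s). The line time is
never published for the phone sensors used; it is a free configuration
parameter with a fixture default of `t_line = 10 µs`, chosen so a
600.08 Hz strobe yields ≈ 166.6 rows per cycle — about 18 well-resolved
band cycles over a 3000-row frame, matching the visual character of the
reference images.

Pixel response is linear: expected photoelectrons are
`photon_scale × (radiant exposure)` plus a constant ambient background
rate per channel; noise is Poisson shot noise plus Gaussian read noise
(`read_noise_sigma`, default 3 e⁻ RMS in fixtures), clipped at
`full_well` and quantized linearly to 8 or 16 bits. Real phone pipelines
add a tone curve and white balance; an explicit linearization step is
deliberately out of scope here, and analysis of real (non-simulated)
captures should linearize first.

### Excitation and emission

The strobe is an ideal square wave (frequency, duty ∈ (0,1), phase,
amplitude); LED slew is ignored — the reference hardware mitigates it by
running square waves at 50% duty. `enabled=False` degenerates the strobe
to constant illumination, the steady-state control condition.

Each luminophore is a single-exponential emitter. Slow emitters follow
the linear kinetics `dE/dt = b·x(t) − E/τ` in their periodic steady
state, for which the per-cycle solution is closed-form piecewise
exponential with boundary levels

    E2 = b·τ·(1 − e^(−T_on/τ)) / (1 − e^(−P/τ)),   E1 = E2·e^(−T_off/τ)

(evaluated with `expm1` so τ ≫ P keeps precision). Fast emitters
(τ ≪ t_line) emit `b·x(t)` instantaneously. Row signals are the exact
analytic integrals of these forms over each exposure window, split at
the ON/OFF boundaries — no quadrature or time stepping anywhere in the
forward model. Multi-exponential decays are out of scope.

Emitter brightness coefficients in the fixtures are normalized as
`b = 1/τ` for slow emitters so fast and slow species have comparable
radiance scales; LED reflection off the substrate is spectrally flat
(⅓, ⅓, ⅓) and instantaneous.

## Inverse pipeline

Channel separation is lossless array slicing; row profiles are means
over a column range (default: the middle 50% of columns).

**Segmentation.** The on/off threshold is the midpoint of the robust
5th/95th percentiles — stabler than Otsu on 1-D profiles whose "off"
level carries decaying slow emission. Runs shorter than 3 rows are
merged. If the robust contrast `(p95 − p5)/(p95 + p5)` falls below 0.05
the profile is flat: that error *is* the steady-state verdict, not a
failure. Band edges are refined to sub-row precision by linear
interpolation of the threshold crossing; under the window-center time
convention (below) a crossing row maps exactly onto the LED edge time.

**Strobe estimation.** Period in rows = mean spacing of interior rising
edges; frequency = 1/(period_rows·t_line); duty = mean on-width /
period. First and last (possibly partial) bands are always discarded.
Uncertainties come from edge-spacing scatter.

**Row→time.** `t = r·t_line + t_exp/2`. Averaging an exponential over a
fixed window rescales its amplitude by a constant factor but leaves it
exactly exponential in the window-center time, so sampled decays have
the true τ with no window correction.

**Decay fitting.** Each interior off band is fitted with
`I(t) = A·e^(−t/τ) + b` by nonlinear least squares, initialized from a
log-linear regression against a trailing-rows median baseline. The time
origin is the interpolated falling edge, making amplitudes comparable
across bands. `ceil(t_exp/t_line)` rows at both band ends are excluded
(their exposure windows straddle the LED edges). Quality control rejects
fits that fail to converge, have `se(τ) > 0.5·τ`, amplitudes below 3×
the trailing-row noise, or τ beyond 100× the fitted window.

**Shared-baseline joint refinement.** When τ approaches the strobe
period an off band covers only ~half a lifetime and cannot identify its
own baseline; independent per-band fits then acquire several-percent
biases (and inverse-variance weighting amplifies them, because the
fitted `se(τ)` correlates with the τ estimate). Since the ambient
baseline is physically band-independent, the accepted per-band fits
seed a single least-squares over all bands with per-band `(A_i, τ_i)`
and one shared baseline. This removes the bias (measured ≲ 0.5% at
τ/period up to 1 at peak SNR 20, versus ≈ 14% for weighted independent
fits). The shared baseline correlates the band estimates, so the
weighted mean's standard error is propagated through the full τ
covariance of the joint fit, not the diagonal. Band τ estimates are
then combined by inverse-variance weighting; between-band dispersion is
reported alongside.

**Species identification** returns the unique library entry whose
reference lifetime matches within its stated relative tolerance;
several matches raise an ambiguity error rather than guessing.

**Tag authentication** derives one global segmentation from a
fast-emitter region (bands are horizontal and image-wide) and then
checks each template region: slow regions must yield the referenced
lifetime, fast regions must show on-band contrast and *no* off-band
lifetime. Under constant illumination segmentation raises the
flat-profile error, so authentication refuses — constant light cannot
reveal the time-resolved pattern.

## Sensing calibrations

Quenching uses the Stern–Volmer form `I₀/I = 1 + K_SV·P` (equivalently
τ₀/τ), with ambient pressure as the quencher proxy; no conversion to
%O₂ is attempted. Temperature uses a single-barrier (Mott–Seitz) form
`τ(T) = τ_ref/(1 + C·e^(−ΔE/T))`, strictly decreasing for positive
parameters; temperatures are kelvin internally. Both plots in the
reference work carry no stated functional form — these are this
package's model choices, standard for O₂ quenching of delayed emission
and lanthanide thermal quenching respectively, and both are pluggable: a
shape-preserving monotone-spline (PCHIP) fallback is provided for real
responses that fit neither. Whether "decay rate" means τ or 1/τ is
ambiguous in the source; both parameterizations invert identically, and
the lifetime form is used throughout.

The thermal fit works in `(τ_ref, ΔE, log C)` with explicit parameter
scales — the raw parameters span seven orders of magnitude and are
strongly correlated, which defeats an unscaled optimizer (the naive fit
converges to visibly wrong curves even on exact data). Inverse
prediction inverts the fitted monotone model (closed form for
Stern–Volmer, Brent bracketing for thermal) with a delta-method
interval from the fit's residual scale; observables outside the
calibrated response range raise an extrapolation error.

## Synthetic scenarios

Six fixture scenarios mirror the reference experiments: direct LED
reflection; co-deposited fast blue + slow red (Eu, τ = 500 µs) solid;
homogeneous fast-perylene + Eu solution under pulsed or steady light; a
three-ink security tag (fast yellow/green polymer, Eu red 500 µs, Tb
green 1 ms in column regions); a pressure series with a TADF emitter
(τ₀ = 500 µs, K_SV = 0.01 mbar⁻¹, six pressures 0–300 mbar); and a
temperature series (Eu in PMMA, τ_ref = 500 µs, ΔE = 2500 K, C = 2000,
−25 °C to +100 °C, matching the chamber range) under ambient or dark
background. Strobe defaults are the experimental 600.08 Hz at 50% duty.

The signal scale is set by a peak pixel SNR: `photon_scale` is chosen so
the brightest pixel of the analyzed channel satisfies
`S/√(S + σ_read²) = SNR` (default 20; column averaging raises the
profile-level SNR by √n_cols). Series scenarios carry a 5% ambient
pedestal by default: with a pitch-black background, the sensor's
zero-clip of read noise skews short-lifetime decay tails and biases τ
low by ~2% — a real-sensor effect that black-level pedestals exist to
avoid.

What the generator does *not* emulate: phone ISP tone curves and white
balance, Bayer demosaicing, JPEG artifacts, vignetting, LED slew, tilted
or rotated band geometry, and spatially varying backgrounds. Passing
tests therefore demonstrate correctness of the physics and inference
chain, not robustness to those real-capture artifacts.

## Problem sizes and determinism

Tests and studies use 3000-row frames with 16–320 columns (column count
only affects profile noise, by √n_cols) so the full suite runs in
minutes on one CPU: lifetime recovery uses 100 noise realizations per
τ/period ratio with the expected image rendered once and noise redrawn
per seed; quenching recovery uses 50 seeds × 6 pressures. All
randomness flows through seeded `numpy` generators recorded in capture
metadata; identical seeds reproduce captures bit-for-bit.

## Known limitations

- Aggregate lifetime standard errors are mildly underestimated (~70% of
  the true sampling spread at peak SNR 20) because segmentation and
  falling-edge jitter are not propagated; the 2·SE robustness criterion
  still holds at roughly its nominal rate.
- Blind line-time estimation from a single image is impossible without
  a known strobe frequency; the calibration recipe is
  `t_line = 1/(f_strobe · period_rows)`.
- Segmentation assumes bands parallel to rows and at least two complete
  interior cycles; lifetimes beyond ~10× the strobe period are flagged
  unresolvable rather than reported.
- Banding contrast vanishes only when the exposure equals an integer
  number of strobe periods; between integer multiples a reduced ripple
  survives (e.g. contrast ⅓ at 1.5 periods, duty 0.5).
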