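# shutterlum

Rolling-shutter time-gated luminescence: a physics-faithful forward
simulator of a CMOS rolling-shutter camera imaging pulsed-LED-excited
luminescent scenes, and the inverse pipeline that turns the resulting
banded images into strobe parameters, emissive lifetimes, species
identities and sensed quantities (oxygen/pressure, temperature).

## The measurement

A CMOS rolling shutter exposes sensor rows sequentially: row *r* starts
integrating at *r·t_line* and integrates for *t_exp*. When the scene is
excited by a square-wave-strobed UV LED faster than the frame traversal,
the image acquires horizontal bands — each row samples a different phase
of the strobe. That banding is an accidental time axis: the row index
converts to time through the line time, so a single photograph of a
luminescent sample is a time-resolved experiment.

A fast fluorophore (τ ≪ t_line) tracks the LED and appears only in the
"on" bands. A slow emitter — a lanthanide chelate or a TADF compound
with τ in the µs–ms range — obeys

    dE/dt = b·x(t) − E/τ

and keeps emitting into the "off" bands, where its row profile decays as
*A·exp(−t/τ) + b*. Fitting that decay gives the emissive lifetime;
comparing on/off band widths and counts gives the strobe duty cycle and
frequency. Lifetimes feed three applications:

- **species identification** against a library of reference lifetimes,
- **security-tag authentication** (spatial patterns of inks with
  distinct lifetime/channel signatures, invisible to steady-state
  inspection),
- **sensing**: oxygen/pressure via Stern–Volmer quenching
  (*τ₀/τ = 1 + K_SV·P*) and temperature via single-barrier thermal
  quenching (*τ(T) = τ_ref / (1 + C·e^(−ΔE/T))*).

The forward simulator renders expected pixel counts from the exact
closed-form periodic steady state of the emission kinetics (analytic
integrals over each row's exposure window — no time stepping), then
applies Poisson shot noise, Gaussian read noise, clipping and
quantization.

## Worked example

```python
import shutterlum as sl

# co-deposited fast blue + slow red (Eu, tau = 500 us) solid sample,
# strobed at 600.08 Hz with a 50% duty cycle; peak pixel SNR 20
fix = sl.make_fixture(sl.FixtureSpec("two_emitter_solid", {"n_cols": 256}))
cap = fix.capture(seed=7)

report = sl.analyze_image(
    cap.image, fix.sensor, channel="R", seg_channel="B",
    species_library=fix.truth["library"],
)
print(f"strobe frequency : {report['strobe']['frequency_hz']:.2f} Hz")
print(f"duty cycle       : {report['strobe']['duty_cycle']:.3f}")
print(f"lifetime (red)   : {report['lifetime']['tau_s']*1e6:.1f} us")
print(f"species          : {report['species']}")
```

prints

```
strobe frequency : 600.08 Hz
duty cycle       : 0.500
lifetime (red)   : 500.3 us
species          : Eu(tta)3phen
```

The blue (fast) channel's band geometry recovers the strobe settings;
the red (slow) channel's off-band decays, fitted per band and combined,
recover the Eu complex's 500 µs lifetime and identify the species.

The same flows are available from the shell:

```
shutterlum simulate --scenario two_emitter_solid --seed 7 --out cap.tif
shutterlum analyze --image cap.tif --channel R --seg-channel B --out report.json
shutterlum calibrate --mode oxygen --series series.csv --out cal.json
shutterlum predict --cal cal.json --tau 2.5e-4
shutterlum authenticate --image tag.tif --template template.json
shutterlum e2e --scenario pressure_series --seed 1
```

Exit codes: 0 success, 2 quality-control verdict (no banding, no
lifetime, failed authentication), 3 input error.

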