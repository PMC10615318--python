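import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shutterlum as sl

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pulse_600():
    return sl.ExcitationPulse(frequency=600.08, duty_cycle=0.5)


@pytest.fixture(scope="session")
def solid_fixture_nf():
    """Noise-free two-emitter solid scenario (fast blue + slow red Eu,
    tau = 500 us) at a narrow column count for speed."""
    return sl.make_fixture(
        sl.FixtureSpec("two_emitter_solid", {"n_cols": 32, "peak_snr": None})
    )


@pytest.fixture(scope="session")
def solid_capture_nf(solid_fixture_nf):
    return solid_fixture_nf.capture(noise=False)


def ode_emission_oracle(emitter, pulse, t_eval, n_warm_cycles=None):
    """Brute-force periodic steady state by piecewise ODE integration.

    Integrates dE/dt = b*x(t) - E/tau segment by segment with an
    adaptive RK solver (forcing is constant within each ON/OFF segment)
    from E(0) = 0 over enough warm-up cycles for the transient to die,
    then reports E at the requested times of the following cycle.
    ``t_eval`` are times within one period, relative to the cycle start.
    """
    from scipy.integrate import solve_ivp

    tau, b = emitter.lifetime, emitter.brightness * pulse.amplitude
    p, t_on = pulse.period, pulse.t_on
    if n_warm_cycles is None:
        n_warm_cycles = max(int(np.ceil(25 * tau / p)), 5)

    e = 0.0
    for _ in range(n_warm_cycles):
        for forcing, dur in ((b, t_on), (0.0, p - t_on)):
            sol = solve_ivp(
                lambda t, y: forcing - y / tau,
                (0.0, dur),
                [e],
                rtol=1e-12,
                atol=1e-30,
            )
            e = float(sol.y[0, -1])

    out = []
    for t in sorted(t_eval):
        ei = e
        remaining = [(b, min(t, t_on))]
        if t > t_on:
            remaining.append((0.0, t - t_on))
        for forcing, dur in remaining:
            if dur <= 0:
                continue
            sol = solve_ivp(
                lambda tt, y: forcing - y / tau,
                (0.0, dur),
                [ei],
                rtol=1e-12,
                atol=1e-30,
            )
            ei = float(sol.y[0, -1])
        out.append(ei)
    order = np.argsort(np.argsort(t_eval))
    return np.asarray(out)[order]


def quad_emission_integral(a, b_end, emitter, pulse):
    """Quadrature oracle for the emission integral: adaptive quadrature
    of emission_rate split at every ON/OFF boundary inside [a, b]."""
    from scipy.integrate import quad

    edges = [a, b_end]
    p = pulse.period
    k0 = int(np.floor((a - pulse.phase) / p))
    k1 = int(np.ceil((b_end - pulse.phase) / p)) + 1
    for k in range(k0, k1):
        for edge in (pulse.phase + k * p, pulse.phase + k * p + pulse.t_on):
            if a < edge < b_end:
                edges.append(edge)
    edges = sorted(set(edges))
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(
            lambda t: sl.emission_rate(t, emitter, pulse),
            lo,
            hi,
            epsabs=1e-16,
            epsrel=1e-10,
            limit=200,
        )
        total += val
    return total
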