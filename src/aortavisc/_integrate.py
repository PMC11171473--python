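"""Fixed-step RK4 integration of the chirp-driven Kelvin-Voigt/Duffing element.

The strip couples the driven upper end (base displacement u) to the suspended
mass through a spring and a dashpot in parallel; a cubic term on the strip
extension models amplitude-dependent (softening/hardening) elasticity:

    m x'' = k e (1 + beta e^2) + c e',      e = u - x

The excitation is a constant-amplitude sine whose frequency is held at the
sweep's start value for ``settle`` seconds (so the free transient decays)
and then ramped linearly.  Slow sweeps through a narrow resonance need 1e5 -
1e7 steps, so the stepper is compiled with numba; an interpreted fallback
with identical semantics is kept for JIT-less environments.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True)
def _phase_freq(t: float, f_a: float, rate: float, sgn: float, settle: float):
    """Excitation phase (rad) and instantaneous frequency (Hz) at time t."""
    if t <= settle:
        return 2.0 * math.pi * f_a * t, f_a
    tau = t - settle
    f = f_a + sgn * rate * tau
    phase = 2.0 * math.pi * (f_a * settle + f_a * tau + 0.5 * sgn * rate * tau * tau)
    return phase, f


@njit(cache=True)
def _accel(x, v, t, k, c, m, beta, A, f_a, rate, sgn, settle):
    phase, f = _phase_freq(t, f_a, rate, sgn, settle)
    u = A * math.sin(phase)
    du = A * 2.0 * math.pi * f * math.cos(phase)
    e = u - x
    return (k * e * (1.0 + beta * e * e) + c * (du - v)) / m


@njit(cache=True)
def _rk4_sweep(n_out, n_sub, dt, k, c, m, beta, A, f_a, rate, sgn, settle):
    """Integrate from rest, returning the response on the output grid."""
    x = 0.0
    v = 0.0
    out = np.empty(n_out)
    t = 0.0
    h = dt
    for i in range(n_out):
        out[i] = x
        for _ in range(n_sub):
            k1x = v
            k1v = _accel(x, v, t, k, c, m, beta, A, f_a, rate, sgn, settle)
            k2x = v + 0.5 * h * k1v
            k2v = _accel(x + 0.5 * h * k1x, v + 0.5 * h * k1v, t + 0.5 * h,
                         k, c, m, beta, A, f_a, rate, sgn, settle)
            k3x = v + 0.5 * h * k2v
            k3v = _accel(x + 0.5 * h * k2x, v + 0.5 * h * k2v, t + 0.5 * h,
                         k, c, m, beta, A, f_a, rate, sgn, settle)
            k4x = v + h * k3v
            k4v = _accel(x + h * k3x, v + h * k3v, t + h,
                         k, c, m, beta, A, f_a, rate, sgn, settle)
            x += h * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
            v += h * (k1v + 2.0 * k2v + 2.0 * k3v + k4v) / 6.0
            t += h
    return out


def integrate_sweep(
    *,
    k: float,
    c: float,
    m: float,
    beta: float,
    amplitude: float,
    f_anchor: float,
    rate: float,
    sign: float,
    settle: float,
    n_out: int,
    n_sub: int,
    dt: float,
) -> np.ndarray:
    """Run the stepper and validate the result.

    ``f_anchor`` is the frequency held during settle (sweep start for an
    up-sweep, sweep end for a down-sweep); ``sign`` is +1/-1 for up/down.

    Raises
    ------
    RuntimeError
        If the integration produced non-finite samples or an exploding
        response (step too large for the oscillator's frequency).
    """
    x = _rk4_sweep(int(n_out), int(n_sub), float(dt), float(k), float(c),
                   float(m), float(beta), float(amplitude), float(f_anchor),
                   float(rate), float(sign), float(settle))
    if not np.all(np.isfinite(x)):
        raise RuntimeError(
            "integration diverged (non-finite response); reduce the step "
            "size or check the oscillator parameters"
        )
    if np.max(np.abs(x)) > 1e6 * abs(amplitude):
        raise RuntimeError(
            "integration unstable (response exceeds 1e6 x excitation "
            "amplitude); the integrator step is too large for this stiffness"
        )
    return x


def excitation_series(times: np.ndarray, amplitude: float, f_anchor: float,
                      rate: float, sign: float, settle: float) -> np.ndarray:
    """Excitation displacement u(t) evaluated analytically on a time grid."""
    t = np.asarray(times, dtype=float)
    tau = np.clip(t - settle, 0.0, None)
    phase = 2.0 * np.pi * (f_anchor * np.minimum(t, settle)
                           + f_anchor * tau + 0.5 * sign * rate * tau**2)
    return amplitude * np.sin(phase)


def instantaneous_frequency(times: np.ndarray, f_anchor: float, rate: float,
                            sign: float, settle: float) -> np.ndarray:
    """Commanded sweep frequency (Hz) on a time grid (settle section flat)."""
    t = np.asarray(times, dtype=float)
    return f_anchor + sign * rate * np.clip(t - settle, 0.0, None)
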