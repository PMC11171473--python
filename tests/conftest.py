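"""Shared fixtures: cached slow-sweep simulations and a tiny noiseless study.

The slow swept-sine integrations are the expensive part of the suite, so a
session-scoped factory caches (record, curve) pairs by parameter set and
hands them to whichever test asks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from aortavisc import (
    KVParams,
    SweepSpec,
    default_study_config,
    generate_study,
    simulate_strip_response,
)
from aortavisc.resonance_analysis import analyze_study, extract_resonance_curve


def make_oscillator(f0: float, zeta: float, m: float = 0.006,
                    **kv_kwargs) -> KVParams:
    """KVParams realizing a target natural frequency and damping ratio."""
    k = m * (2.0 * math.pi * f0) ** 2
    c = 2.0 * zeta * math.sqrt(k * m)
    return KVParams(k=k, c=c, m_osc=m, **kv_kwargs)


@pytest.fixture(scope="session")
def sweep_sim():
    """Cached factory of slow-sweep simulations.

    ``sweep_sim(f0, zeta, eta, span, direction, ...)`` returns the
    (record, curve) pair; ``eta`` is the sweep-rate / bandwidth^2 ratio
    controlling quasi-steady fidelity and ``span`` the sweep range as
    multiples of f0.
    """
    cache: dict = {}

    def make(f0=10.0, zeta=0.05, eta=0.02, span=(0.18, 3.05), direction="up",
             beta=0.0, noise=0.0, seed=0, n_points=300, amplitude=1e-4,
             fs_factor=12.5):
        key = (f0, zeta, eta, span, direction, beta, noise, seed, n_points,
               amplitude, fs_factor)
        if key not in cache:
            params = make_oscillator(
                f0, zeta, excitation_amplitude=amplitude,
                duffing_beta=beta, noise_sigma=noise, seed=seed)
            bw = 2.0 * zeta * f0
            settle = max(4.0, 6.0 / (zeta * 2.0 * math.pi * f0))
            sw = SweepSpec(f_start=span[0] * f0, f_end=span[1] * f0,
                           sweep_rate=eta * bw**2, direction=direction,
                           sampling_rate=fs_factor * span[1] * f0,
                           settle_time=settle)
            rec = simulate_strip_response(params, sw)
            cache[key] = (rec, extract_resonance_curve(rec, n_points=n_points))
        return cache[key]

    return make


@pytest.fixture(scope="session")
def duffing_curves(sweep_sim):
    """Up/down curve pairs for softening / linear / hardening strips."""
    out = {}
    for beta in (0.0, -1e5, 1e5):
        pair = {}
        for direction in ("up", "down"):
            _, pair[direction] = sweep_sim(
                f0=12.0, zeta=0.03, eta=0.05, span=(0.58, 1.5),
                direction=direction, beta=beta, n_points=250)
        out[beta] = pair
    return out


@pytest.fixture(scope="session")
def tiny_noiseless_study():
    """One sham animal, two stages, all noise sources off."""
    cfg = default_study_config(
        n_sham=1, n_pin=0, stages=["control", "Fe-9"],
        between_animal_sigma=0.0, f0_noise_sigma=0.0,
        signal_noise_sigma=0.0, seed=3)
    study = generate_study(cfg)
    features = analyze_study(study)
    return cfg, study, features
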