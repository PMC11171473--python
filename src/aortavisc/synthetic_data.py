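"""Physics-based generator of swept-sine strip-oscillation experiments.

The generator plays the role of the measurement rig: an aortic-strip
preparation modelled as a Kelvin-Voigt element (spring k and dashpot c in
parallel, optional cubic softening/hardening term) couples a driven upper
end to a suspended oscillating mass (opaque mask + lead ring).  A constant
amplitude sine whose frequency sweeps linearly through the resonance is
applied at the base and the response of the mass is recorded, mimicking the
ADC record of excitation and forced oscillations.

Besides single records, the module generates complete multi-animal studies
with the statistical structure the downstream analysis assumes: per
(group, treatment stage) the natural frequency is linear in the equivalent
blood pressure, the dynamic modulus then follows from the strip geometry,
and group/stage effects are phenomenological shifts of the f0 line.  The
true generating parameters are stored alongside for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import _integrate
from .protocol import GROUPS, STAGE_LABELS, TreatmentStage
from .viscoelasticity import (
    G_STANDARD,
    StripGeometry,
    dynamic_modulus,
    mass_to_equivalent_pressure,
)

__all__ = [
    "KVParams",
    "SweepSpec",
    "OscillationRecord",
    "GeometryConfig",
    "SweepConfig",
    "EffectLine",
    "StudyConfig",
    "SyntheticStudy",
    "kv_transmissibility",
    "simulate_strip_response",
    "static_elongation",
    "design_truth",
    "generate_points",
    "generate_study",
    "calibrate_ring_masses",
    "default_study_config",
    "write_record",
    "DEFAULT_RING_MASSES",
]

#: Ring masses (kg) calibrated once (scripts/calibrate_masses.py) so that the
#: Laplace mass-to-pressure mapping with the default geometry (strip width
#: 3 mm, vessel radius 1.3 mm) yields four equally spaced equivalent blood
#: pressures spanning 77.2-157.4 mmHg.
DEFAULT_RING_MASSES: tuple[float, ...] = (0.0040932, 0.00551062, 0.00692804, 0.00834546)

#: Mass of the opaque mask + hook that oscillates together with the ring (kg).
DEFAULT_MASK_MASS = 0.002


# ---------------------------------------------------------------------------
# Elementary domain types


@dataclasses.dataclass(frozen=True)
class KVParams:
    """Parameters of one strip-mass oscillator.

    Attributes
    ----------
    k : float
        Strip stiffness, N/m.
    c : float
        Viscous damping coefficient, N*s/m.
    m_osc : float
        Oscillating mass (mask + ring), kg.
    duffing_beta : float
        Cubic stiffness coefficient on strip extension, 1/m^2.  Negative
        values bend the resonance backbone left (softening), positive right
        (hardening); 0 is the linear Kelvin-Voigt element.
    excitation_amplitude : float
        Base displacement amplitude A, m.
    noise_sigma : float
        Additive Gaussian noise on the recorded response, expressed as a
        fraction of A.
    seed : int
        Seed of the record's noise realization.
    """

    k: float
    c: float = 0.0
    m_osc: float = 0.005
    duffing_beta: float = 0.0
    excitation_amplitude: float = 1e-4
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"stiffness k must be > 0, got {self.k}")
        if self.c < 0:
            raise ValueError(f"damping c must be >= 0, got {self.c}")
        if self.m_osc <= 0:
            raise ValueError(f"oscillating mass must be > 0, got {self.m_osc}")
        if self.excitation_amplitude <= 0:
            raise ValueError("excitation amplitude must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.zeta < 1.0:
            raise ValueError(
                f"damping ratio zeta={self.zeta:.4g} outside [0, 1); the "
                "model covers the underdamped resonant regime only"
            )

    @property
    def zeta(self) -> float:
        """Damping ratio c / (2 sqrt(k m))."""
        return self.c / (2.0 * math.sqrt(self.k * self.m_osc))

    @property
    def natural_frequency(self) -> float:
        """Undamped natural frequency sqrt(k/m) / (2 pi), Hz."""
        return math.sqrt(self.k / self.m_osc) / (2.0 * math.pi)


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """Linear frequency sweep of the excitation."""

    f_start: float
    f_end: float
    sweep_rate: float
    direction: Literal["up", "down"] = "up"
    sampling_rate: float = 300.0
    settle_time: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.f_start < self.f_end:
            raise ValueError(
                f"need 0 < f_start < f_end, got ({self.f_start}, {self.f_end})"
            )
        if self.sweep_rate <= 0:
            raise ValueError("sweep_rate must be > 0")
        if self.sampling_rate <= 10.0 * self.f_end:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz must exceed 10 x "
                f"f_end = {10 * self.f_end} Hz"
            )
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.settle_time < 0:
            raise ValueError("settle_time must be >= 0")

    @property
    def duration(self) -> float:
        """Total record length (settle + sweep), s."""
        return self.settle_time + (self.f_end - self.f_start) / self.sweep_rate

    @property
    def anchor(self) -> float:
        """Frequency held during the settle section."""
        return self.f_start if self.direction == "up" else self.f_end

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "up" else -1.0

    def frequency_at(self, t: np.ndarray | float) -> np.ndarray:
        """Commanded instantaneous frequency at record time t (s)."""
        return _integrate.instantaneous_frequency(
            np.asarray(t, dtype=float), self.anchor, self.sweep_rate,
            self.sign, self.settle_time)

    def time_at_frequency(self, f: np.ndarray | float) -> np.ndarray:
        """Record time at which the sweep passes frequency f (Hz)."""
        f = np.asarray(f, dtype=float)
        return self.settle_time + (f - self.anchor) * self.sign / self.sweep_rate


@dataclasses.dataclass
class OscillationRecord:
    """One swept-sine measurement: simultaneous excitation and response."""

    time: np.ndarray
    excitation: np.ndarray
    response: np.ndarray
    sweep: SweepSpec
    metadata: dict = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.time)
        if len(self.excitation) != n or len(self.response) != n:
            raise ValueError("time, excitation and response must share length")
        if n < 2:
            raise ValueError("record too short")
        steps = np.diff(self.time)
        dt = 1.0 / self.sweep.sampling_rate
        if np.any(steps <= 0) or not np.allclose(steps, dt, rtol=1e-6):
            raise ValueError("time grid must be uniform with step 1/sampling_rate")
        for name in ("excitation", "response"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite samples in {name}")


# ---------------------------------------------------------------------------
# Single-oscillator physics


def kv_transmissibility(r, zeta):
    """Steady-state amplitude ratio |x|/|u| of the base-excited element.

    For base excitation through both the spring and the dashpot the linear
    Kelvin-Voigt element transmits

        T(r, zeta) = sqrt( (1 + (2 zeta r)^2) /
                           ((1 - r^2)^2 + (2 zeta r)^2) )

    with r = f_excitation / f_natural.

    Parameters are scalars or arrays; broadcasting applies.
    """
    r = np.asarray(r, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if np.any(r < 0):
        raise ValueError("frequency ratio r must be >= 0")
    if np.any(zeta < 0) or np.any(zeta >= 1):
        raise ValueError("damping ratio zeta must lie in [0, 1)")
    num = 1.0 + (2.0 * zeta * r) ** 2
    den = (1.0 - r**2) ** 2 + (2.0 * zeta * r) ** 2
    out = np.sqrt(num / den)
    return float(out) if out.ndim == 0 else out


def quasi_steady_ratio(params: KVParams, sweep: SweepSpec) -> float:
    """Sweep-rate / bandwidth^2 ratio; quasi-steady tracking needs << 1.

    The resonance takes ~1/(pi df_3dB) seconds to respond; a linear sweep
    crosses its half-power band (df_3dB = 2 zeta f0) in df_3dB/rate seconds.
    The distortion of the measured curve is controlled by
    rate / df_3dB^2, which should stay below ~0.1-0.2 for percent-level
    fidelity.
    """
    bw = 2.0 * params.zeta * params.natural_frequency
    if bw == 0:
        return math.inf
    return sweep.sweep_rate / bw**2


def simulate_strip_response(params: KVParams, sweep: SweepSpec) -> OscillationRecord:
    """Numerically integrate one swept-sine experiment.

    The equation of motion is

        m x'' = k (u - x) (1 + beta (u - x)^2) + c (u' - x')

    with u(t) a constant-amplitude sine held at the sweep anchor frequency
    for ``settle_time`` and then chirped linearly.  Additive Gaussian noise
    of sd ``noise_sigma * A`` is applied to the response only, reproducibly
    from ``params.seed``.

    For beta = 0 and a slow sweep (``quasi_steady_ratio`` << 1) the measured
    amplitude ratio matches :func:`kv_transmissibility` to within ~2%.
    """
    n_out = int(round(sweep.duration * sweep.sampling_rate)) + 1
    f_top = max(sweep.f_end, params.natural_frequency)
    dt_target = 1.0 / (40.0 * f_top)
    n_sub = max(1, math.ceil(1.0 / (sweep.sampling_rate * dt_target)))
    dt = 1.0 / (sweep.sampling_rate * n_sub)

    x = _integrate.integrate_sweep(
        k=params.k, c=params.c, m=params.m_osc, beta=params.duffing_beta,
        amplitude=params.excitation_amplitude, f_anchor=sweep.anchor,
        rate=sweep.sweep_rate, sign=sweep.sign, settle=sweep.settle_time,
        n_out=n_out, n_sub=n_sub, dt=dt)

    time = np.arange(n_out) / sweep.sampling_rate
    u = _integrate.excitation_series(
        time, params.excitation_amplitude, sweep.anchor, sweep.sweep_rate,
        sweep.sign, sweep.settle_time)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        x = x + rng.normal(
            0.0, params.noise_sigma * params.excitation_amplitude, n_out)

    rec = OscillationRecord(time=time, excitation=u, response=x, sweep=sweep,
                            metadata={"seed": params.seed})
    rec.validate()
    return rec


def static_elongation(m_ring: float, params: KVParams) -> float:
    """Static stretch of the strip under a suspended ring mass.

    Solves k dL (1 + beta dL^2) = m g for the elongation; with beta = 0 this
    is Hooke's law dL = m g / k.  For a softening strip (beta < 0) the load
    must stay below the fold point of the cubic, otherwise no static
    equilibrium exists and a ValueError is raised.
    """
    if m_ring < 0:
        raise ValueError("ring mass must be >= 0")
    if m_ring == 0:
        return 0.0
    w = m_ring * G_STANDARD
    beta = params.duffing_beta
    x_lin = w / params.k
    if beta == 0 or abs(beta) * x_lin**2 < 1e-14:
        return x_lin

    from scipy.optimize import brentq

    def force_balance(x: float) -> float:
        return params.k * x * (1.0 + beta * x * x) - w

    if beta > 0:  # hardening: monotone restoring force, root below x_lin
        return float(brentq(force_balance, 0.0, x_lin * (1.0 + 1e-12)))
    # softening: the restoring force folds over at x* = 1/sqrt(3|beta|);
    # a static equilibrium (stable branch) exists only below the fold
    x_fold = 1.0 / math.sqrt(3.0 * abs(beta))
    if force_balance(x_fold) < 0.0:
        raise ValueError(
            f"no static equilibrium for m_ring={m_ring} kg: load exceeds "
            "the softening fold of the cubic stiffness"
        )
    return float(brentq(force_balance, 0.0, x_fold))


# ---------------------------------------------------------------------------
# Study-level configuration


class GeometryConfig(BaseModel):
    """Strip geometry defaults; see viscoelasticity.StripGeometry."""

    L0: float = 0.02
    b: float = 0.003
    h: float = 1.0e-4
    r_v: float = 0.0013

    def to_geometry(self) -> StripGeometry:
        return StripGeometry(L0=self.L0, b=self.b, h=self.h, r_v=self.r_v)


class SweepConfig(BaseModel):
    f_start: float = 5.0
    f_end: float = 25.0
    sweep_rate: float = 0.1
    sampling_rate: float = 300.0
    settle_time: float = 4.0
    directions: tuple[Literal["up", "down"], ...] = ("up", "down")

    def to_spec(self, direction: str) -> SweepSpec:
        return SweepSpec(f_start=self.f_start, f_end=self.f_end,
                         sweep_rate=self.sweep_rate, direction=direction,
                         sampling_rate=self.sampling_rate,
                         settle_time=self.settle_time)


class EffectLine(BaseModel):
    """f0(p) = intercept + slope * p for one group x stage cell."""

    f0_intercept: float  # Hz
    f0_slope: float  # Hz/mmHg


#: Multiplicative stage factors on the group's base f0 line.  They encode the
#: study's qualitative treatment effects: fentanyl relaxes the sham strip at
#: every concentration; the melatonin-deficient (pin) strip resists the
#: lowest dose (Fe-9, with or without naloxone) but matches sham at higher
#: doses; wash-out restores sham almost fully while pin stays depressed;
#: naloxone alone lowers stiffness in both groups.
DEFAULT_STAGE_FACTORS: dict[str, dict[str, float]] = {
    "sham": {
        "control": 1.00, "Fe-9": 0.90, "Fe-8": 0.89, "Fe-7": 0.88,
        "Fe-6": 0.86, "washout30": 0.99, "nal10": 0.90, "Fe-9+Nal": 0.88,
        "Fe-8+Nal": 0.97, "Fe-7+Nal": 0.88, "Fe-6+Nal": 0.87,
    },
    "pin": {
        "control": 1.00, "Fe-9": 1.00, "Fe-8": 0.89, "Fe-7": 0.88,
        "Fe-6": 0.86, "washout30": 0.93, "nal10": 0.92, "Fe-9+Nal": 0.99,
        "Fe-8+Nal": 0.96, "Fe-7+Nal": 0.90, "Fe-6+Nal": 0.88,
    },
}

#: Base f0 line shared by both groups at control (no significant group
#: difference in untreated preparations).
DEFAULT_BASE_LINE = EffectLine(f0_intercept=8.0, f0_slope=0.055)


def _default_effects() -> dict[str, dict[str, EffectLine]]:
    out: dict[str, dict[str, EffectLine]] = {}
    for group, factors in DEFAULT_STAGE_FACTORS.items():
        out[group] = {
            stage: EffectLine(
                f0_intercept=DEFAULT_BASE_LINE.f0_intercept * fac,
                f0_slope=DEFAULT_BASE_LINE.f0_slope * fac,
            )
            for stage, fac in factors.items()
        }
    return out


class StudyConfig(BaseModel):
    """Full description of a synthetic multi-animal study."""

    n_sham: int = Field(3, ge=0)
    n_pin: int = Field(4, ge=0)
    stages: list[str] = Field(default_factory=lambda: list(STAGE_LABELS))
    ring_masses: list[float] = Field(
        default_factory=lambda: list(DEFAULT_RING_MASSES))
    mask_mass: float = Field(DEFAULT_MASK_MASS, gt=0)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    effects: dict[str, dict[str, EffectLine]] = Field(
        default_factory=_default_effects)
    damping_zeta: float = Field(0.05, gt=0, lt=1)
    duffing_beta: float = 0.0
    excitation_amplitude: float = Field(1e-4, gt=0)
    signal_noise_sigma: float = Field(0.01, ge=0)
    between_animal_sigma: float = Field(0.05, ge=0)  # Hz, on the intercept
    f0_noise_sigma: float = Field(0.15, ge=0)  # Hz, per measurement
    sweep: SweepConfig = Field(default_factory=SweepConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        for label in self.stages:
            TreatmentStage.from_label(label)  # raises naming the label
        order = [STAGE_LABELS.index(s) for s in self.stages]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(
                "stages must be unique and follow the protocol order "
                f"{list(STAGE_LABELS)}; got {self.stages}")
        if len(self.ring_masses) != 4:
            raise ValueError("exactly 4 ring masses are required")
        if not all(b > a for a, b in zip(self.ring_masses, self.ring_masses[1:])):
            raise ValueError("ring masses must be strictly increasing")
        geometry = self.geometry.to_geometry()
        pressures = [mass_to_equivalent_pressure(m, geometry)
                     for m in self.ring_masses]
        for group, n in (("sham", self.n_sham), ("pin", self.n_pin)):
            if n == 0:
                continue
            if group not in self.effects:
                raise ValueError(f"no effect model for group {group!r}")
            for stage in self.stages:
                if stage not in self.effects[group]:
                    raise ValueError(
                        f"no effect model for cell ({group!r}, {stage!r})")
                line = self.effects[group][stage]
                for p in pressures:
                    f0 = line.f0_intercept + line.f0_slope * p
                    if f0 <= 0:
                        raise ValueError(
                            f"effect model for cell ({group!r}, {stage!r}) "
                            f"implies non-physical k <= 0 (f0 = {f0:.3g} Hz "
                            f"at p = {p:.1f} mmHg)")
        return self

    @property
    def pressures(self) -> list[float]:
        geometry = self.geometry.to_geometry()
        return [mass_to_equivalent_pressure(m, geometry)
                for m in self.ring_masses]

    def subjects(self) -> list[tuple[str, str]]:
        """(subject id, group) pairs, sham first."""
        return ([(f"sham{i + 1:02d}", "sham") for i in range(self.n_sham)]
                + [(f"pin{i + 1:02d}", "pin") for i in range(self.n_pin)])


def default_study_config(**overrides) -> StudyConfig:
    """The default study: sham n=3, pin n=4, 11 stages, 4 loads."""
    return StudyConfig(**overrides)


def calibrate_ring_masses(geometry: StripGeometry, p_min: float = 77.2,
                          p_max: float = 157.4, n: int = 4) -> list[float]:
    """Invert the Laplace mass-to-pressure mapping for n equally spaced
    target pressures (mmHg) -> ring masses (kg)."""
    if not 0 < p_min < p_max or n < 2:
        raise ValueError("need 0 < p_min < p_max and n >= 2")
    from .viscoelasticity import MMHG_PA  # local to keep namespace tidy
    targets = np.linspace(p_min, p_max, n)
    return [float(p * MMHG_PA * geometry.b * geometry.r_v / G_STANDARD)
            for p in targets]


# ---------------------------------------------------------------------------
# Study generation


def design_truth(config: StudyConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-measurement ground truth of a study.

    One row per subject x stage x load step, holding the realized oscillator
    (k, c, m_osc), the static elongation and equivalent pressure, and the
    true f0 / E' the downstream pipeline should recover.  Between-animal
    scatter perturbs each animal's intercept; per-measurement scatter
    (``f0_noise_sigma``) perturbs the realized stiffness, so the stored
    truth *is* what the rig would see.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geometry = config.geometry.to_geometry()
    pressures = config.pressures
    rows = []
    for subject, group in config.subjects():
        animal_offset = (rng.normal(0.0, config.between_animal_sigma)
                         if config.between_animal_sigma > 0 else 0.0)
        for stage in config.stages:
            line = config.effects[group][stage]
            for idx, (m_ring, p) in enumerate(zip(config.ring_masses,
                                                  pressures), start=1):
                f0 = line.f0_intercept + animal_offset + line.f0_slope * p
                if config.f0_noise_sigma > 0:
                    f0 += rng.normal(0.0, config.f0_noise_sigma)
                if f0 <= 0:
                    raise ValueError(
                        f"drawn f0 <= 0 for ({subject}, {stage}, load {idx}); "
                        "noise level incompatible with the effect model")
                m_osc = config.mask_mass + m_ring
                k = m_osc * (2.0 * math.pi * f0) ** 2
                c = 2.0 * config.damping_zeta * math.sqrt(k * m_osc)
                params = KVParams(k=k, c=c, m_osc=m_osc,
                                  duffing_beta=config.duffing_beta,
                                  excitation_amplitude=config.excitation_amplitude)
                dl = static_elongation(m_ring, params)
                eprime = dynamic_modulus(f0, m_osc, geometry.L0, dl, geometry.S)
                rows.append({
                    "subject": subject, "group": group, "stage": stage,
                    "mass_index": idx, "m_ring_kg": m_ring, "m_osc_kg": m_osc,
                    "p_mmHg": p, "k_N_per_m": k, "c_Ns_per_m": c,
                    "dL_m": dl, "f0_Hz": f0, "Eprime_Pa": eprime,
                })
    return pd.DataFrame(rows)


def generate_points(config: StudyConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Tidy observation table of a study, skipping signal synthesis.

    Statistically equivalent to running the full signal pipeline on a
    generated study up to the (small) resonance-extraction error: the
    realized per-measurement f0 already carries the configured noise.
    """
    truth = design_truth(config, rng=rng)
    points = truth[["subject", "group", "stage", "mass_index",
                    "p_mmHg", "f0_Hz", "Eprime_Pa"]].copy()
    points["Eprime_MPa"] = points["Eprime_Pa"] / 1e6
    points["qc_flags"] = ""
    return points


@dataclasses.dataclass
class SyntheticStudy:
    """A generated study: manifest, signal records and ground truth."""

    manifest: dict
    records: list[OscillationRecord]
    truth: pd.DataFrame


def _record_filename(subject: str, stage: str, mass_index: int,
                     direction: str) -> str:
    slug = TreatmentStage.from_label(stage).slug
    return f"{subject}/{slug}_m{mass_index}_{direction}.csv"


def generate_study(config: StudyConfig,
                   out_dir: str | Path | None = None) -> SyntheticStudy:
    """Generate the full signal-level study.

    For every subject x stage x load step one swept-sine record per
    configured sweep direction is integrated from the drawn ground truth.
    With ``out_dir`` given, records are written as 3-column delimited text
    plus a JSON manifest and ground-truth file (see :func:`write_study`).
    """
    rng = np.random.default_rng(config.seed)
    truth = design_truth(config, rng=rng)
    records: list[OscillationRecord] = []
    measurements = []
    for row in truth.itertuples(index=False):
        files = {}
        for direction in config.sweep.directions:
            params = KVParams(
                k=row.k_N_per_m, c=row.c_Ns_per_m, m_osc=row.m_osc_kg,
                duffing_beta=config.duffing_beta,
                excitation_amplitude=config.excitation_amplitude,
                noise_sigma=config.signal_noise_sigma,
                seed=int(rng.integers(2**31)))
            rec = simulate_strip_response(params, config.sweep.to_spec(direction))
            rec.metadata.update({
                "subject": row.subject, "group": row.group,
                "stage": row.stage, "mass_index": int(row.mass_index),
                "direction": direction,
            })
            records.append(rec)
            files[direction] = _record_filename(
                row.subject, row.stage, int(row.mass_index), direction)
        measurements.append({
            "subject": row.subject, "group": row.group, "stage": row.stage,
            "mass_index": int(row.mass_index), "m_ring_kg": row.m_ring_kg,
            "m_osc_kg": row.m_osc_kg, "dL_m": row.dL_m,
            "p_mmHg": row.p_mmHg, "files": files,
        })
    manifest = {
        "format": "aortavisc-study/1",
        "seed": config.seed,
        "geometry": config.geometry.model_dump(),
        "ring_masses_kg": list(config.ring_masses),
        "mask_mass_kg": config.mask_mass,
        "stages": list(config.stages),
        "subjects": [{"subject": s, "group": g} for s, g in config.subjects()],
        "sweep": config.sweep.model_dump(),
        "measurements": measurements,
    }
    study = SyntheticStudy(manifest=manifest, records=records, truth=truth)
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_record(record: OscillationRecord, path: str | Path) -> None:
    """Write one record as 3-column delimited text (time_s, excitation, response)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([record.time, record.excitation, record.response])
    np.savetxt(path, data, fmt="%.9g", delimiter="\t",
               header="time_s\texcitation\tresponse", comments="")


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write manifest JSON, ground-truth JSON and all signal files."""
    out = Path(out_dir)
    signals = out / "signals"
    signals.mkdir(parents=True, exist_ok=True)
    by_key: dict[tuple, OscillationRecord] = {
        (r.metadata["subject"], r.metadata["stage"],
         r.metadata["mass_index"], r.metadata["direction"]): r
        for r in study.records}
    for meas in study.manifest["measurements"]:
        for direction, rel in meas["files"].items():
            rec = by_key[(meas["subject"], meas["stage"],
                          meas["mass_index"], direction)]
            write_record(rec, signals / rel)
    with open(out / "manifest.json", "w") as fh:
        json.dump(study.manifest, fh, indent=1)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"rows": study.truth.to_dict(orient="records")}, fh, indent=1)
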