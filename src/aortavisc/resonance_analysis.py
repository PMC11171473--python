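"""Resonance curves and their scalar features from swept-sine records.

A recorded measurement holds the commanded excitation and the strip's
forced-oscillation response.  Because the rig commands the sweep, the
instantaneous frequency is taken from the known sweep law rather than
estimated from the signal.  The amplitude-versus-frequency (resonance)
curve is built from short-window RMS envelopes of both channels — the
window spans a fixed number of cycles of the local frequency, which is
robust for swept sines and free of analytic-signal edge artefacts — and
the features the method reports are read off the curve: natural frequency
f0 (quadratically refined peak), 3 dB (half-power) bandwidth, octave
length, the half-power damping-ratio estimate, and a signed
softening/hardening index from the up/down sweep pair.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_data import OscillationRecord, SweepSpec, SyntheticStudy

__all__ = [
    "ResonanceAnalysisError",
    "ResonanceCurve",
    "ResonanceFeatures",
    "extract_resonance_curve",
    "smooth_curve",
    "merge_sweeps",
    "natural_frequency",
    "bandwidth_3db",
    "octave_length",
    "damping_ratio",
    "skew_index",
    "analyze_measurement",
    "analyze_study",
    "read_record",
]

logger = logging.getLogger(__name__)

#: Sweep-rate / bandwidth^2 threshold above which the quasi-steady
#: assumption is considered violated and the measurement is flagged.
QUASI_STEADY_LIMIT = 0.25


class ResonanceAnalysisError(ValueError):
    """Raised when a curve or record cannot support the requested feature."""


@dataclasses.dataclass
class ResonanceCurve:
    """Amplitude-ratio curve on a strictly increasing frequency grid."""

    frequency: np.ndarray
    amplitude: np.ndarray
    direction: Literal["up", "down", "merged"] = "up"
    qc_flags: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.frequency.size < 20:
            raise ResonanceAnalysisError(
                f"resonance curve needs >= 20 points, got {self.frequency.size}")
        if self.frequency.size != self.amplitude.size:
            raise ResonanceAnalysisError("frequency/amplitude length mismatch")
        if np.any(np.diff(self.frequency) <= 0):
            raise ResonanceAnalysisError("frequency grid must be strictly increasing")
        if np.any(~np.isfinite(self.amplitude)) or np.any(self.amplitude < 0):
            raise ResonanceAnalysisError("amplitudes must be finite and >= 0")


@dataclasses.dataclass
class ResonanceFeatures:
    """Scalar features of one measurement's resonance curve."""

    f0: float
    peak_amplitude: float
    f_lo: float
    f_hi: float
    bandwidth_3db: float
    octave_length: float
    damping_ratio: float
    skew_index: float = math.nan
    qc_flags: list[str] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Curve construction


def _rms(x: np.ndarray) -> float:
    return math.sqrt(float(np.mean(np.square(x))))


def extract_resonance_curve(record: OscillationRecord, *, n_points: int = 200,
                            window_cycles: float = 3.0) -> ResonanceCurve:
    """Estimate the resonance curve of one swept-sine record.

    The amplitude at each output frequency is the RMS envelope of the
    response divided by the RMS envelope of the excitation over a window of
    ``window_cycles`` cycles of the local commanded frequency, centred at
    the instant the sweep passes that frequency.  The settle section of the
    record is discarded.
    """
    record.validate()
    sweep = record.sweep
    t_end = record.time[-1]
    sweep_seconds = t_end - sweep.settle_time
    if sweep_seconds <= window_cycles / sweep.f_start:
        raise ResonanceAnalysisError(
            "sweep interval empty: record ends before the sweep section "
            "could be analysed")
    if n_points < 20:
        raise ValueError("n_points must be >= 20")

    # frequencies actually reachable inside this record, window included
    f_first, f_last = sweep.frequency_at(sweep.settle_time), sweep.frequency_at(t_end)
    f_min, f_max = min(f_first, f_last), max(f_first, f_last)
    centers = np.linspace(f_min, f_max, n_points + 2)[1:-1]

    t = record.time
    freqs, amps = [], []
    for f_c in centers:
        half = 0.5 * window_cycles / f_c
        t_c = float(sweep.time_at_frequency(f_c))
        lo, hi = t_c - half, t_c + half
        if lo < sweep.settle_time or hi > t_end:
            continue
        i0 = int(np.searchsorted(t, lo))
        i1 = int(np.searchsorted(t, hi))
        if i1 - i0 < 8:
            continue
        exc = _rms(record.excitation[i0:i1])
        if exc == 0.0:
            continue
        freqs.append(f_c)
        amps.append(_rms(record.response[i0:i1]) / exc)
    if len(freqs) < 20:
        raise ResonanceAnalysisError(
            "sweep interval empty: fewer than 20 usable envelope windows")
    return ResonanceCurve(np.asarray(freqs), np.asarray(amps),
                          direction=sweep.direction)


def smooth_curve(curve: ResonanceCurve, *, median: int = 5,
                 mean: int = 5) -> ResonanceCurve:
    """Moving median then moving mean (both odd window sizes, edge-held)."""
    amp = curve.amplitude
    if median > 1:
        amp = ndimage.median_filter(amp, size=median, mode="nearest")
    if mean > 1:
        amp = ndimage.uniform_filter1d(amp, size=mean, mode="nearest")
    return ResonanceCurve(curve.frequency.copy(), amp,
                          direction=curve.direction,
                          qc_flags=list(curve.qc_flags))


def merge_sweeps(up: ResonanceCurve, down: ResonanceCurve, *,
                 smooth: bool = True, median: int = 5,
                 mean: int = 5) -> ResonanceCurve:
    """Merge an up/down sweep pair into one theoretical resonance curve.

    The merged curve is the pointwise upper envelope of the two curves on
    the intersection of their frequency ranges (each single sweep
    under-reads the true steady-state peak on its lagging side, so the
    envelope is the better estimate of the stationary curve), followed by
    the module's standard smoothing.
    """
    lo = max(up.frequency[0], down.frequency[0])
    hi = min(up.frequency[-1], down.frequency[-1])
    if hi <= lo:
        raise ResonanceAnalysisError(
            f"cannot merge sweeps with disjoint frequency ranges "
            f"([{up.frequency[0]:.3g}, {up.frequency[-1]:.3g}] vs "
            f"[{down.frequency[0]:.3g}, {down.frequency[-1]:.3g}])")
    if np.array_equal(up.frequency, down.frequency):
        grid = up.frequency.copy()
    else:
        n = max(up.frequency.size, down.frequency.size)
        grid = np.linspace(lo, hi, n)
    a_up = np.interp(grid, up.frequency, up.amplitude)
    a_down = np.interp(grid, down.frequency, down.amplitude)
    merged = ResonanceCurve(grid, np.maximum(a_up, a_down), direction="merged",
                            qc_flags=sorted(set(up.qc_flags) | set(down.qc_flags)))
    if smooth:
        merged = smooth_curve(merged, median=median, mean=mean)
    return merged


# ---------------------------------------------------------------------------
# Scalar features


def _refined_peak(curve: ResonanceCurve) -> tuple[float, float, int]:
    """Quadratically refined (frequency, amplitude, discrete index) of the
    curve maximum; ties resolve to the lowest frequency."""
    amp = curve.amplitude
    i = int(np.argmax(amp))  # first (= lowest-frequency) maximum on ties
    if i == 0 or i == amp.size - 1:
        raise ResonanceAnalysisError(
            "resonance not bracketed: curve maximum lies on the boundary of "
            "the frequency grid")
    f1, f2, f3 = curve.frequency[i - 1:i + 2]
    a1, a2, a3 = amp[i - 1:i + 2]
    denom = (a1 - 2.0 * a2 + a3)
    if denom >= 0.0:  # flat or non-concave triple: keep the discrete peak
        return float(curve.frequency[i]), float(a2), i
    # vertex of the parabola through the three points (general spacing)
    x1, x2, x3 = f1 - f2, 0.0, f3 - f2
    num = (a1 - a2) * (x3**2 - x2**2) - (a3 - a2) * (x1**2 - x2**2)
    den = 2.0 * ((a1 - a2) * (x3 - x2) - (a3 - a2) * (x1 - x2))
    dx = num / den if den != 0 else 0.0
    dx = float(np.clip(dx, x1, x3))
    # amplitude of the parabola at the vertex
    coeffs = np.polyfit([x1, x2, x3], [a1, a2, a3], 2)
    a_peak = float(np.polyval(coeffs, dx))
    return float(f2 + dx), a_peak, i


def natural_frequency(curve: ResonanceCurve) -> float:
    """Frequency of the curve's maximum, refined by 3-point quadratic
    interpolation around the discrete peak.  The maximum must be interior.
    """
    f0, _, _ = _refined_peak(curve)
    return f0


def bandwidth_3db(curve: ResonanceCurve) -> tuple[float, float, float]:
    """Half-power points (f_lo, f_hi) nearest the peak and their width.

    The crossings of peak_amplitude / sqrt(2) are linearly interpolated on
    each side of the peak; if the curve never drops below the half-power
    level on one side the bandwidth is not resolved and an error is raised.
    """
    f_peak, a_peak, i_peak = _refined_peak(curve)
    level = a_peak / math.sqrt(2.0)
    f, a = curve.frequency, curve.amplitude

    def cross(idx_range, side: str) -> float:
        for i in idx_range:
            j = i + 1
            if (a[i] - level) * (a[j] - level) <= 0 and a[i] != a[j]:
                return float(f[i] + (level - a[i]) * (f[j] - f[i]) / (a[j] - a[i]))
        raise ResonanceAnalysisError(
            f"bandwidth not resolved: half-power level never crossed on the "
            f"{side} side of the peak")

    f_lo = cross(range(i_peak - 1, -1, -1), "low-frequency")
    f_hi = cross(range(i_peak, a.size - 1), "high-frequency")
    if not f_lo < f_peak < f_hi:
        raise ResonanceAnalysisError("bandwidth not resolved: crossings do "
                                     "not bracket the peak")
    return f_lo, f_hi, f_hi - f_lo


def octave_length(f_lo: float, f_hi: float) -> float:
    """Half-power interval in octaves: log2(f_hi / f_lo)."""
    if not 0 < f_lo < f_hi:
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    return math.log2(f_hi / f_lo)


def damping_ratio(f0: float, delta_f: float) -> float:
    """Half-power damping-ratio estimate zeta = delta_f / (2 f0)."""
    if f0 <= 0 or delta_f <= 0:
        raise ValueError("f0 and delta_f must be > 0")
    return delta_f / (2.0 * f0)


def skew_index(up: ResonanceCurve, down: ResonanceCurve) -> float:
    """Signed softening/hardening index from an up/down sweep pair.

    With a bent (nonlinear) resonance the sweep running toward the bend
    tracks the resonant branch out to its high-amplitude tip, so the two
    single-sweep peaks separate in frequency and the *higher-amplitude*
    sweep peaks on the side the backbone bends toward.  The index is the
    peak-frequency shift, normalised by the mean peak frequency and
    oriented by the amplitude ordering:

        index = (f_peak[stronger sweep] - f_peak[weaker sweep]) / f_mean

    Negative for softening (tip at low frequency, carried by the
    down-sweep), positive for hardening, ~0 for a linear strip.
    """
    f_up, a_up, _ = _refined_peak(up)
    f_down, a_down, _ = _refined_peak(down)
    f_mean = 0.5 * (f_down + f_up)
    shift = (f_down - f_up) / f_mean
    return shift if a_down >= a_up else -shift


# ---------------------------------------------------------------------------
# Measurement- and study-level drivers


def analyze_measurement(up: OscillationRecord | None = None,
                        down: OscillationRecord | None = None, *,
                        n_points: int = 200, window_cycles: float = 3.0,
                        smooth: bool = True) -> ResonanceFeatures:
    """Extract the features of one measurement (one or both sweep directions).

    With both directions, the features are read from the merged (upper
    envelope) curve and the skew index from the single-sweep pair; with one
    direction the skew index is NaN.
    """
    if up is None and down is None:
        raise ValueError("at least one sweep record is required")
    curves: dict[str, ResonanceCurve] = {}
    if up is not None:
        curves["up"] = extract_resonance_curve(up, n_points=n_points,
                                               window_cycles=window_cycles)
    if down is not None:
        curves["down"] = extract_resonance_curve(down, n_points=n_points,
                                                 window_cycles=window_cycles)
    if len(curves) == 2:
        curve = merge_sweeps(curves["up"], curves["down"], smooth=smooth)
        skew = skew_index(curves["up"], curves["down"])
    else:
        curve = next(iter(curves.values()))
        if smooth:
            curve = smooth_curve(curve)
        skew = math.nan

    f0, a_peak, _ = _refined_peak(curve)
    f_lo, f_hi, bw = bandwidth_3db(curve)
    zeta = damping_ratio(f0, bw)
    flags = list(curve.qc_flags)
    rec = up if up is not None else down
    if rec.sweep.sweep_rate > QUASI_STEADY_LIMIT * bw**2:
        flags.append("sweep_too_fast")
    return ResonanceFeatures(f0=f0, peak_amplitude=a_peak, f_lo=f_lo,
                             f_hi=f_hi, bandwidth_3db=bw,
                             octave_length=octave_length(f_lo, f_hi),
                             damping_ratio=zeta, skew_index=skew,
                             qc_flags=flags)


def read_record(path: str | Path, sweep: SweepSpec,
                metadata: dict | None = None) -> OscillationRecord:
    """Read one 3-column delimited signal file (time_s, excitation, response)."""
    data = np.loadtxt(path, skiprows=1)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns (time, excitation, response)")
    # rebuild the exact uniform grid (text storage truncates the time stamps)
    grid = data[0, 0] + np.arange(data.shape[0]) / sweep.sampling_rate
    if np.max(np.abs(data[:, 0] - grid)) > 1e-4:
        raise ValueError(f"{path}: time column is not the uniform grid of "
                         f"the declared sampling rate {sweep.sampling_rate} Hz")
    rec = OscillationRecord(time=grid, excitation=data[:, 1],
                            response=data[:, 2], sweep=sweep,
                            metadata=dict(metadata or {}))
    rec.validate()
    return rec


def _iter_measurements(source: SyntheticStudy | str | Path):
    """Yield (measurement dict, {direction: record}) pairs from a study
    object or an on-disk study directory."""
    if isinstance(source, SyntheticStudy):
        by_key: dict[tuple, dict[str, OscillationRecord]] = {}
        for rec in source.records:
            md = rec.metadata
            key = (md["subject"], md["stage"], md["mass_index"])
            by_key.setdefault(key, {})[md["direction"]] = rec
        for meas in source.manifest["measurements"]:
            key = (meas["subject"], meas["stage"], meas["mass_index"])
            yield meas, by_key.get(key, {})
        return
    root = Path(source)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    import json

    with open(manifest_path) as fh:
        manifest = json.load(fh)
    sweep_cfg = manifest["sweep"]
    for meas in manifest["measurements"]:
        recs = {}
        for direction, rel in meas["files"].items():
            spec = SweepSpec(f_start=sweep_cfg["f_start"],
                             f_end=sweep_cfg["f_end"],
                             sweep_rate=sweep_cfg["sweep_rate"],
                             direction=direction,
                             sampling_rate=sweep_cfg["sampling_rate"],
                             settle_time=sweep_cfg["settle_time"])
            recs[direction] = read_record(root / "signals" / rel, spec)
        yield meas, recs


def analyze_study(source: SyntheticStudy | str | Path, *, n_points: int = 200,
                  window_cycles: float = 3.0,
                  smooth: bool = True) -> pd.DataFrame:
    """Run the resonance analysis over every measurement of a study.

    ``source`` is either a :class:`SyntheticStudy` or a study directory
    (manifest.json + signals/).  Per-measurement failures become rows with
    NaN features and an ``error:`` QC flag instead of aborting the study.
    Returns one row per measurement: subject, group, stage, mass_index,
    f0_Hz, peak_amp, bw3db_Hz, octave_len, zeta, skew_index, qc_flags.
    """
    rows = []
    for meas, recs in _iter_measurements(source):
        base = {"subject": meas["subject"], "group": meas["group"],
                "stage": meas["stage"], "mass_index": int(meas["mass_index"])}
        try:
            feats = analyze_measurement(recs.get("up"), recs.get("down"),
                                        n_points=n_points,
                                        window_cycles=window_cycles,
                                        smooth=smooth)
            row = {**base, "f0_Hz": feats.f0, "peak_amp": feats.peak_amplitude,
                   "bw3db_Hz": feats.bandwidth_3db,
                   "octave_len": feats.octave_length,
                   "zeta": feats.damping_ratio, "skew_index": feats.skew_index,
                   "qc_flags": ";".join(feats.qc_flags)}
        except (ResonanceAnalysisError, ValueError) as exc:
            row = {**base, "f0_Hz": math.nan, "peak_amp": math.nan,
                   "bw3db_Hz": math.nan, "octave_len": math.nan,
                   "zeta": math.nan, "skew_index": math.nan,
                   "qc_flags": f"error:{exc}"}
        logger.info("measurement %s/%s/m%s qc=%s",
                    base["subject"], base["stage"], base["mass_index"],
                    row["qc_flags"] or "ok")
        rows.append(row)
    return pd.DataFrame(rows)
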