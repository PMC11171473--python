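# Methods

## Mechanical model

The strip preparation couples the driven upper end (base displacement
u(t)) to the suspended oscillating mass m (opaque mask + lead ring)
through a Kelvin–Voigt element — spring k and dashpot c in parallel —
optionally with a cubic term on the strip extension e = u − x:

    m ẍ = k e (1 + β e²) + c ė

Base excitation acts through both the spring and the dashpot because the
strip is the only element connecting the driver to the mass.  For β = 0
the steady-state amplitude ratio is the classical transmissibility

    T(r, ζ) = √[(1 + (2ζr)²) / ((1 − r²)² + (2ζr)²)],
    r = f / f₀,  f₀ = √(k/m)/2π,  ζ = c / (2√(km))

which serves as the closed-form oracle for the simulator.  β < 0 bends the
resonance backbone toward lower frequencies (softening, the typical
arterial behaviour), β > 0 toward higher (hardening); the cubic is the
minimal standard form for amplitude-dependent stiffness.

The excitation is a constant-amplitude sine held at the sweep's anchor
frequency for a settle time (≥ several ring-down times 1/(ζω₀), so the
free transient decays) and then chirped linearly.  Integration is a
fixed-step RK4 compiled with numba, sub-stepped to ≥ 40 steps per cycle of
the highest relevant frequency; slow sweeps through a narrow resonance
take 10⁵–10⁷ steps, which is why the stepper is compiled.  Non-finite or
exploding trajectories raise immediately — there is no silent truncation.

**Quasi-steady criterion.**  A linear sweep distorts the measured curve by
an amount controlled by η = sweep_rate / Δf₃dB², with Δf₃dB = 2ζf₀.
Measured against the closed form, the pointwise error of the extracted
curve is ≈ 0.5·η (5.5% at η = 0.1, 1% at η = 0.02).  Dedicated
verification sweeps therefore use η = 0.02; the default study sweep
(0.1 Hz/s over 5–25 Hz at 300 Hz sampling) gives η ≈ 0.04–0.09 across the
study's cells, which is accurate to ~0.5% in f₀ once up- and down-sweeps
are merged (the sweep-lag peak shifts of the two directions cancel).
Measurements whose sweep rate exceeds 0.25·Δf² (estimated from the
measured bandwidth) are QC-flagged `sweep_too_fast`.

## Signal processing

* **Envelopes.**  The resonance curve is the RMS of the response over the
  RMS of the excitation in windows of 3 cycles of the local commanded
  frequency, centred where the sweep law passes each output frequency
  (200 points by default).  The instantaneous frequency comes from the
  sweep law, not from the signal, because the rig commands the sweep.
  The settle section is discarded.
* **Merging.**  Up- and down-sweep curves are merged as the pointwise
  upper envelope on the intersection of their ranges (each single sweep
  under-reads the stationary peak on its lagging side), then smoothed by a
  5-point moving median followed by a 5-point moving mean.
* **Peak.**  f₀ is the curve maximum refined by 3-point quadratic
  interpolation; ties take the lower frequency; a maximum on the grid
  boundary is an error ("resonance not bracketed").  The peak of T lies at
  r slightly below 1, so reading f₀ from the peak under-estimates the
  undamped natural frequency by O(ζ²) (≈ 0.25% at ζ = 0.05) — accepted, as
  the curve peak is what the method reports.
* **Bandwidth.**  Half-power points are the linearly interpolated
  crossings of peak/√2 nearest the peak; octave length is log₂(f_hi/f_lo)
  of those points (an interpretation: the half-power interval expressed in
  octaves); ζ is estimated as Δf/(2f₀).
* **Skew index.**  With a bent resonance, the sweep running toward the
  bend tracks the resonant branch to its high-amplitude tip, so in
  brute-force Duffing sweeps the down-sweep peak sits below the up-sweep
  peak for *both* bend directions — the raw peak-shift sign does not
  discriminate softening from hardening.  The index is therefore the
  normalised peak-frequency shift oriented by the amplitude ordering of
  the two sweeps (the stronger sweep peaks on the bend side): negative for
  softening, positive for hardening, ≈ 0 (|index| < 0.01 at the tested
  sweep rates) for a linear strip.

## Loads, pressures and the modulus

Static elongation solves k·ΔL·(1 + β·ΔL²) = m_ring·g (Hooke's law when
β = 0; for softening strips loads beyond the fold of the cubic have no
equilibrium and raise).  g = 9.80665 m/s².

The equivalent blood pressure of a suspended ring is the thin-walled
Laplace equivalence p = m·g/(b·r_v) (1 mmHg = 133.322 Pa): the hanging
mass loads the strip of width b with the same tension per unit length that
pressure p exerts on a vessel of radius r_v.  The mapping is isolated in
one function and r_v is configurable, so any alternative calibration can
be substituted.  The default ring masses (4.0932, 5.51062, 6.92804,
8.34546 g; `scripts/calibrate_masses.py`) were calibrated once so the four
loads map to equally spaced pressures spanning 77.2–157.4 mmHg with the
default geometry.

E′ = (2πf₀)²·m·(L₀+ΔL)/S uses the full oscillating mass (mask + ring) for
m — the mask oscillates with the ring — with the mask mass an explicit,
configurable field.  E′ is kept in Pa internally and reported in MPa.

Default geometry: L₀ = 20 mm (helical strip from a rat descending thoracic
aorta), width b = 3 mm, media thickness h = 0.1 mm (S = 0.3 mm²), vessel
radius r_v = 1.3 mm.

## Synthetic study design

The generator's defaults are the study conditions: sham n = 3 and pin
n = 4 animals, 11 protocol stages (control; cumulative fentanyl 10⁻⁹,
10⁻⁸, 10⁻⁷, 10⁻⁶ M; 30-min wash-out; 10-min naloxone 10⁻⁶ M; the four
fentanyl concentrations under naloxone), four loads per stage.

The effect model is the f₀(p) line per group × stage: a base line
f₀ = 8.0 + 0.055·p (Hz, p in mmHg; ~12.2–16.7 Hz over the operating
range) scaled by per-stage factors encoding the qualitative treatment
effects — fentanyl relaxes the sham wall at every dose (factors
0.86–0.90), the melatonin-deficient wall resists only the lowest dose
(factor 1.00 at 10⁻⁹ M, with or without naloxone), wash-out restores sham
almost fully (0.99) while pin stays depressed (0.93), and naloxone alone
lowers stiffness in both groups.  E′ is *derived* from the realized f₀
through the modulus formula rather than configured independently: with
mass and geometry fixed, E′ is a deterministic transform of f₀, so an
independent E′ target would be over-determined.  The induced E′(p) rises
≈ 3-fold over the span and is well approximated by a·exp(b·p)
(b ≈ 0.013–0.014 /mmHg), so the exponential regression branch behaves as
intended.

Noise: per-animal intercept scatter (sd 0.05 Hz) plus per-measurement
scatter (sd 0.15 Hz, ~1% of f₀) perturb the realized stiffness k of every
oscillator, so signal-level and feature-level generation share one truth
table; ADC noise (sd 1% of the excitation amplitude) is added to the
recorded response only.  ζ = 0.05 and β = 0 by default (nonlinearity is
exercised through the API, keeping the default study's linear analysis
unbiased).  With all noise off, the pipeline recovers the configured slope
and intercept to ≪ 1% through the full signal path.

What the generator does **not** emulate: tissue creep and preconditioning
drift, strip slack at large response amplitudes, multi-mode or distributed
mass dynamics, drug pharmacokinetics (treatment effects are instantaneous
phenomenological shifts), temperature or superfusion hydrodynamics, and
realistic between-animal heterogeneity (deliberately small, see
limitations).  Passing tests therefore validate the estimation and
inference machinery under the stated model, not the biology of real
preparations.

## Statistics

Cells pool all subjects of a group × stage (group-level curves over the
four pressures; no per-subject random effects).  f₀(p): OLS with
closed-form SEs.  E′(p): least squares on a·exp(b·p), initialised from the
log-linear fit; non-converged fits are flagged and excluded from
comparisons.  Comparisons: two-line ANCOVA for f₀ (equal-slopes F; equal
elevations under a common slope, reported only when the slopes do not
differ significantly) and the extra-sum-of-squares F test for E′ (shared
vs separate (a, b), df = (2, n_A + n_B − 4)).  α = 0.05 per comparison, no
multiplicity correction by default (a Holm option exists, default off).
Exact fits (residual SS below 10⁻¹²) short-circuit the F ratio to 0/1 —
identical datasets give p = 1 rather than 0/0.

Both tests are calibrated: under 2000-rep null simulations at the study's
design (4 pressure levels × 4 replicates per cell) the empirical type-I
error is within 2 Monte-Carlo SEs of 0.05.  On generated studies the curve
test runs slightly conservative (null rejection ≈ 2% rather than 5%):
the two-parameter exponential carries a small, group-shared lack-of-fit to
the modulus-induced E′(p) shape, inflating the residual SS in the F
denominator.

## Problem sizes in the test suite

Verification sweeps use f₀ = 8–20 Hz oscillators with 10⁵–10⁶ samples per
record; feature-recovery statistics use 100 random oscillators; null
calibrations use 2000 replicates; treatment-pattern recovery uses 200
replicate feature-level studies of the 5-stage fentanyl block.  These
sizes give Monte-Carlo SEs small relative to every asserted tolerance
while keeping the default suite under a minute of simulation time.

## Known limitations

* Pooled regression treats all points within a cell as independent; with
  realistic between-animal variance the F tests would be anticonservative
  for between-group contrasts.  The default between-animal sd is therefore
  kept small, and mixed-effects modelling is explicitly out of scope.
* Because E′ is computed from the measured f₀, the f₀ and E′ branches of
  the report are statistically coupled on synthetic data; observed
  discrepancies between the two branches on real data (where E′ also
  carries geometry-measurement error) cannot be reproduced by the
  generator.
* The skew index needs visible jump hysteresis (nonlinear frequency shift
  comparable to the bandwidth) to be reliable; weak nonlinearity leaves
  both sweeps nearly coincident and the index near 0.
* The exponential model form a·exp(b·p) and the Laplace pressure mapping
  are documented interpretations; both sit behind single functions and can
  be swapped without touching the rest of the pipeline.
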