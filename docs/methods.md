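# Methods

This note documents the models, estimators and numerical choices behind
`leafwave`, and what the synthetic benchmark does and does not establish.

## Sensor model and calibration

A corona-phase SWNT nanosensor responds to its analyte with a saturating
fractional quench described by the Langmuir adsorption isotherm

    r(c) = r_max · c / (K_D + c),

with K_D the dissociation constant (µM) and r_max the fractional quench at
saturation.  Responses are stored as signed fractions with quenching
positive; turn-on responses are negative.  The SA sensor is parameterised
by K_D = 32 µM and r_max = 0.462 (the value implied by a 35 % quench at
100 µM together with that K_D).  The H₂O₂ sensor's constants are not
published; the fixture curve (K_D = 150 µM, r_max = 0.80) is a *synthetic
placeholder* of the same functional form, used only to close the
render-and-recover loop — nothing downstream depends on its particular
values because the generator and the pipeline share the curve.

Fitting uses bounded nonlinear least squares (K_D ∈ (10⁻³, 10⁵) µM,
r_max ∈ (10⁻³, 1]) from ten log-spaced K_D starts; the reported fit
quality is the Pearson correlation of fitted vs observed responses.  The
detection limit is the smallest concentration whose response clears three
times a supplied blank-noise SD — analytically
`invert_response(3·noise_sd)` since the isotherm is monotone.  A noise SD
of 0.0186 reproduces the SA sensor's ~4.4 µM limit and is kept as the
default fixture for that sensor.  Inversion clips negative responses
(baseline jitter) to 0 µM and counts them in a diagnostics dict rather
than failing; responses at or above r_max raise a saturation error in the
scalar API and are set to a reported ceiling (10·K_D) in the pixel-wise
map pathway.

## Reaction network

Stress signalling is modelled as mass action over nine-plus species
(concentrations in µM, time in minutes):

    A + P  --k-->   2A          autocatalytic H₂O₂ production (RBOH pool)
    A      --kd-->  B           H₂O₂ decay
    A + pF --kf1--> F1          activation of the SA precursor chain
    F1 --kF2--> F2 --> ... --> Fn --ks--> S
    A + pI --ki-->  I           inhibitor production
    I + pF --kr-->  xF1         precursor deactivation

A stress at `t_stress` seeds A with `a0`; an optional secondary burst
re-injects `p2` of P at `t2` (an impulse, with integration restarted at
the discontinuity).  The instantaneous seed is the simplest mechanism
consistent with an H₂O₂ wave that appears within minutes; whether P
regenerates between bursts is unknown, so the impulse model was chosen.
The chain length defaults to n = 3 intermediates (configurable 1–6): the
delay between the H₂O₂ burst and SA release grows with chain length at
fixed per-step rate, which is what makes the late infection-triggered
onset representable.  Increasing the inhibitor pool pi0 likewise delays
SA onset; both monotonicities are property-tested.

Integration is piecewise LSODA with rtol 1e-8 / atol 1e-10 across the
`t_stress` and `t2` discontinuities.  Three exact conservation laws —
A-units, pF-units and pI-units — are checked against every trajectory;
an independent reaction-list formulation (fixed-step RK4 at dt = 1e-3 min,
and a Gillespie SSA at large copy number) serves as the cross-check in
the test suite.

Fitting minimises w_A·Σ(A_model−A_obs)² + w_S·Σ(S_model−S_obs)² with
weights the inverse squared series maxima, so the µM-scale disparity
between the H₂O₂ burst and the SA plateau cannot let one channel
dominate.  Parameters are optimised in log10 space, bounded to ±3 decades
around the initial guess (unbounded fitting can wander into pathologically
stiff corners), with Latin-hypercube multistarts (default 16; 1 suffices
when the start is informative).  Parameters whose initial value is exactly
zero are implicitly frozen, since they cannot be log-scaled — this is also
the natural encoding of a wounding-type experiment with no SA branch.

## Imaging

The measurement contract is ratiometric: both the active and the
co-infiltrated reference spot see the same multiplicative artefacts
(laser drift, leaf movement), so
R(t) = (I_act/Ī_act,pre) / (I_ref/Ī_ref,pre) cancels them exactly and the
quench fraction is r(t) = 1 − R(t), smoothed with a centred 10-point
moving average (shrinking windows at the record edges).  The pre-stress
baseline is all frames before `t_stress`.  Two ROI reductions are
provided: plain mask means (SA and reference spots), and a fixed subset of
the 200 pixels with the largest total first-to-last quench (H₂O₂ spot).
The subset is chosen once over the whole record so the series tracks one
coherent region; per-frame re-selection is available but biases a null
record (ranking pure noise manufactures an apparent decline — the reason
feature extraction gates on significance, below).  Pixel-wise maps
normalise each pixel to its own pre-stress mean and divide by the
reference ROI's scalar drift series, since reference and active spots are
spatially separate; map-vs-series consistency is property-tested.

## Wave features

* **Baseline and peak** — baseline is the pre-stress mean; the wave
  amplitude is the post-stress global maximum above it.
* **Significance gate** — a peak that does not clear
  k_sd × max(baseline SD, sensor noise floor) counts as no wave; the floor
  is the concentration equivalent of 0.5 % of r_max through the sensor's
  calibration (≈0.16 µM for the SA sensor).
* **FWHM** — time between the two half-amplitude crossings, linearly
  interpolated, each taken as the crossing nearest the peak.
* **Rates** — least-squares slopes over the 10–90 % amplitude band of each
  flank, ×60 to µM/h.  The falling flank ends where the record ends, the
  wave drops below the band, or the curve rebounds more than 5 % of the
  amplitude above its running minimum — a secondary ROS burst is a new
  wave, not decay.
* **Onset** — first post-stress time exceeding baseline mean + k_sd·SD for
  3 consecutive frames (defaults k_sd = 1, sustain = 3), relative to
  `t_stress`; the multiplier and sustainment are configurable because the
  original criterion is stated only loosely.
* **SA velocity** — stress-site distance over mean onset time, 3-decimal
  cm/min.  The site-to-sensor distance is 1.0 cm in all presets.
* **ROS front velocity** — pixels binned by distance from the stress site
  (0.05 cm bins); per bin, the median concentration trace (smoothed over
  5 frames) is crossed at several levels (20–60 % of the 99th-percentile
  spatial peak) with linear interpolation in time; per level, the front
  slowness is the slope of arrival time vs distance; the velocity is the
  inverse mean slowness.  Three estimator choices matter and were made on
  statistical grounds: regressing time on distance keeps arrival noise off
  the regressor (avoiding errors-in-variables attenuation); sub-frame
  interpolation is required because the fastest front (1.2 cm/min)
  crosses the whole sensor strip within about one frame; and averaging
  over crossing levels uses quasi-independent parts of the rising flank,
  reducing the variance by roughly a third at 1 % noise.

## Synthetic data generator

The generator emulates the measurement, not the leaf.  Defaults: 128×128
grid at 0.01 cm/pixel, 0.5 min frame interval (a 30 s exposure cadence),
240 min duration, stress at t = 10 min, base intensity 10 000 counts, 1 %
Gaussian camera noise, 10 % multiplicative drift (60-min sinusoid plus a
linear ramp of half that amplitude) shared by every spot.  The H₂O₂ field
at distance d is the local kinetic waveform delayed by d/wave_speed — a
constant-shape travelling wave.  SA appears at the source at `sa_onset`
and spreads as a 2-D Gaussian plume of variance σ₀² + 2·D·(t − sa_onset)
whose *amplitude* follows the kinetic S(t); the plume's spatial integral
therefore equals S(t)·2πσ²(t), which the quadrature test verifies.  D is
a phenomenological spread coefficient (apoplastic transport, not
molecular diffusion) set per archetype so the plume reaches the sensor
spot at the archetype's onset time.

The four archetype presets are one-time fixtures: the waveform parameters
(k, kd, a0, p0) were tuned once against the target features measured on
the generator's own ROI output (so front-sweep smearing across the sensor
strip is accounted for), the chain rate against the source onset, and D
against the sensor onset; the resulting numbers are frozen in
`leafwave/data/presets.yaml` and never re-derived at run time.  Archetype
signatures: wounding — narrow fast wave (FWHM ≈ 17 min), no SA; Xcc —
broad wave, SA onset ≈ 87 min, after the wave has decayed below half-max;
light — broad wave, SA at ≈ 22.5 min, while the wave is high, secondary
burst at 2 h; heat — very fast rise (≈ 106 µM/h) with slow decay
(≈ 12 µM/h), SA at ≈ 35.5 min, secondary burst at 1.5 h.  H₂O₂ peak
amplitudes (≈ 10–19 µM) follow from those constraints rather than being
targets themselves.

What passing the round-trip shows: that the pipeline's normalisation,
smoothing, inversion and estimators recover known fields at realistic
noise and drift.  What it does not show: robustness to leaf morphology,
chlorophyll autofluorescence, sensor photobleaching, spatially varying
sensor loading, or cross-sensitivity between the two analytes — none of
which the generator emulates.

## Benchmark protocol and problem sizes

Feature-recovery measurements average three replicate renders (different
noise seeds, same ground truth), matching the usual n = 3 replicate
design; single-replicate front velocities are noise-limited to roughly
±15 %.  The parameter-recovery study fits 20 noisy realisations (5 %
multiplicative noise) of the wounding waveform on a 1-min grid from
starts perturbed by ×U(0.5, 2); the 1-min cadence matters because the
seed amplitude a0 is constrained mainly by the few pre-burst rise
samples.  The conservation audit draws 100 random parameter sets.  These
sizes keep the full suite and the acceptance script within a few minutes
on one CPU while leaving the medians well clear of their tolerances.

## Known limitations

* The kinetic model is a local (well-mixed) description; spatial
  propagation lives entirely in the generator's kinematic wave and plume.
* Rate constants fitted to real data are not expected to match any
  particular published fit — the loss weighting and parameter-sharing
  scheme of the original analysis is not public, so only waveform-level
  agreement (peak, FWHM, onsets) is claimed.
* The inhibitor branch is generic: it reproduces onset ordering, not any
  identified molecular mechanism.
* `a0` is weakly identified from waveform data (median recovery ≈ 10 %,
  worst cases ≈ 50 % at 5 % noise); k, kd and p0 are much tighter.
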