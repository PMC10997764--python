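"""Synthetic nIR frame stacks with known ground truth.

The generator emulates the measurement geometry of a multiplexed
nanosensor experiment on a leaf: three spatially separated sensor spots
(H₂O₂, SA, reference), a stress applied at a known site and time, a
travelling H₂O₂ wave, a delayed diffusive SA field, multiplicative
laser/leaf-movement drift shared by all spots, and additive Gaussian
camera noise.  Because the underlying concentration fields and their
wave features are known exactly, every pipeline stage can be validated
end-to-end without real data.

Physical model
--------------
* H₂O₂ at a pixel a distance ``d`` from the stress site is the local
  kinetic waveform A(t) delayed by the front travel time ``d /
  wave_speed`` — a constant-speed travelling wave of fixed shape.
* SA appears at the source at ``sa_onset`` and spreads as a 2-D
  Gaussian plume of variance σ²(t) = σ₀² + 2·D·(t − sa_onset) whose
  amplitude follows the kinetic S(t) waveform (the generation front
  travels; the subsequent profile evolves diffusively).
* A pixel of a sensor spot with calibration curve r(·) renders as
  I = I_base · (1 − r(c)) · drift(t) + ε, with drift(t) a slow
  sinusoid plus linear ramp shared by *all* spots (the reference spot
  has r ≡ 0) and ε ~ N(0, noise_sd · I_base).

The four stress archetypes (wounding, Xcc infection, high light, high
heat) plus a null control are available through :func:`preset`; their
kinetic parameters are frozen fixtures chosen so the noise-free ground
truth reproduces each archetype's characteristic wave features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .calibration import CalibrationCurve, response_at
from .imaging import FrameStack, RoiSet
from .kinetics import KineticParams, simulate
from .presets import preset_dict
from .wave_features import (
    ConcentrationSeries,
    WaveFeatures,
    extract_features,
    ros_front_velocity,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_rois",
    "default_curves",
    "make_fields",
    "render_stack",
    "preset",
    "ground_truth_series",
]

STRESS_LABELS = ("wounding", "xcc", "light", "heat", "null")

#: SA sensor calibration (K_D = 32 µM, 46.2 % saturation quench).
SA_CURVE = CalibrationCurve(analyte="sa", kd=32.0, r_max=0.462)

#: Synthetic stand-in for the H₂O₂ sensor calibration, whose constants
#: are not published: a Langmuir curve of plausible shape, used only to
#: close the render/recover loop in tests.
H2O2_CURVE_SYNTHETIC = CalibrationCurve(analyte="h2o2", kd=150.0, r_max=0.80)


def default_curves() -> dict[str, CalibrationCurve]:
    return {"sa": SA_CURVE, "h2o2": H2O2_CURVE_SYNTHETIC}


def default_rois(grid: tuple[int, int] = (128, 128)) -> RoiSet:
    """Sensor-spot layout used by all presets.

    Stress site near the top edge; the H₂O₂ sensor is a strip running
    away from the site (0.10–0.80 cm at the default 0.01 cm pixels) so a
    front can be tracked across it; the SA spot is a disc centred 1.00 cm
    from the site; the reference disc sits to the side.
    """
    rows, cols = grid
    site = (round(0.08 * rows), cols // 2)
    yy, xx = np.mgrid[0:rows, 0:cols]

    strip = (
        (np.abs(xx - site[1]) <= round(0.04 * cols))
        & (yy >= site[0] + round(0.08 * rows))
        & (yy <= site[0] + round(0.63 * rows))
    )
    sa_center = (site[0] + round(0.78 * rows), site[1])
    sa = (yy - sa_center[0]) ** 2 + (xx - sa_center[1]) ** 2 <= round(0.09 * rows) ** 2
    ref_center = (site[0] + round(0.42 * rows), round(0.16 * cols))
    ref = (yy - ref_center[0]) ** 2 + (xx - ref_center[1]) ** 2 <= round(
        0.09 * rows
    ) ** 2
    return RoiSet(masks={"h2o2": strip, "sa": sa, "reference": ref}, stress_site=site)


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of one synthetic stress experiment."""

    stress_label: str
    kinetic_params: KineticParams
    wave_speed: float  # cm/min, H₂O₂ front
    sa_onset: float | None = None  # min, SA appearance at the source
    sa_diffusion: float | None = None  # cm²/min
    sa_sigma0: float = 0.05  # cm, initial plume width
    grid: tuple[int, int] = (128, 128)
    pixel_size: float = 0.01  # cm
    frame_interval: float = 0.5  # min (30 s exposure cadence)
    duration: float = 240.0  # min
    t_stress: float = 10.0  # min
    stress_site: tuple[int, int] | None = None  # default: from roi layout
    drift_amplitude: float = 0.10  # fraction
    noise_sd: float = 0.01  # fraction of I_base
    i_base: float = 10_000.0  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stress_label not in STRESS_LABELS:
            raise ValueError(f"unknown stress label '{self.stress_label}'")
        if self.duration <= self.t_stress:
            raise ValueError("duration must exceed t_stress")
        if self.sa_onset is not None and self.sa_onset < self.t_stress:
            raise ValueError("sa_onset cannot precede t_stress")
        if (self.sa_onset is None) != (self.sa_diffusion is None):
            raise ValueError("sa_onset and sa_diffusion must be given together")
        for name in ("pixel_size", "frame_interval", "i_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wave_speed <= 0 and self.stress_label != "null":
            raise ValueError("wave_speed must be > 0")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def rois(self) -> RoiSet:
        layout = default_rois(self.grid)
        if self.stress_site is not None:
            layout = RoiSet(masks=layout.masks, stress_site=self.stress_site)
        return layout


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free concentration fields and the features they encode."""

    times: np.ndarray
    h2o2_field: np.ndarray  # (T, H, W) µM
    sa_field: np.ndarray  # (T, H, W) µM
    features: dict[str, WaveFeatures]
    velocities: dict[str, float | None]  # cm/min per species


def _radial_h2o2(
    traj_t: np.ndarray, traj_a: np.ndarray, d_grid: np.ndarray, times: np.ndarray,
    speed: float,
) -> np.ndarray:
    """A(t − d/speed) on a (T, D) grid; zero before the front arrives."""
    shifted = times[:, None] - d_grid[None, :] / speed  # (T, D)
    return np.interp(shifted, traj_t, traj_a, left=0.0)


def _radial_sa(
    traj_t: np.ndarray,
    traj_s: np.ndarray,
    d_grid: np.ndarray,
    times: np.ndarray,
    onset: float,
    diffusion: float,
    sigma0: float,
) -> np.ndarray:
    """Gaussian plume: amplitude S(t), variance σ₀² + 2·D·(t − onset)."""
    s_t = np.interp(times, traj_t, traj_s)
    out = np.zeros((times.size, d_grid.size))
    active = times >= onset
    var = sigma0**2 + 2.0 * diffusion * (times[active] - onset)
    out[active] = s_t[active, None] * np.exp(
        -(d_grid[None, :] ** 2) / (2.0 * var[:, None])
    )
    return out


def ground_truth_series(
    truth: GroundTruth, rois: RoiSet, label: str, config: SynthConfig
) -> ConcentrationSeries:
    """ROI-mean concentration series of a noise-free ground-truth field."""
    fld = truth.sa_field if label == "sa" else truth.h2o2_field
    vals = fld[:, rois.masks[label]].mean(axis=1)
    return ConcentrationSeries(
        times=truth.times, values=vals, t_stress=config.t_stress, label=label
    )


def make_fields(config: SynthConfig) -> GroundTruth:
    """Noise-free H₂O₂ and SA concentration fields plus their features."""
    times = config.times
    rois = config.rois()
    site = rois.stress_site
    rows, cols = config.grid
    yy, xx = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(yy - site[0], xx - site[1]) * config.pixel_size

    shape = (times.size, rows, cols)
    if config.stress_label == "null":
        zero = np.zeros(shape, dtype=np.float32)
        truth = GroundTruth(
            times=times,
            h2o2_field=zero,
            sa_field=zero.copy(),
            features={},
            velocities={"h2o2": None, "sa": None},
        )
        return truth

    fine = np.arange(0.0, config.duration + 0.25, 0.25)
    traj = simulate(config.kinetic_params, fine)

    d_grid = np.linspace(0.0, float(dist.max()) + 1e-6, 400)
    rad_h = _radial_h2o2(fine, traj.h2o2, d_grid, times, config.wave_speed)
    if config.sa_onset is not None:
        rad_s = _radial_sa(
            fine, traj.sa, d_grid, times, config.sa_onset,
            config.sa_diffusion, config.sa_sigma0,
        )
    else:
        rad_s = np.zeros_like(rad_h)

    flat = dist.ravel()
    h2o2_field = np.empty(shape, dtype=np.float32)
    sa_field = np.empty(shape, dtype=np.float32)
    for i in range(times.size):
        h2o2_field[i] = np.interp(flat, d_grid, rad_h[i]).reshape(rows, cols)
        sa_field[i] = np.interp(flat, d_grid, rad_s[i]).reshape(rows, cols)

    truth = GroundTruth(
        times=times,
        h2o2_field=h2o2_field,
        sa_field=sa_field,
        features={},
        velocities={},
    )
    _fill_truth_features(truth, rois, config)
    return truth


def _fill_truth_features(
    truth: GroundTruth, rois: RoiSet, config: SynthConfig
) -> None:
    from .imaging import ConcentrationMap  # local: avoid import cycle at module load

    sa_dist = _roi_distance_cm(rois, "sa", config.pixel_size)
    for label in ("h2o2", "sa"):
        series = ground_truth_series(truth, rois, label, config)
        dist = sa_dist if label == "sa" else None
        truth.features[label] = extract_features(series, distance_cm=dist)

    truth.velocities["sa"] = truth.features["sa"].velocity
    masked = np.where(
        rois.masks["h2o2"][None, :, :], truth.h2o2_field, np.nan
    )
    cmap = ConcentrationMap(
        times=truth.times,
        maps=masked,
        pixel_size=config.pixel_size,
        saturated_pixel_count=np.zeros(truth.times.size, dtype=int),
    )
    try:
        truth.velocities["h2o2"] = ros_front_velocity(cmap, rois.stress_site)
    except ValueError:
        truth.velocities["h2o2"] = None


def _roi_distance_cm(rois: RoiSet, label: str, pixel_size: float) -> float:
    rr, cc = np.nonzero(rois.masks[label])
    centroid = (rr.mean(), cc.mean())
    return float(
        np.hypot(centroid[0] - rois.stress_site[0], centroid[1] - rois.stress_site[1])
        * pixel_size
    )


def render_stack(
    truth: GroundTruth,
    config: SynthConfig,
    curves: Mapping[str, CalibrationCurve] | None = None,
) -> tuple[FrameStack, RoiSet]:
    """Forward measurement model: fields -> noisy drifting intensity stack.

    Sensor pixels render as I_base·(1 − r(c))·drift(t) + ε with the
    label's calibration r(·); the reference spot and the leaf background
    (at 10 % of I_base) carry the same drift and noise.  Deterministic
    for a fixed ``config.seed``.
    """
    curves = dict(curves) if curves is not None else default_curves()
    rois = config.rois()
    times = truth.times
    rng = np.random.default_rng(config.seed)

    # slow sinusoid plus a linear ramp of half the sinusoid amplitude,
    # shared by every pixel (laser power / leaf movement surrogate)
    drift = (
        1.0
        + config.drift_amplitude * np.sin(2 * np.pi * times / 60.0)
        + 0.5 * config.drift_amplitude * times / max(config.duration, 1.0)
    )

    frames = np.full(
        (times.size, *config.grid), 0.10 * config.i_base, dtype=float
    )
    for label, mask in rois.masks.items():
        if label == "reference":
            frames[:, mask] = config.i_base
            continue
        fld = truth.sa_field if label == "sa" else truth.h2o2_field
        r = response_at(curves[label], np.asarray(fld[:, mask], dtype=float))
        frames[:, mask] = config.i_base * (1.0 - r)

    frames *= drift[:, None, None]
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd * config.i_base, frames.shape)
    frames = np.clip(frames, 0.0, None)

    stack = FrameStack(
        times=times,
        frames=frames,
        pixel_size=config.pixel_size,
        t_stress=config.t_stress,
    )
    return stack, rois


def preset(stress_label: str, seed: int = 0, **overrides) -> SynthConfig:
    """Frozen configuration for one of the stress archetypes.

    Labels: ``wounding`` (fast narrow ROS wave, no SA), ``xcc``
    (infection: slow wave, late SA onset), ``light`` (slow wave, early
    SA, secondary burst at 2 h), ``heat`` (fast asymmetric wave, mid SA,
    secondary burst at 1.5 h), ``null`` (no stress).  Keyword overrides
    replace any :class:`SynthConfig` field.
    """
    d = preset_dict(stress_label)
    kp = KineticParams.from_dict(d["kinetics"]) if d.get("kinetics") else KineticParams(
        a0=1e-9
    )
    cfg = SynthConfig(
        stress_label=stress_label,
        kinetic_params=kp,
        wave_speed=d.get("wave_speed", 1.0),
        sa_onset=d.get("sa_onset"),
        sa_diffusion=d.get("sa_diffusion"),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
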