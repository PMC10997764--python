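"""Temporal feature extraction from stress-induced concentration waves.

A stress applied at ``t_stress`` launches a transient H₂O₂ wave and, for
most stresses, a delayed salicylic-acid rise.  The identity of the
stress is encoded in a handful of scalar features of these waveforms:

* FWHM — time between the two amplitude midpoints of the wave, measured
  above the pre-stress baseline;
* production / decay rates — slopes of the rising and falling flanks,
  regressed over the 10–90 % amplitude band and reported in µM/h;
* onset time — first sustained excursion beyond baseline variability,
  relative to the stress time;
* wave velocities — SA: stress-site distance over mean onset time;
  ROS: slope of a distance-vs-arrival-time regression over a pixel map.

All operations take a :class:`ConcentrationSeries` (mean concentration
vs time for one sensor ROI) or, for the ROS front, a pixel-wise
concentration map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .imaging import ConcentrationMap

__all__ = [
    "ConcentrationSeries",
    "WaveFeatures",
    "OneSidedWaveError",
    "BandTooNarrowError",
    "InsufficientFrontError",
    "UndefinedVelocityError",
    "average_series",
    "fwhm",
    "peak",
    "onset_time",
    "production_and_decay_rates",
    "rate_curve",
    "sa_wave_velocity",
    "ros_front_velocity",
    "extract_features",
    "features_to_csv",
]

# Noise floor (µM) substituted for a zero baseline SD during onset
# detection: the quench-noise floor of the SA sensor (0.5 % of its
# saturating response) mapped through the 32 µM / 0.462 calibration.
DEFAULT_SD_FLOOR_UM = 0.16


class OneSidedWaveError(ValueError):
    """Raised when a wave never returns through its half-maximum on one flank."""


class BandTooNarrowError(ValueError):
    """Raised when a flank holds fewer than two samples in the 10–90 % band."""


class InsufficientFrontError(ValueError):
    """Raised when fewer than three distance bins register a front arrival."""


class UndefinedVelocityError(ValueError):
    """Raised when a velocity is requested but no onset was detected."""


@dataclass(frozen=True)
class ConcentrationSeries:
    """Mean concentration (µM) vs time (min) for one sensor ROI."""

    times: np.ndarray
    values: np.ndarray
    t_stress: float
    stderr: np.ndarray | None = None
    replicate_count: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (t[0] <= self.t_stress <= t[-1]):
            raise ValueError("t_stress must lie within the time range")
        if self.stderr is not None:
            se = np.asarray(self.stderr, dtype=float)
            if se.shape != t.shape:
                raise ValueError("stderr must match times")
            object.__setattr__(self, "stderr", se)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_min": self.times, "concentration_uM": self.values})
        if self.stderr is not None:
            df["stderr_uM"] = self.stderr
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, t_stress: float, label: str = ""
    ) -> "ConcentrationSeries":
        df = pd.read_csv(path)
        se = df["stderr_uM"].to_numpy() if "stderr_uM" in df.columns else None
        return cls(
            times=df["time_min"].to_numpy(),
            values=df["concentration_uM"].to_numpy(),
            t_stress=t_stress,
            stderr=se,
            label=label,
        )


@dataclass(frozen=True)
class WaveFeatures:
    """Scalar wave statistics for one stress experiment."""

    peak_time: float | None = None  # min
    peak_value: float | None = None  # µM above baseline
    fwhm: float | None = None  # min
    production_rate: float | None = None  # µM/h
    decay_rate: float | None = None  # µM/h
    onset_time: float | None = None  # min post-stress, None if never
    velocity: float | None = None  # cm/min


def average_series(replicates: Sequence[ConcentrationSeries]) -> ConcentrationSeries:
    """Replicate mean ± standard error on a shared time grid.

    All replicates must share times and stress time; the result carries
    the per-time standard error of the mean and the replicate count.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for r in replicates[1:]:
        if not np.array_equal(r.times, first.times) or r.t_stress != first.t_stress:
            raise ValueError("replicates must share time grid and t_stress")
    vals = np.stack([r.values for r in replicates])
    n = len(replicates)
    stderr = vals.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else None
    return ConcentrationSeries(
        times=first.times,
        values=vals.mean(axis=0),
        t_stress=first.t_stress,
        stderr=stderr,
        replicate_count=n,
        label=first.label,
    )


def _baseline(series: ConcentrationSeries) -> float:
    pre = series.times < series.t_stress
    if not np.any(pre):
        return 0.0
    return float(np.mean(series.values[pre]))


def peak(series: ConcentrationSeries) -> tuple[float, float]:
    """(time, amplitude-above-baseline) of the global post-stress maximum."""
    post = series.times >= series.t_stress
    if not np.any(post):
        raise ValueError("no samples after t_stress")
    base = _baseline(series)
    idx = np.flatnonzero(post)
    k = idx[np.argmax(series.values[idx])]
    amp = float(series.values[k] - base)
    return float(series.times[k]), amp


def _cross_time(t0, v0, t1, v1, level) -> float:
    if v1 == v0:
        return float(t0)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def fwhm(series: ConcentrationSeries) -> float:
    """Full width at half maximum of the post-stress wave, in minutes.

    The wave amplitude is measured above the pre-stress baseline; the
    width is the time between the two half-amplitude crossings, each
    located by linear interpolation and, if a flank crosses the level
    several times, taken as the crossing nearest the peak.
    """
    t, v = series.times, series.values
    base = _baseline(series)
    pk_time, amp = peak(series)
    if amp <= 0:
        raise ValueError("no wave above baseline")
    half = base + amp / 2.0
    k = int(np.argmin(np.abs(t - pk_time)))

    t_left = None
    for i in range(k, 0, -1):
        if (v[i - 1] - half) * (v[i] - half) <= 0 and v[i] >= half:
            t_left = _cross_time(t[i - 1], v[i - 1], t[i], v[i], half)
            break
    if t_left is None:
        raise OneSidedWaveError("no half-maximum crossing on the rising flank")

    t_right = None
    for i in range(k, t.size - 1):
        if (v[i] - half) * (v[i + 1] - half) <= 0 and v[i] >= half:
            t_right = _cross_time(t[i], v[i], t[i + 1], v[i + 1], half)
            break
    if t_right is None:
        raise OneSidedWaveError("no half-maximum crossing on the falling flank")
    return t_right - t_left


def onset_time(
    series: ConcentrationSeries,
    baseline_window: float | None = None,
    k_sd: float = 1.0,
    sustain: int = 3,
    sd_floor: float = DEFAULT_SD_FLOOR_UM,
) -> float | None:
    """First sustained post-stress excursion beyond baseline variability.

    The baseline is the window of length ``baseline_window`` minutes ending
    at ``t_stress`` (all pre-stress frames when None).  The onset is the
    first post-stress time whose value exceeds baseline mean + ``k_sd`` ×
    baseline SD for ``sustain`` consecutive frames, returned relative to
    ``t_stress``; None when the signal never leaves baseline.  A zero
    baseline SD is replaced by the absolute floor ``sd_floor`` (µM).
    """
    t, v = series.times, series.values
    pre = t < series.t_stress
    if baseline_window is not None:
        pre &= t >= series.t_stress - baseline_window
    if np.sum(pre) < 3:
        raise ValueError("baseline window must contain >= 3 pre-stress points")
    mu = float(np.mean(v[pre]))
    sd = float(np.std(v[pre], ddof=1))
    sd = max(sd, sd_floor)
    thresh = mu + k_sd * sd

    post = np.flatnonzero(t >= series.t_stress)
    above = v[post] > thresh
    run = 0
    for j, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            first = post[j - sustain + 1]
            return float(t[first] - series.t_stress)
    return None


def _band_slope(t: np.ndarray, v: np.ndarray, flank: str) -> float:
    if t.size < 2:
        raise BandTooNarrowError(
            f"fewer than 2 samples in the 10-90% band on the {flank} flank; "
            "sample the wave more finely"
        )
    return float(np.polyfit(t, v, 1)[0])


def production_and_decay_rates(
    series: ConcentrationSeries,
    band: tuple[float, float] = (0.10, 0.90),
) -> tuple[float, float]:
    """Initial production and decay rates of the wave, in µM/h.

    Production: least-squares slope through the rising-flank samples whose
    amplitude lies between 10 % and 90 % of the peak amplitude.  Decay: the
    absolute slope over the same band on the falling flank, truncated at
    the record end when the wave never relaxes back to 10 % (slowly
    decaying, heat-like waves).
    """
    t, v = series.times, series.values
    base = _baseline(series)
    pk_time, amp = peak(series)
    if amp <= 0:
        raise ValueError("no wave above baseline")
    lo, hi = base + band[0] * amp, base + band[1] * amp
    k = int(np.argmin(np.abs(t - pk_time)))

    # rising flank: walk back from the peak until the signal drops below lo
    i0 = k
    while i0 > 0 and v[i0 - 1] >= lo and t[i0 - 1] >= series.t_stress:
        i0 -= 1
    rise = slice(i0, k + 1)
    m_rise = (v[rise] >= lo) & (v[rise] <= hi)
    prod = _band_slope(t[rise][m_rise], v[rise][m_rise], "rising") * 60.0

    # falling flank: ends where the wave drops below the band, the record
    # ends, or the curve rebounds >5% of the amplitude above its running
    # minimum (a secondary burst is a new wave, not part of the decay)
    i1 = k
    i = k
    while i < t.size - 1:
        i += 1
        if v[i] < v[i1]:
            i1 = i
        if v[i] < lo or v[i] > v[i1] + 0.05 * amp:
            break
    fall = slice(k, i1 + 1)
    m_fall = (v[fall] >= lo) & (v[fall] <= hi)
    dec = abs(_band_slope(t[fall][m_fall], v[fall][m_fall], "falling")) * 60.0
    return max(prod, 0.0), dec


def rate_curve(
    series: ConcentrationSeries, step: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Production-rate curve: central-difference derivative at every
    ``step``-minute time point, in µM/h.

    Values at step multiples are obtained by linear interpolation of the
    series; the derivative at each point uses its ±step neighbours
    (one-sided at the record edges).
    """
    t, v = series.times, series.values
    if t[-1] - t[0] < 2 * step:
        raise ValueError("series must span at least two steps")
    grid = np.arange(np.ceil(t[0] / step) * step, t[-1] + 1e-9, step)
    vals = np.interp(grid, t, v)
    rates = np.gradient(vals, grid) * 60.0
    return grid, rates


def sa_wave_velocity(distance_cm: float, onset_min: float | None) -> float:
    """SA wave velocity: stress-site distance over mean SA onset time.

    Reported in cm/min rounded to 3 decimals.  An absent onset (e.g.
    wounding, which triggers no SA) has no defined velocity.
    """
    if onset_min is None:
        raise UndefinedVelocityError("no SA onset detected; velocity undefined")
    if distance_cm <= 0 or onset_min <= 0:
        raise ValueError("distance and onset time must be > 0")
    return round(distance_cm / onset_min, 3)


def ros_front_velocity(
    cmap: "ConcentrationMap",
    stress_site: tuple[int, int],
    threshold_uM: float | None = None,
    bin_width_cm: float = 0.05,
    interpolate: bool = True,
    arrival_smooth: int = 5,
    threshold_fractions: Sequence[float] = (0.2, 0.3, 0.4, 0.5, 0.6),
) -> float:
    """ROS wave front velocity from arrival-time tracking, in cm/min.

    Pixels are binned by Euclidean distance from the stress site; a
    bin's arrival time at a crossing level is when its median
    concentration — lightly smoothed in time over ``arrival_smooth``
    frames — first crosses that level, located by linear interpolation
    between frames (first-frame quantisation with
    ``interpolate=False``).  For each level, the front slowness (min/cm)
    is the slope of the arrival-time-vs-distance regression; regressing
    time on distance keeps the arrival noise off the regressor.  By
    default the slowness is averaged over crossing levels at
    ``threshold_fractions`` of the robust spatial peak (99th
    percentile), so different parts of the rising flank contribute
    independent arrival estimates; passing ``threshold_uM`` uses that
    single level instead.  The velocity (1/slowness) is rounded to 3
    decimals.
    """
    maps = np.asarray(cmap.maps)
    times = np.asarray(cmap.times, dtype=float)
    valid = np.isfinite(maps[0])
    if threshold_uM is not None:
        levels = [float(threshold_uM)]
    else:
        peak_c = float(np.nanpercentile(maps, 99.0))
        levels = [f * peak_c for f in threshold_fractions]
    if min(levels) <= 0:
        raise ValueError("threshold must be > 0")

    rr, cc = np.nonzero(valid)
    dist = np.hypot(rr - stress_site[0], cc - stress_site[1]) * cmap.pixel_size
    bins = np.floor(dist / bin_width_cm).astype(int)

    medians = {}
    for b in np.unique(bins):
        sel = bins == b
        med = np.median(maps[:, rr[sel], cc[sel]], axis=1)
        if arrival_smooth > 1:
            med = (
                pd.Series(med)
                .rolling(arrival_smooth, center=True, min_periods=1)
                .mean()
                .to_numpy()
            )
        medians[b] = med

    slownesses = []
    n_best = 0
    for level in levels:
        d_list, t_list = [], []
        for b, med in medians.items():
            above = np.flatnonzero(med >= level)
            if above.size == 0:
                continue
            i = above[0]
            if interpolate and i > 0:
                t_arr = _cross_time(times[i - 1], med[i - 1], times[i], med[i], level)
            else:
                t_arr = times[i]
            d_list.append((b + 0.5) * bin_width_cm)
            t_list.append(t_arr)
        n_best = max(n_best, len(d_list))
        if len(d_list) < 3:
            continue
        slope = np.polyfit(d_list, t_list, 1)[0]
        if slope > 0:
            slownesses.append(slope)

    if not slownesses:
        raise InsufficientFrontError(
            f"no crossing level yielded >= 3 distance bins with increasing "
            f"arrival times (best: {n_best} bins)"
        )
    return round(float(1.0 / np.mean(slownesses)), 3)


def extract_features(
    series: ConcentrationSeries,
    distance_cm: float | None = None,
    **onset_kwargs,
) -> WaveFeatures:
    """All scalar features of one concentration series.

    Degenerate waves yield None for the affected features rather than
    raising, so feature tables can be assembled across mixed
    experiments: a peak that does not clear the baseline-variability
    threshold used for onset detection (k_sd × max(baseline SD, floor))
    counts as no wave at all, and one-sided waves have no FWHM.
    """
    onset = None
    try:
        onset = onset_time(series, **onset_kwargs)
    except ValueError:
        pass
    pre = series.times < series.t_stress
    k_sd = onset_kwargs.get("k_sd", 1.0)
    floor = onset_kwargs.get("sd_floor", DEFAULT_SD_FLOOR_UM)
    if pre.sum() >= 3:
        floor = max(floor, float(np.std(series.values[pre], ddof=1)))
    try:
        pk_time, amp = peak(series)
        if amp <= k_sd * floor:
            raise ValueError
    except ValueError:
        return WaveFeatures(onset_time=onset)
    try:
        width = fwhm(series)
    except (OneSidedWaveError, ValueError):
        width = None
    try:
        prod, dec = production_and_decay_rates(series)
    except (BandTooNarrowError, ValueError):
        prod = dec = None
    vel = None
    if distance_cm is not None and onset is not None and onset > 0:
        vel = sa_wave_velocity(distance_cm, onset)
    return WaveFeatures(
        peak_time=pk_time,
        peak_value=amp,
        fwhm=width,
        production_rate=prod,
        decay_rate=dec,
        onset_time=onset,
        velocity=vel,
    )


def features_to_csv(
    rows: dict[str, WaveFeatures], path: str | Path
) -> pd.DataFrame:
    """Write one CSV row per experiment (label -> features); returns the frame."""
    recs = []
    for label, f in rows.items():
        recs.append(
            {
                "stress_label": label,
                "peak_time_min": f.peak_time,
                "peak_uM": f.peak_value,
                "fwhm_min": f.fwhm,
                "production_uM_per_h": f.production_rate,
                "decay_uM_per_h": f.decay_rate,
                "onset_min": f.onset_time,
                "velocity_cm_per_min": f.velocity,
            }
        )
    df = pd.DataFrame(recs)
    df.to_csv(path, index=False)
    return df
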