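"""From raw nIR frame stacks to calibrated concentration series and maps.

The measurement is ratiometric: each leaf carries an *active* sensor
spot (SA or H₂O₂) and a co-infiltrated *reference* spot whose
fluorescence does not respond to the analytes.  Dividing the active
signal (normalised to its pre-stress mean) by the equally normalised
reference signal cancels multiplicative artefacts — laser power drift
and leaf movement — that hit both spots alike.  The resulting quench
fraction r(t) = 1 − R(t) is smoothed with a centred moving average and
inverted through the sensor's Langmuir calibration to concentration.

Two pathways are provided: per-ROI scalar series (with the paper-style
options of averaging the whole mask or the 200 most-quenched pixels)
and pixel-wise concentration maps, each pixel normalised to its own
pre-stress mean and divided by the reference ROI's scalar drift series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationCurve, invert_response
from .wave_features import ConcentrationSeries

__all__ = [
    "FrameStack",
    "RoiSet",
    "ConcentrationMap",
    "roi_intensity_series",
    "ratiometric_series",
    "series_to_concentration",
    "concentration_map",
    "moving_average",
]

ROI_LABELS = ("sa", "h2o2", "reference")
TOP_QUENCH_PIXELS = 200  # paper-style subset size for the H₂O₂ sensor ROI


@dataclass(frozen=True)
class FrameStack:
    """Timestamped 2-D intensity frames with physical pixel size."""

    times: np.ndarray  # minutes, strictly increasing
    frames: np.ndarray  # (T, H, W) intensities >= 0
    pixel_size: float  # cm per pixel
    t_stress: float  # minutes

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3 or f.shape[0] != t.size:
            raise ValueError("frames must be (T, H, W) matching times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def save(self, prefix: str | Path) -> None:
        """Write multi-page TIFF + sidecar JSON (<prefix>.tif / .json)."""
        prefix = Path(prefix)
        tifffile.imwrite(prefix.with_suffix(".tif"), self.frames.astype(np.float32))
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {
                    "times_min": self.times.tolist(),
                    "pixel_size_cm": self.pixel_size,
                    "t_stress_min": self.t_stress,
                }
            )
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "FrameStack":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        frames = tifffile.imread(prefix.with_suffix(".tif"))
        return cls(
            times=np.asarray(meta["times_min"]),
            frames=frames,
            pixel_size=meta["pixel_size_cm"],
            t_stress=meta["t_stress_min"],
        )


@dataclass(frozen=True)
class RoiSet:
    """Named boolean sensor-spot masks plus the stress-site pixel."""

    masks: dict[str, np.ndarray]  # label -> (H, W) bool
    stress_site: tuple[int, int]  # (row, col), 0-based

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one shape")
        for label, m in self.masks.items():
            if not np.any(m):
                raise ValueError(f"mask '{label}' is empty")
        labels = list(self.masks)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"masks '{a}' and '{b}' overlap")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, m in self.masks.items():
            tifffile.imwrite(directory / f"roi_{label}.tif", m.astype(np.uint8) * 255)
        (directory / "stress_site.json").write_text(
            json.dumps({"row": self.stress_site[0], "col": self.stress_site[1]})
        )

    @classmethod
    def load(cls, directory: str | Path) -> "RoiSet":
        directory = Path(directory)
        masks = {
            p.stem.removeprefix("roi_"): tifffile.imread(p) > 0
            for p in sorted(directory.glob("roi_*.tif"))
        }
        site = json.loads((directory / "stress_site.json").read_text())
        return cls(masks=masks, stress_site=(site["row"], site["col"]))


@dataclass(frozen=True)
class ConcentrationMap:
    """Pixel-wise concentration fields (µM), NaN outside sensor ROIs."""

    times: np.ndarray
    maps: np.ndarray  # (T, H, W), µM
    pixel_size: float
    saturated_pixel_count: np.ndarray  # per frame

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        tifffile.imwrite(prefix.with_suffix(".tif"), self.maps.astype(np.float32))
        pd.DataFrame(
            {
                "time_min": self.times,
                "mean_uM": np.nanmean(self.maps, axis=(1, 2)),
                "max_uM": np.nanmax(self.maps, axis=(1, 2)),
                "saturated_pixels": self.saturated_pixel_count,
            }
        ).to_csv(prefix.with_suffix(".csv"), index=False)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with windows that shrink at the edges.

    Interior points average ``window`` samples; near the record ends the
    window is truncated symmetrically, so a constant signal is preserved
    exactly everywhere.
    """
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def roi_intensity_series(
    stack: FrameStack,
    rois: RoiSet,
    label: str,
    mode: str = "mean",
    n_top: int = TOP_QUENCH_PIXELS,
) -> np.ndarray:
    """Per-frame raw intensity of one sensor ROI.

    ``mode="mean"`` averages the whole mask each frame (SA and reference
    sensors).  ``mode="top-quench"`` first ranks pixels by their total
    first-to-last intensity drop and averages the ``n_top`` most-quenched
    pixels, the subset being fixed over the whole record so the series
    tracks one coherent region (H₂O₂ sensor).  ROIs smaller than
    ``n_top`` fall back to all pixels with a warning.
    """
    if label not in rois.masks:
        raise KeyError(f"no ROI named '{label}'")
    mask = rois.masks[label]
    pix = stack.frames[:, mask]  # (T, N)
    if pix.shape[1] == 0:
        raise ValueError(f"mask '{label}' is empty")

    if mode == "mean":
        return pix.mean(axis=1)
    if mode == "top-quench":
        if pix.shape[1] < n_top:
            warnings.warn(
                f"ROI '{label}' has {pix.shape[1]} < {n_top} pixels; using all",
                stacklevel=2,
            )
            n_top = pix.shape[1]
        quench = pix[0] - pix[-1]  # total drop over the record
        order = np.argsort(quench)[::-1][:n_top]
        return pix[:, order].mean(axis=1)
    raise ValueError(f"unknown mode '{mode}' (use 'mean' or 'top-quench')")


def ratiometric_series(
    active: np.ndarray,
    reference: np.ndarray,
    times: np.ndarray,
    t_stress: float,
    window: int = 10,
) -> np.ndarray:
    """Drift-cancelled quench fraction r(t) from active/reference intensities.

    R(t) = (I_act / mean pre-stress I_act) / (I_ref / mean pre-stress
    I_ref); r(t) = 1 − R(t), then a centred ``window``-point moving
    average.  Any multiplicative factor common to both channels cancels
    exactly.  Requires >= 3 pre-stress frames to define the baseline.
    """
    active = np.asarray(active, dtype=float)
    reference = np.asarray(reference, dtype=float)
    times = np.asarray(times, dtype=float)
    if active.shape != reference.shape or active.shape != times.shape:
        raise ValueError("active, reference and times must have equal length")
    bad = np.flatnonzero(reference == 0)
    if bad.size:
        raise ValueError(f"zero reference intensity at frames {bad.tolist()[:10]}")
    pre = times < t_stress
    if np.sum(pre) < 3:
        raise ValueError("need >= 3 pre-stress frames for the baseline")
    ratio = (active / active[pre].mean()) / (reference / reference[pre].mean())
    return moving_average(1.0 - ratio, window)


def series_to_concentration(
    quench: np.ndarray,
    times: np.ndarray,
    curve: CalibrationCurve,
    t_stress: float,
    replicate_count: int = 1,
    saturation_ceiling: float | None = None,
    diagnostics: dict | None = None,
) -> ConcentrationSeries:
    """Invert a quench series through a calibration curve, point-wise.

    Negative quench values (baseline jitter) clip to 0 µM; saturated
    values (r >= r_max) are set to ``saturation_ceiling`` (default
    10·K_D).  Both event counts accumulate in ``diagnostics`` under
    ``"clipped"`` and ``"saturated"`` — never silently.
    """
    q = np.asarray(quench, dtype=float)
    if saturation_ceiling is None:
        saturation_ceiling = 10.0 * curve.kd
    diagnostics = diagnostics if diagnostics is not None else {}

    sat = q >= curve.r_max
    if np.any(sat):
        diagnostics["saturated"] = diagnostics.get("saturated", 0) + int(sat.sum())
    safe = np.where(sat, 0.0, q)
    conc = np.asarray(invert_response(curve, safe, clip_counter=diagnostics))
    conc[sat] = saturation_ceiling
    return ConcentrationSeries(
        times=np.asarray(times, dtype=float),
        values=conc,
        t_stress=t_stress,
        replicate_count=replicate_count,
        label=curve.analyte,
    )


def concentration_map(
    stack: FrameStack,
    rois: RoiSet,
    curves: Mapping[str, CalibrationCurve],
    window: int = 10,
    saturation_ceiling_factor: float = 10.0,
) -> ConcentrationMap:
    """Pixel-wise concentration fields for every calibrated sensor ROI.

    Each ROI pixel is normalised to its own pre-stress mean and divided
    by the reference ROI's scalar drift series (reference and active
    spots are spatially separate, so no per-pixel reference exists); the
    resulting quench is smoothed in time and inverted through the ROI
    label's calibration curve.  Pixels outside calibrated ROIs are NaN.
    """
    if "reference" not in rois.masks:
        raise ValueError("a 'reference' ROI is required for ratiometric maps")
    ref = roi_intensity_series(stack, rois, "reference", mode="mean")
    if np.any(ref == 0):
        raise ValueError("zero reference intensity")
    pre = stack.times < stack.t_stress
    if pre.sum() < 3:
        raise ValueError("need >= 3 pre-stress frames")
    ref_norm = ref / ref[pre].mean()

    T = stack.times.size
    out = np.full(stack.frames.shape, np.nan, dtype=float)
    saturated = np.zeros(T, dtype=int)

    for label, curve in curves.items():
        if label not in rois.masks:
            raise KeyError(f"calibration given for unknown ROI '{label}'")
        mask = rois.masks[label]
        pix = stack.frames[:, mask]  # (T, N)
        base = pix[pre].mean(axis=0)
        if np.any(base == 0):
            raise ValueError(f"zero pre-stress intensity in ROI '{label}'")
        q = 1.0 - (pix / base) / ref_norm[:, None]
        q = np.apply_along_axis(moving_average, 0, q, window)

        ceiling = saturation_ceiling_factor * curve.kd
        sat = q >= curve.r_max
        saturated += sat.sum(axis=1)
        safe = np.where(sat, 0.0, np.clip(q, 0.0, None))
        conc = np.asarray(invert_response(curve, safe))
        conc[sat] = ceiling
        out[:, mask] = conc

    return ConcentrationMap(
        times=stack.times,
        maps=out,
        pixel_size=stack.pixel_size,
        saturated_pixel_count=saturated,
    )


def roi_concentration_series(
    stack: FrameStack,
    rois: RoiSet,
    label: str,
    curve: CalibrationCurve,
    mode: str = "mean",
    window: int = 10,
    diagnostics: dict | None = None,
) -> ConcentrationSeries:
    """Convenience pipeline: ROI intensity -> ratiometric quench -> µM."""
    act = roi_intensity_series(stack, rois, label, mode=mode)
    ref = roi_intensity_series(stack, rois, "reference", mode="mean")
    q = ratiometric_series(act, ref, stack.times, stack.t_stress, window=window)
    return series_to_concentration(
        q, stack.times, curve, stack.t_stress, diagnostics=diagnostics
    )
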