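"""Langmuir calibration of nanosensor fluorescence response.

A corona-phase SWNT sensor responds to its analyte with a saturating
fractional fluorescence change described by the Langmuir adsorption
isotherm

    r(c) = r_max * c / (K_D + c)

where ``c`` is the analyte concentration (µM), ``K_D`` the dissociation
constant (µM, the concentration at half-maximal response) and ``r_max``
the fractional response at saturation.  Throughout this package responses
are stored as *signed fractions with quenching positive*: a sensor that
loses 35 % of its intensity has r = 0.35, a turn-on sensor has r < 0.

The module fits the isotherm to titration data, inverts it to convert
quench fractions back to concentrations, derives the limit of detection
(smallest concentration whose response clears three times the noise SD),
and classifies analyte-screen response tables against the ±20 % hit
threshold used during sensor selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "TitrationData",
    "CalibrationCurve",
    "ScreenTable",
    "LangmuirFitError",
    "SaturationError",
    "fit_langmuir",
    "response_at",
    "invert_response",
    "estimate_lod",
    "classify_screen",
]


class LangmuirFitError(RuntimeError):
    """Raised when the Langmuir fit cannot converge or is unidentifiable."""


class SaturationError(ValueError):
    """Raised when a response at or above r_max is inverted: concentration
    is unbounded there and the sensor carries no information."""


@dataclass(frozen=True)
class TitrationData:
    """One sensor/analyte titration: fractional response vs concentration."""

    analyte: str
    concentrations: np.ndarray  # µM, strictly increasing
    responses: np.ndarray  # fractional, quench positive
    response_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        if c.ndim != 1 or r.shape != c.shape:
            raise ValueError("concentrations and responses must be 1-D and equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing (hence unique)")
        if self.response_sd is not None:
            sd = np.asarray(self.response_sd, dtype=float)
            if sd.shape != c.shape or np.any(sd < 0):
                raise ValueError("response_sd must match length and be >= 0")
            object.__setattr__(self, "response_sd", sd)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TitrationData":
        df = pd.read_csv(path)
        sd = df["response_sd"].to_numpy() if "response_sd" in df.columns else None
        return cls(
            analyte=str(df["analyte"].iloc[0]),
            concentrations=df["concentration_uM"].to_numpy(),
            responses=df["response"].to_numpy(),
            response_sd=sd,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "analyte": self.analyte,
                "concentration_uM": self.concentrations,
                "response": self.responses,
            }
        )
        if self.response_sd is not None:
            df["response_sd"] = self.response_sd
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted Langmuir parameters for one sensor/analyte pair.

    Attributes
    ----------
    kd:
        Dissociation constant K_D in µM (> 0).
    r_max:
        Maximal fractional quench at saturation, in (0, 1].
    fit_r:
        Pearson correlation between fitted and observed responses.
    lod:
        Limit of detection in µM (three-sigma criterion), if computed.
    """

    analyte: str
    kd: float
    r_max: float
    fit_r: float | None = None
    lod: float | None = None

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be > 0")
        if not (0 < self.r_max <= 1):
            raise ValueError("r_max must be in (0, 1]")
        if self.lod is not None and self.lod < 0:
            raise ValueError("lod must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "analyte": self.analyte,
                    "kd_uM": self.kd,
                    "r_max": self.r_max,
                    "fit_r": self.fit_r,
                    "lod_uM": self.lod,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            analyte=d["analyte"],
            kd=d["kd_uM"],
            r_max=d["r_max"],
            fit_r=d.get("fit_r"),
            lod=d.get("lod_uM"),
        )


@dataclass(frozen=True)
class ScreenTable:
    """Signed fractional responses of a sensor panel to an analyte panel."""

    sensors: list[str]
    analytes: list[str]
    responses: np.ndarray  # |sensors| x |analytes|

    def __post_init__(self) -> None:
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", r)
        if r.shape != (len(self.sensors), len(self.analytes)):
            raise ValueError("responses matrix must be |sensors| x |analytes|")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScreenTable":
        df = pd.read_csv(path)
        pivot = df.pivot(index="sensor", columns="analyte", values="response")
        return cls(
            sensors=list(pivot.index),
            analytes=list(pivot.columns),
            responses=pivot.to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"sensor": s, "analyte": a, "response": self.responses[i, j]}
            for i, s in enumerate(self.sensors)
            for j, a in enumerate(self.analytes)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _langmuir(c: np.ndarray, kd: float, r_max: float) -> np.ndarray:
    return r_max * c / (kd + c)


def fit_langmuir(data: TitrationData) -> CalibrationCurve:
    """Fit the Langmuir isotherm to titration data by bounded least squares.

    K_D is searched over (1e-3, 1e5) µM and r_max over (1e-3, 1] from ten
    log-spaced K_D starting points; the best solution by squared error wins.
    Returns the fitted :class:`CalibrationCurve` with the Pearson correlation
    of fitted vs observed responses.

    Raises
    ------
    ValueError
        If fewer than 4 titration points are supplied.
    LangmuirFitError
        If no start converges, or the response carries no signal
        (e.g. all-zero responses, where r_max is unidentifiable).
    """
    c, r = data.concentrations, data.responses
    if c.size < 4:
        raise ValueError("Langmuir fit needs at least 4 titration points")
    if np.allclose(r, 0):
        raise LangmuirFitError("all responses are zero; r_max is unidentifiable")

    lo, hi = (1e-3, 1e-3), (1e5, 1.0)
    best = None
    for kd0 in np.geomspace(1e-2, 1e4, 10):
        r_max0 = float(np.clip(np.max(np.abs(r)), 1e-2, 1.0))
        try:
            sol = least_squares(
                lambda p: _langmuir(c, p[0], p[1]) - r,
                x0=[kd0, r_max0],
                bounds=(lo, hi),
                method="trf",
            )
        except Exception:  # pragma: no cover - solver-internal failures
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise LangmuirFitError("Langmuir fit failed to converge from any start")

    kd, r_max = float(best.x[0]), float(best.x[1])
    fitted = _langmuir(c, kd, r_max)
    with np.errstate(invalid="ignore"):
        fit_r = float(np.corrcoef(fitted, r)[0, 1]) if np.std(fitted) > 0 else 0.0
    return CalibrationCurve(analyte=data.analyte, kd=kd, r_max=r_max, fit_r=fit_r)


def response_at(curve: CalibrationCurve, c: float | np.ndarray) -> float | np.ndarray:
    """Fractional response predicted at concentration ``c`` (µM, >= 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = _langmuir(c, curve.kd, curve.r_max)
    return float(out) if out.ndim == 0 else out


def invert_response(
    curve: CalibrationCurve,
    r: float | np.ndarray,
    *,
    clip_counter: dict | None = None,
) -> float | np.ndarray:
    """Concentration (µM) whose Langmuir response equals ``r``.

    Exact inverse c = K_D * r / (r_max - r).  Negative responses (baseline
    jitter read as turn-on) are clipped to concentration 0; the number of
    clipped entries is added to ``clip_counter['clipped']`` when a dict is
    given, so pipelines can report how often it happened.

    Raises
    ------
    SaturationError
        If any response reaches or exceeds r_max.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr >= curve.r_max):
        raise SaturationError(
            f"response >= r_max ({curve.r_max:.4g}); sensor saturated, "
            "concentration unbounded"
        )
    n_neg = int(np.sum(arr < 0))
    if n_neg:
        if clip_counter is not None:
            clip_counter["clipped"] = clip_counter.get("clipped", 0) + n_neg
        else:
            warnings.warn(f"{n_neg} negative response(s) clipped to 0 µM", stacklevel=2)
    clipped = np.clip(arr, 0.0, None)
    out = curve.kd * clipped / (curve.r_max - clipped)
    return float(out) if out.ndim == 0 else out


def estimate_lod(curve: CalibrationCurve, noise_sd: float) -> float:
    """Limit of detection: smallest c with response >= 3 * noise_sd.

    With a monotone isotherm this is exactly ``invert_response(3*noise_sd)``.
    ``noise_sd`` is the standard deviation of the fractional response of a
    blank, so 3*noise_sd is the signal-to-noise >= 3 criterion.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    target = 3.0 * noise_sd
    if target >= curve.r_max * (1.0 - 1e-9):
        raise SaturationError("3*noise_sd reaches r_max; LOD undefined")
    return float(invert_response(curve, target))


def noise_floor_concentration(curve: CalibrationCurve, frac: float = 0.005) -> float:
    """Concentration equivalent of a small quench fraction of saturation.

    Used as the absolute noise floor when a baseline's standard deviation
    is (near) zero: ``frac`` of r_max mapped through the curve's inverse,
    i.e. the smallest concentration this sensor can meaningfully resolve
    against residual quench jitter of that size.
    """
    return float(invert_response(curve, frac * curve.r_max))


def classify_screen(table: ScreenTable, threshold: float = 0.20) -> np.ndarray:
    """Classify each sensor x analyte response against the hit threshold.

    Returns an object array of the same shape with entries ``"quench-hit"``
    (r >= threshold), ``"turn-on-hit"`` (r <= -threshold) or ``"inert"``.
    The boundary |r| == threshold counts as a hit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    r = table.responses
    out = np.full(r.shape, "inert", dtype=object)
    out[r >= threshold] = "quench-hit"
    out[r <= -threshold] = "turn-on-hit"
    return out
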