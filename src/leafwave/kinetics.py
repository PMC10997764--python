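"""Mass-action model of stress-triggered H₂O₂ and SA signalling.

The network couples an autocatalytic, self-limiting H₂O₂ burst to a
delayed salicylic-acid release through a linear chain of biosynthetic
intermediates, with a generic inhibitor branch that deactivates the
first intermediate's precursor:

    A + P  --k-->   A + A        autocatalytic H₂O₂ production (RBOH pool P)
    A      --kd-->  B            H₂O₂ decay to product B
    A + pF --kf1--> F1           activation of the SA precursor chain
    F1 --> F2 --> ... --> Fn --ks--> S    intermediate chain releasing SA
    A + pI --ki-->  I            inhibitor production
    I + pF --kr-->  xF1          deactivation of pF (xF1 is inert)

Species names: A = H₂O₂, P = precursor pool, B = degradation product,
pF / pI = precursor pools of the chain and the inhibitor, F1..Fn =
biosynthetic intermediates, S = salicylic acid, I = inhibitor, xF1 =
deactivated precursor.  Concentrations are µM, time is minutes, all
bimolecular rates 1/(µM·min) and unimolecular rates 1/min.

A stress at ``t_stress`` seeds A with ``a0`` µM; an optional secondary
burst re-injects ``p2`` µM of P at ``t2`` (the impulse model of the
later ROS bursts seen under high light and high heat).  Integration is
piecewise across both discontinuities with a stiff-capable solver.

Three exact stoichiometric conservation laws follow from the network and
are used as an integration audit (:func:`conservation_check`):

    (i)   A + B + ΣF + S + I + xF1  =  a0 + (P_injected − P)
    (ii)  pF + ΣF + S + xF1         =  pf0
    (iii) pI + I + xF1              =  pi0
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .wave_features import ConcentrationSeries

__all__ = [
    "KineticParams",
    "KineticTrajectory",
    "FitResult",
    "IntegrationError",
    "simulate",
    "conservation_check",
    "fit_kinetic_model",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails on a valid parameter set."""


_RATE_NAMES = ("k", "kd", "kf1", "ks", "ki", "kr")
_POOL_NAMES = ("a0", "p0", "pf0", "pi0")


@dataclass(frozen=True)
class KineticParams:
    """Rate constants, pools and timing of one stress simulation.

    ``kf_chain`` holds the intra-chain rates k_F2..k_Fn (length
    ``n_intermediates - 1``); the terminal Fn -> S rate is ``ks``.
    ``t2``/``p2`` configure the optional secondary precursor injection.
    """

    k: float = 0.01  # 1/(µM·min) autocatalysis
    kd: float = 0.1  # 1/min H₂O₂ decay
    kf1: float = 0.0  # 1/(µM·min) chain activation
    kf_chain: tuple[float, ...] = (0.05, 0.05)  # 1/min, k_F2..k_Fn
    ks: float = 0.05  # 1/min terminal SA release
    ki: float = 0.0  # 1/(µM·min) inhibitor production
    kr: float = 0.0  # 1/(µM·min) pF deactivation
    n_intermediates: int = 3
    a0: float = 1.0  # µM H₂O₂ seed at stress
    p0: float = 20.0  # µM precursor pool
    pf0: float = 0.0  # µM chain precursor pool
    pi0: float = 0.0  # µM inhibitor precursor pool
    t_stress: float = 10.0  # min
    t2: float | None = None  # min, secondary burst
    p2: float | None = None  # µM, secondary injection

    def __post_init__(self) -> None:
        for name in _RATE_NAMES + _POOL_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(r < 0 for r in self.kf_chain):
            raise ValueError("chain rates must be >= 0")
        if self.n_intermediates < 1:
            raise ValueError("n_intermediates must be >= 1")
        if len(self.kf_chain) != self.n_intermediates - 1:
            raise ValueError("need n_intermediates - 1 chain rates")
        if self.t2 is not None and self.t2 <= self.t_stress:
            raise ValueError("t2 must be after t_stress")
        if (self.t2 is None) != (self.p2 is None):
            raise ValueError("t2 and p2 must be given together")

    @property
    def species_names(self) -> list[str]:
        n = self.n_intermediates
        return (
            ["A", "P", "B", "pF"]
            + [f"F{i}" for i in range(1, n + 1)]
            + ["S", "pI", "I", "xF1"]
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["kf_chain"] = list(self.kf_chain)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParams":
        d = dict(d)
        if "kf_chain" in d:
            d["kf_chain"] = tuple(d["kf_chain"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class KineticTrajectory:
    """Integrated species time courses on a user time grid (µM vs min)."""

    times: np.ndarray
    species: dict[str, np.ndarray]
    params: KineticParams

    @property
    def h2o2(self) -> np.ndarray:
        return self.species["A"]

    @property
    def sa(self) -> np.ndarray:
        return self.species["S"]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_min": self.times, **self.species})
        df.to_csv(path, index=False)


def _rhs(t: float, y: np.ndarray, p: KineticParams) -> np.ndarray:
    n = p.n_intermediates
    A, P, B, pF = y[0], y[1], y[2], y[3]
    F = y[4 : 4 + n]
    pI, I = y[5 + n], y[6 + n]

    dy = np.zeros_like(y)
    auto = p.k * A * P
    act = p.kf1 * A * pF
    inh = p.ki * A * pI
    deact = p.kr * I * pF

    dy[0] = auto - p.kd * A - act - inh  # A
    dy[1] = -auto  # P
    dy[2] = p.kd * A  # B
    dy[3] = -act - deact  # pF
    # chain: out-rate of F_j is kf_chain[j-1] for j < n, ks for j = n
    out_rates = list(p.kf_chain) + [p.ks]
    dy[4] = act - out_rates[0] * F[0]
    for j in range(1, n):
        dy[4 + j] = out_rates[j - 1] * F[j - 1] - out_rates[j] * F[j]
    dy[4 + n] = p.ks * F[n - 1]  # S
    dy[5 + n] = -inh  # pI
    dy[6 + n] = inh - deact  # I
    dy[7 + n] = deact  # xF1
    return dy


def simulate(
    params: KineticParams,
    t_grid: Sequence[float],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> KineticTrajectory:
    """Integrate the network and sample it on ``t_grid`` (minutes).

    Before ``t_stress`` every species sits at its initial pool (A = 0);
    at ``t_stress`` A jumps to ``a0`` and mass-action dynamics start.  A
    secondary burst, when configured, adds ``p2`` to P at ``t2`` with the
    integration restarted at the discontinuity.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")
    if t[-1] < params.t_stress:
        raise ValueError("t_grid must cover t_stress")

    n = params.n_intermediates
    n_sp = 8 + n
    names = params.species_names
    out = np.zeros((n_sp, t.size))

    # resting state before the stress
    y0 = np.zeros(n_sp)
    y0[1], y0[3], y0[5 + n] = params.p0, params.pf0, params.pi0
    pre = t < params.t_stress
    out[:, pre] = y0[:, None]

    y = y0.copy()
    y[0] = params.a0
    breaks = [params.t_stress]
    if params.t2 is not None and params.t2 < t[-1]:
        breaks.append(params.t2)
    breaks.append(t[-1])

    for t_lo, t_hi in zip(breaks[:-1], breaks[1:]):
        sel = (t >= t_lo) & (t <= t_hi) & ~pre
        t_eval = np.unique(np.concatenate([[t_lo], t[sel], [t_hi]]))
        sol = solve_ivp(
            _rhs,
            (t_lo, t_hi),
            y,
            args=(params,),
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{t_lo}, {t_hi}]: {sol.message}")
        # map evaluated points back onto the requested grid
        idx = np.searchsorted(sol.t, t[sel])
        out[:, sel] = sol.y[:, idx]
        y = sol.y[:, -1].copy()
        if params.t2 is not None and np.isclose(t_hi, params.t2):
            y[1] += params.p2

    species = {name: out[i] for i, name in enumerate(names)}
    return KineticTrajectory(times=t, species=species, params=params)


def conservation_check(traj: KineticTrajectory) -> dict[str, float]:
    """Maximum absolute drift of the three stoichiometric conservation laws.

    Returns a dict with keys ``"a_units"``, ``"pf_units"``, ``"pi_units"``,
    each the max |drift| in µM over the trajectory.  The A-unit law accounts
    for the stress seed and any secondary injection only at times where they
    have occurred.
    """
    p = traj.params
    t = traj.times
    sp = traj.species
    F_sum = sum(sp[f"F{i}"] for i in range(1, p.n_intermediates + 1))

    seeded = (t >= p.t_stress).astype(float)
    injected = p.p0 * np.ones_like(t)
    if p.t2 is not None:
        injected = injected + p.p2 * (t >= p.t2)
    lhs_a = sp["A"] + sp["B"] + F_sum + sp["S"] + sp["I"] + sp["xF1"]
    drift_a = lhs_a - (injected - sp["P"]) - p.a0 * seeded

    drift_pf = sp["pF"] + F_sum + sp["S"] + sp["xF1"] - p.pf0
    drift_pi = sp["pI"] + sp["I"] + sp["xF1"] - p.pi0
    return {
        "a_units": float(np.max(np.abs(drift_a))),
        "pf_units": float(np.max(np.abs(drift_pf))),
        "pi_units": float(np.max(np.abs(drift_pi))),
    }


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting the network to observed H₂O₂ and SA series."""

    params: KineticParams
    residual_h2o2: np.ndarray  # model - observed, µM, on the H₂O₂ grid
    residual_sa: np.ndarray
    sse: float
    converged: bool


_FITTABLE = _RATE_NAMES + _POOL_NAMES + ("kf_chain",)


def _pack(params: KineticParams, free: list[str]) -> np.ndarray:
    vals = []
    for name in free:
        v = np.mean(params.kf_chain) if name == "kf_chain" else getattr(params, name)
        vals.append(np.log10(v))
    return np.array(vals)


def _unpack(x: np.ndarray, base: KineticParams, free: list[str]) -> KineticParams:
    updates: dict = {}
    for name, lv in zip(free, x):
        v = float(10.0**lv)
        if name == "kf_chain":
            updates["kf_chain"] = tuple([v] * (base.n_intermediates - 1))
        else:
            updates[name] = v
    return replace(base, **updates)


def fit_kinetic_model(
    h2o2: ConcentrationSeries,
    sa: ConcentrationSeries,
    init: KineticParams,
    frozen: Iterable[str] = (),
    *,
    n_starts: int = 16,
    seed: int = 0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> FitResult:
    """Fit the free rate constants and pools to measured concentration series.

    Minimises ``w_A Σ(A_model−A_obs)² + w_S Σ(S_model−S_obs)²`` with weights
    equal to the inverse squared maximum of each observed series, so the
    µM-scale disparity between the H₂O₂ burst and the SA plateau does not
    let one channel dominate.  Parameters are optimised in log10 space with
    ``n_starts - 1`` Latin-hypercube perturbations (×[0.5, 2]) of ``init``
    in addition to ``init`` itself; ``frozen`` names (including any
    parameter whose initial value is exactly 0, which cannot be log-scaled)
    are held fixed.  ``kf_chain`` is fitted as one shared chain rate.

    Non-convergence of every start returns ``converged=False`` with the
    best parameters found.
    """
    frozen = set(frozen)
    free = [
        name
        for name in _FITTABLE
        if name not in frozen
        and (
            np.mean(init.kf_chain) if name == "kf_chain" else getattr(init, name)
        )
        > 0
    ]
    if not free:
        raise ValueError("no free parameters to fit")

    t_obs = np.union1d(h2o2.times, sa.times)
    i_h = np.searchsorted(t_obs, h2o2.times)
    i_s = np.searchsorted(t_obs, sa.times)
    max_h = float(np.max(np.abs(h2o2.values))) or 1.0
    max_s = float(np.max(np.abs(sa.values))) or 1.0
    w_h, w_s = 1.0 / max_h, 1.0 / max_s

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(x, init, free)
        try:
            traj = simulate(p, t_obs, rtol=rtol, atol=atol)
        except IntegrationError:
            return np.full(i_h.size + i_s.size, 1e3)
        res_h = (traj.h2o2[i_h] - h2o2.values) * w_h
        res_s = (traj.sa[i_s] - sa.values) * w_s
        return np.concatenate([res_h, res_s])

    x0 = _pack(init, free)
    starts = [x0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        # perturbations of init by a factor in [0.5, 2] in log space
        offs = (sampler.random(n_starts - 1) * 2 - 1) * np.log10(2.0)
        starts += [x0 + o for o in offs]

    # bounded in log space: ±3 decades around the initial guess keeps the
    # solver out of pathologically stiff corners of parameter space
    lo, hi = x0 - 3.0, x0 + 3.0
    best, best_cost, converged = None, np.inf, False
    for s in starts:
        try:
            sol = least_squares(
                residuals,
                np.clip(s, lo, hi),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                max_nfev=400,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
            converged = converged or bool(sol.success)

    if best is None:
        p_best = init
        converged = False
    else:
        p_best = _unpack(best.x, init, free)

    traj = simulate(p_best, t_obs, rtol=rtol, atol=atol)
    res_h = traj.h2o2[i_h] - h2o2.values
    res_s = traj.sa[i_s] - sa.values
    sse = float(w_h**2 * np.sum(res_h**2) + w_s**2 * np.sum(res_s**2))
    return FitResult(
        params=p_best,
        residual_h2o2=res_h,
        residual_sa=res_s,
        sse=sse,
        converged=converged,
    )
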