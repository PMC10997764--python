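"""Independent oracles for the test suite.

The reaction network is re-expressed here as an explicit reaction list
(reactants, products, rate constant) from which mass-action derivatives
and stochastic propensities are built generically.  This formulation
shares no code with the package's hand-written ODE right-hand side, so
agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def species_index(n: int) -> dict[str, int]:
    names = ["A", "P", "B", "pF"] + [f"F{i}" for i in range(1, n + 1)] + [
        "S", "pI", "I", "xF1"
    ]
    return {name: i for i, name in enumerate(names)}


def reaction_list(params) -> list[tuple[dict, dict, float]]:
    """(reactants, products, rate) triples of the stress-signalling network."""
    n = params.n_intermediates
    rx = [
        ({"A": 1, "P": 1}, {"A": 2}, params.k),
        ({"A": 1}, {"B": 1}, params.kd),
        ({"A": 1, "pF": 1}, {"F1": 1}, params.kf1),
        ({"A": 1, "pI": 1}, {"I": 1}, params.ki),
        ({"I": 1, "pF": 1}, {"xF1": 1}, params.kr),
    ]
    for j in range(1, n):
        rx.append(({f"F{j}": 1}, {f"F{j+1}": 1}, params.kf_chain[j - 1]))
    rx.append(({f"F{n}": 1}, {"S": 1}, params.ks))
    return rx


def _stoich(params):
    idx = species_index(params.n_intermediates)
    rx = reaction_list(params)
    n_sp = len(idx)
    S = np.zeros((len(rx), n_sp))
    orders = []
    rates = []
    for r, (reac, prod, k) in enumerate(rx):
        for sp, m in reac.items():
            S[r, idx[sp]] -= m
        for sp, m in prod.items():
            S[r, idx[sp]] += m
        orders.append([(idx[sp], m) for sp, m in reac.items()])
        rates.append(k)
    return S, orders, np.array(rates), idx


def mass_action_rhs(params):
    """Derivative function y -> dy/dt built from the reaction list."""
    S, orders, rates, _ = _stoich(params)

    def rhs(y):
        v = rates.copy()
        for r, terms in enumerate(orders):
            for i, m in terms:
                v[r] *= y[i] ** m
        return S.T @ v

    return rhs


def rk4_trajectory(params, y0: np.ndarray, t0: float, t1: float, dt: float):
    """Fixed-step classical Runge-Kutta integration of the network."""
    rhs = mass_action_rhs(params)
    n_steps = int(round((t1 - t0) / dt))
    times = t0 + dt * np.arange(n_steps + 1)
    ys = np.empty((n_steps + 1, y0.size))
    y = y0.astype(float).copy()
    ys[0] = y
    for i in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        ys[i + 1] = y
    return times, ys


def initial_state(params, seeded: bool = True) -> np.ndarray:
    idx = species_index(params.n_intermediates)
    y0 = np.zeros(len(idx))
    y0[idx["P"]] = params.p0
    y0[idx["pF"]] = params.pf0
    y0[idx["pI"]] = params.pi0
    if seeded:
        y0[idx["A"]] = params.a0
    return y0


def gillespie(params, volume: float, t_end: float, rng: np.random.Generator):
    """Exact SSA sample path in molecule counts (volume in 1/µM units).

    Bimolecular propensities scale as k/V; the returned trajectory holds
    (times, counts) per event plus the stoichiometry matrix so callers
    can audit conservation per event.
    """
    S, orders, rates, idx = _stoich(params)
    y = np.round(initial_state(params) * volume).astype(np.int64)
    t = 0.0
    times = [t]
    states = [y.copy()]
    order_tot = [sum(m for _, m in terms) for terms in orders]
    while t < t_end:
        a = rates.copy()
        for r, terms in enumerate(orders):
            for i, m in terms:
                a[r] *= y[i] ** m
            a[r] /= volume ** (order_tot[r] - 1)
        a_sum = a.sum()
        if a_sum <= 0:
            break
        t += rng.exponential(1.0 / a_sum)
        if t >= t_end:
            break
        r = rng.choice(a.size, p=a / a_sum)
        y = y + S[r].astype(np.int64)
        times.append(t)
        states.append(y.copy())
    return np.array(times), np.array(states), S, idx


def dense_fwhm_oracle(times: np.ndarray, values: np.ndarray, t_stress: float) -> float:
    """Brute-force FWHM: exhaustive scan of all midpoint crossings on a
    dense linear interpolation of the series."""
    dense_t = np.linspace(times[0], times[-1], 200_001)
    dense_v = np.interp(dense_t, times, values)
    base = dense_v[dense_t < t_stress].mean()
    post = dense_t >= t_stress
    k = np.flatnonzero(post)[np.argmax(dense_v[post])]
    half = base + (dense_v[k] - base) / 2.0
    above = dense_v >= half
    left = np.flatnonzero(~above[: k + 1])
    right = np.flatnonzero(~above[k:])
    t_left = dense_t[left[-1] + 1] if left.size else None
    t_right = dense_t[k + right[0] - 1] if right.size else None
    assert t_left is not None and t_right is not None
    return float(t_right - t_left)
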