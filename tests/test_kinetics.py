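import numpy as np
import pytest
from dataclasses import replace

from _oracles import (
    gillespie,
    initial_state,
    rk4_trajectory,
    species_index,
)
from leafwave.kinetics import (
    FitResult,
    KineticParams,
    conservation_check,
    fit_kinetic_model,
    simulate,
)
from leafwave.presets import kinetic_preset
from leafwave.wave_features import ConcentrationSeries

# a generic parameter set exercising every branch of the network
FULL = KineticParams(
    k=0.02, kd=0.08, kf1=0.005, kf_chain=(0.04, 0.04), ks=0.04,
    ki=0.006, kr=0.05, a0=0.5, p0=20.0, pf0=6.0, pi0=3.0, t_stress=10.0,
)
T_GRID = np.arange(0.0, 180.5, 0.5)


def random_params(rng: np.random.Generator) -> KineticParams:
    return KineticParams(
        k=rng.uniform(0.001, 0.05),
        kd=rng.uniform(0.01, 0.3),
        kf1=rng.uniform(0.0, 0.01),
        kf_chain=(rng.uniform(0.01, 0.3),) * 2,
        ks=rng.uniform(0.01, 0.3),
        ki=rng.uniform(0.0, 0.01),
        kr=rng.uniform(0.0, 0.2),
        a0=rng.uniform(0.05, 2.0),
        p0=rng.uniform(5.0, 80.0),
        pf0=rng.uniform(0.0, 10.0),
        pi0=rng.uniform(0.0, 5.0),
        t2=100.0,
        p2=rng.uniform(0.0, 20.0),
    )


class TestSimulate:
    def test_logistic_limit_closed_form(self):
        """With the decay and both A-consuming branches off, A follows
        logistic growth to a0 + p0 and A + P is conserved."""
        p = replace(FULL, kd=0.0, kf1=0.0, ki=0.0, pf0=0.0, pi0=0.0, kr=0.0)
        traj = simulate(p, T_GRID)
        post = T_GRID >= p.t_stress
        tau = T_GRID[post] - p.t_stress
        K = p.a0 + p.p0
        expected = p.a0 * K * np.exp(p.k * K * tau) / (
            p.p0 + p.a0 * np.exp(p.k * K * tau)
        )
        np.testing.assert_allclose(traj.h2o2[post], expected, rtol=1e-6)
        np.testing.assert_allclose(
            traj.h2o2 + traj.species["P"],
            np.where(post, K, p.p0),
            rtol=1e-8,
        )

    def test_no_inhibition_limit_sa_monotone_and_bounded(self):
        p = KineticParams(
            k=0.02, kd=0.08, kf1=0.05, kf_chain=(), ks=0.05,
            n_intermediates=1, a0=0.5, p0=20.0, pf0=5.0, pi0=0.0, ki=0.0, kr=0.0,
        )
        traj = simulate(p, np.arange(0.0, 600.0, 1.0))
        assert np.all(np.diff(traj.sa) >= -1e-9)
        assert traj.sa[-1] <= p.pf0 + 1e-6
        # with ample H2O2 the whole pF pool is eventually routed into S
        assert traj.sa[-1] == pytest.approx(p.pf0, rel=0.05)

    def test_matches_fixed_step_rk4_oracle(self):
        """Stiff-solver output agrees with an independent dt=1e-3 RK4
        integration of the reaction list within 0.1% of each species' peak."""
        t = np.arange(10.0, 60.01, 1.0)
        traj = simulate(FULL, t)
        times, ys = rk4_trajectory(FULL, initial_state(FULL), 10.0, 60.0, 1e-3)
        idx = species_index(FULL.n_intermediates)
        sel = np.searchsorted(np.round(times, 6), np.round(t, 6))
        for name, i in idx.items():
            ours = traj.species[name][: t.size]
            scale = max(ys[:, i].max(), 1e-9)
            np.testing.assert_allclose(
                ours, ys[sel, i], atol=1e-3 * scale,
                err_msg=f"species {name} deviates from RK4 oracle",
            )

    def test_secondary_burst_reinjects_precursor(self):
        p = replace(FULL, t2=60.0, p2=5.0)
        traj = simulate(p, T_GRID)
        i = np.searchsorted(T_GRID, 60.0)
        jump = traj.species["P"][i] - traj.species["P"][i - 1]
        assert jump > 4.0  # impulse dominates the smooth depletion

    def test_resting_state_before_stress(self):
        traj = simulate(FULL, T_GRID)
        pre = T_GRID < FULL.t_stress
        assert np.all(traj.h2o2[pre] == 0.0)
        assert np.all(traj.species["P"][pre] == FULL.p0)

    def test_species_nonnegative_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            traj = simulate(random_params(rng), T_GRID)
            for name, vals in traj.species.items():
                assert vals.min() >= -1e-9, name

    @pytest.mark.parametrize(
        "bad",
        [
            dict(k=-1.0),
            dict(n_intermediates=0),
            dict(kf_chain=(0.1,)),
            dict(t2=5.0, p2=1.0),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            replace(FULL, **bad)


class TestConservation:
    def test_laws_hold_on_simulated_trajectories(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_params(rng)
            traj = simulate(p, T_GRID)
            drifts = conservation_check(traj)
            scale = max(p.a0 + p.p0 + (p.p2 or 0.0), p.pf0, p.pi0, 1.0)
            assert max(drifts.values()) < 1e-6 * scale

    def test_constructed_violation_detected(self):
        traj = simulate(FULL, T_GRID)
        traj.species["B"][:] += 1.0
        assert conservation_check(traj)["a_units"] == pytest.approx(1.0, abs=1e-6)

    def test_ssa_paths_conserve_exactly_per_event(self):
        """Discrete-event (Gillespie) sample paths obey all three laws as
        exact integer invariants, and their mean tracks the ODE peak."""
        rng = np.random.default_rng(3)
        vol = 200.0
        p = replace(FULL, t_stress=0.0)
        idx = species_index(p.n_intermediates)
        peaks = []
        for _ in range(3):
            times, states, S, idx = gillespie(p, vol, 25.0, rng)
            F = sum(states[:, idx[f"F{i}"]] for i in range(1, 4))
            a_units = (
                states[:, idx["A"]] + states[:, idx["B"]] + F
                + states[:, idx["S"]] + states[:, idx["I"]] + states[:, idx["xF1"]]
                + states[:, idx["P"]]
            )
            assert np.all(a_units == a_units[0])
            pf_units = states[:, idx["pF"]] + F + states[:, idx["S"]] + states[:, idx["xF1"]]
            pi_units = states[:, idx["pI"]] + states[:, idx["I"]] + states[:, idx["xF1"]]
            assert np.all(pf_units == pf_units[0])
            assert np.all(pi_units == pi_units[0])
            peaks.append(states[:, idx["A"]].max() / vol)
        traj = simulate(p, np.arange(0.0, 25.1, 0.1))
        assert np.mean(peaks) == pytest.approx(traj.h2o2.max(), rel=0.15)


class TestInhibitorAndChain:
    @staticmethod
    def _sa_onset(p, thresh=0.05):
        traj = simulate(p, np.arange(0.0, 300.0, 0.5))
        above = traj.times[traj.sa > thresh]
        return above[0] if above.size else np.inf

    def test_more_inhibitor_precursor_delays_sa_onset(self):
        onsets = [
            self._sa_onset(replace(FULL, pi0=pi0)) for pi0 in (0.0, 2.0, 6.0)
        ]
        assert onsets[0] <= onsets[1] <= onsets[2]
        assert onsets[2] > onsets[0]

    def test_longer_chain_delays_sa_onset_at_fixed_throughput(self):
        onsets = []
        for n in (1, 3, 6):
            p = replace(
                FULL, n_intermediates=n, kf_chain=(0.04,) * (n - 1), ks=0.04
            )
            onsets.append(self._sa_onset(p))
        assert onsets[0] < onsets[1] < onsets[2]


class TestFit:
    def test_self_consistency_from_truth(self):
        p = kinetic_preset("wounding")
        t = np.arange(0.0, 121.0, 1.0)
        traj = simulate(p, t)
        h = ConcentrationSeries(times=t, values=traj.h2o2, t_stress=10.0)
        s = ConcentrationSeries(times=t, values=traj.sa, t_stress=10.0)
        res = fit_kinetic_model(
            h, s, p, frozen=("kf_chain", "ks", "kf1", "ki", "kr", "pf0", "pi0"),
            n_starts=1,
        )
        assert res.sse < 1e-10
        assert res.params.kd == pytest.approx(p.kd, rel=1e-3)

    def test_null_sa_with_frozen_pool_gives_zero_residual(self):
        """A wounding-like experiment: no SA signal, pF pool frozen at zero,
        so the fitted SA trajectory is identically zero."""
        p = kinetic_preset("wounding")
        t = np.arange(0.0, 121.0, 1.0)
        traj = simulate(p, t)
        h = ConcentrationSeries(times=t, values=traj.h2o2, t_stress=10.0)
        s = ConcentrationSeries(times=t, values=np.zeros(t.size), t_stress=10.0)
        res = fit_kinetic_model(
            h, s, p, frozen=("kf_chain", "ks", "kf1", "ki", "kr", "pf0", "pi0"),
            n_starts=1,
        )
        np.testing.assert_allclose(res.residual_sa, 0.0, atol=1e-12)

    def test_no_free_parameters_rejected(self):
        p = kinetic_preset("wounding")
        t = np.arange(0.0, 50.0, 1.0)
        s = ConcentrationSeries(times=t, values=np.zeros(t.size), t_stress=10.0)
        with pytest.raises(ValueError):
            fit_kinetic_model(
                s, s, p,
                frozen=("k", "kd", "kf1", "ks", "ki", "kr", "a0", "p0", "pf0",
                        "pi0", "kf_chain"),
            )


def test_params_json_round_trip(tmp_path):
    FULL.to_json(tmp_path / "p.json")
    back = KineticParams.from_json(tmp_path / "p.json")
    assert back == FULL
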