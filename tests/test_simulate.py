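"""Simulators: ODE adapter, Euler–Maruyama, and the four exact SSAs."""

import numpy as np
import pytest
import sympy as sp

import crnkit as ck
from crnkit.simulate import (
    SSA_METHODS,
    RNGStream,
    Trajectory,
    UnsupportedMethodError,
    prepare_jumps,
    sample_final_states,
    simulate_jumps,
    solve_ode,
    solve_sde_em,
)

k = sp.Symbol("k")


def _decay_system():
    return ck.ReactionSystem.from_reactions(
        [ck.make_reaction(k, [("X", 1)], [])], name="decay"
    )


class TestSolveOde:
    def test_exponential_decay(self):
        """X' = -X integrates to e^{-1} at t=1 within the default tolerances."""
        m = ck.to_ode_model(_decay_system())
        traj = solve_ode(m, {"X": 1.0}, {"k": 1.0}, (0.0, 1.0), saveat=[1.0])
        assert abs(traj.final_state[0] - np.exp(-1)) < 1e-6

    def test_tolerance_convergence(self):
        """Halving tolerances reduces the error against the closed form."""
        m = ck.to_ode_model(_decay_system())
        errors = []
        for rtol in (1e-4, 1e-6, 1e-8, 1e-10):
            traj = solve_ode(
                m, {"X": 1.0}, {"k": 1.0}, (0.0, 1.0),
                abstol=rtol * 1e-3, reltol=rtol, saveat=[1.0],
            )
            errors.append(abs(traj.final_state[0] - np.exp(-1)))
        assert all(a >= b for a, b in zip(errors, errors[1:]))
        assert errors[-1] < errors[0]

    def test_brusselator_fixed_point(self, brusselator):
        """B < 1 + A**2: the deterministic model converges to (A, B/A)."""
        m = ck.to_ode_model(brusselator.system, combinatoric=False)
        traj = solve_ode(m, brusselator.u0, {"A": 1.0, "B": 1.5}, (0.0, 100.0), saveat=[100.0])
        assert np.max(np.abs(traj.final_state - [1.0, 1.5])) < 1e-6

    def test_brusselator_limit_cycle(self, brusselator):
        """B > 1 + A**2: sustained post-transient oscillation."""
        m = ck.to_ode_model(brusselator.system, combinatoric=False)
        grid = np.linspace(50.0, 100.0, 500)
        traj = solve_ode(m, brusselator.u0, {"A": 1.0, "B": 3.0}, (0.0, 100.0), saveat=grid)
        assert traj["X"].max() - traj["X"].min() > 0.5

    def test_invalid_tolerances(self):
        m = ck.to_ode_model(_decay_system())
        with pytest.raises(ck.CRNError):
            solve_ode(m, {"X": 1.0}, {"k": 1.0}, (0, 1), abstol=0.0)


class TestEulerMaruyama:
    def test_zero_noise_is_constant(self, birth_death):
        m = ck.to_sde_model(birth_death.system)
        traj = solve_sde_em(m, {"X": 5.0}, {"b": 0.0, "d": 0.0}, (0, 1), dt=0.1, rng=1)
        assert np.all(traj.states == 5.0)

    def test_seed_determinism(self, birth_death):
        m = ck.to_sde_model(birth_death.system)
        runs = [
            solve_sde_em(m, {"X": 0.0}, {"b": 10.0, "d": 1.0}, (0, 2), dt=0.01,
                         rng=RNGStream(123))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].states, runs[1].states)

    def test_negative_excursions_stay_finite(self):
        """The |.| guard keeps sqrt noise evaluable below zero."""
        m = ck.to_sde_model(_decay_system())
        traj = solve_sde_em(m, {"X": 0.05}, {"k": 5.0}, (0, 5), dt=0.05, rng=RNGStream(4))
        assert np.all(np.isfinite(traj.states))
        assert traj.states.min() < 0  # excursions actually happened

    def test_ensemble_mean_matches_linear_rre(self, birth_death):
        """For the linear birth-death CLE the mean obeys the RRE."""
        m = ck.to_sde_model(birth_death.system)
        gen = RNGStream(2024).generator()
        t_end, n = 5.0, 1000
        finals = np.array([
            solve_sde_em(m, birth_death.u0, birth_death.params, (0, t_end),
                         dt=0.025, rng=gen, saveat=[t_end]).final_state[0]
            for _ in range(n)
        ])
        exact = 10.0 * (1 - np.exp(-t_end))
        se = finals.std(ddof=1) / np.sqrt(n)
        assert abs(finals.mean() - exact) < 3 * se + 1e-3

    def test_weak_convergence_order_one(self, birth_death):
        """The ensemble-mean bias shrinks ~linearly as dt halves."""
        m = ck.to_sde_model(birth_death.system)
        exact = 10.0 * (1 - np.exp(-1.0))
        errors = []
        for dt in (0.5, 0.25, 0.125):
            gen = RNGStream(11).generator()
            finals = np.array([
                solve_sde_em(m, birth_death.u0, birth_death.params, (0, 1.0),
                             dt=dt, rng=gen, saveat=[1.0]).final_state[0]
                for _ in range(4000)
            ])
            errors.append(abs(finals.mean() - exact))
        assert errors[0] > errors[1] > errors[2]
        for coarse, fine in zip(errors, errors[1:]):
            assert 1.3 < coarse / fine < 3.2  # consistent with order ~1


class TestSimulateJumps:
    def test_pure_death_absorbs_at_zero(self):
        js = ck.classify_jumps(_decay_system())
        traj = simulate_jumps(js, {"X": 100}, {"k": 1.0}, (0, 100), rng=RNGStream(0))
        assert traj.states[-1, 0] == 0
        assert np.all(np.diff(traj.states[:, 0]) <= 0)

    def test_extinction_time_mean(self):
        """Mean extinction time of pure death from X0=100 is sum_i 1/(k*i)."""
        js = ck.classify_jumps(_decay_system())
        prep = prepare_jumps(js, {"k": 1.0})
        gen = RNGStream(5).generator()
        n = 3000
        ts = np.empty(n)
        for i in range(n):
            tr = simulate_jumps(prep, {"X": 100}, tspan=(0, 200), method="direct", rng=gen)
            ts[i] = tr.times[np.argmax(tr.states[:, 0] == 0)]
        expect = sum(1.0 / i for i in range(1, 101))
        se = ts.std(ddof=1) / np.sqrt(n)
        assert abs(ts.mean() - expect) < 3 * se

    def test_absorbing_zero_state(self):
        js = ck.classify_jumps(_decay_system())
        traj = simulate_jumps(js, {"X": 0}, {"k": 1.0}, (0, 10), rng=RNGStream(1),
                              saveat=np.linspace(0, 10, 11))
        assert np.all(traj.states == 0)
        assert len(traj) == 11  # zero total propensity still fills the grid

    @pytest.mark.parametrize("method", SSA_METHODS)
    def test_seed_determinism(self, birth_death, method):
        js = ck.classify_jumps(birth_death.system)
        runs = [
            simulate_jumps(js, birth_death.u0, birth_death.params, (0, 5),
                           method=method, rng=RNGStream(77))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].times, runs[1].times)
        assert np.array_equal(runs[0].states, runs[1].states)

    @pytest.mark.parametrize("method", SSA_METHODS)
    def test_birth_death_moments(self, birth_death, method):
        """Quick Poisson(10) check per method (the deep exactness test lives
        in the acceptance suite at larger n)."""
        js = ck.classify_jumps(birth_death.system)
        X = sample_final_states(
            js, birth_death.u0, birth_death.params, t_end=10.0,
            n_paths=2000, method=method, seed=31,
        )[:, 0]
        se_mean = np.sqrt(10.0 / X.size)
        assert abs(X.mean() - 10.0) < 3.5 * se_mean
        se_var = np.sqrt((310.0 - 100.0) / X.size)  # Var(s^2) for Poisson(10)
        assert abs(X.var(ddof=1) - 10.0) < 3.5 * se_var

    def test_variable_rate_rejected(self):
        system = ck.parse_reaction_network("A*(1+sin(t)), 0 --> X\nd, X --> 0")
        js = ck.classify_jumps(system)
        with pytest.raises(UnsupportedMethodError):
            simulate_jumps(js, {"X": 0}, {"A": 1.0, "d": 1.0}, (0, 1), rng=RNGStream(1))

    def test_unknown_method_rejected(self, birth_death):
        js = ck.classify_jumps(birth_death.system)
        with pytest.raises(UnsupportedMethodError):
            simulate_jumps(js, birth_death.u0, birth_death.params, (0, 1),
                           method="tau_leap", rng=RNGStream(1))

    def test_states_are_integers(self, dimerization):
        js = ck.classify_jumps(dimerization.system)
        traj = simulate_jumps(js, dimerization.u0, dimerization.params, (0, 5),
                              rng=RNGStream(3))
        assert traj.states.dtype == np.int64
        assert np.all(traj.states >= 0)


class TestTrajectory:
    def test_validation(self):
        with pytest.raises(ck.CRNError):
            Trajectory(times=[0.0, 1.0], states=np.zeros((3, 1)), species=("X",))
        with pytest.raises(ck.CRNError):
            Trajectory(times=[1.0, 0.0], states=np.zeros((2, 1)), species=("X",))

    def test_species_access(self):
        tr = Trajectory(times=[0.0, 1.0], states=[[1, 2], [3, 4]], species=("X", "Y"))
        assert list(tr["Y"]) == [2, 4]
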