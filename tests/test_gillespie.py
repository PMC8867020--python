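"""Stochastic simulator: determinism, bookkeeping, CTMC oracle, resampling."""

import numpy as np
import pytest

from avalanchekit.model import ModelParams, PopulationState, event_rates
from avalanchekit import gillespie


def ctmc_mean_extinction_time(params: ModelParams, max_n: int) -> dict:
    """Mean absorption time of the truncated continuous-time Markov chain.

    States (x, y) with 1 <= x + y <= max_n; births that would leave the
    truncation are disabled.  Solves (for absorption times tau)
    ``tau(s) = 1/R(s) + sum_r P(s -> r) tau(r)`` as a sparse linear
    system — an independent oracle for the Gillespie ensemble mean.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    states = [
        (x, y)
        for n in range(1, max_n + 1)
        for x in range(n + 1)
        if (y := n - x) >= 0
    ]
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    rows, cols, vals = [], [], []
    b = np.zeros(m)
    for s, i in index.items():
        x, y = s
        bx, by, dx, dy = event_rates(PopulationState(x, y), params)
        n = x + y
        if n >= max_n:
            bx = by = 0.0  # truncation: no births at the ceiling
        moves = [
            ((x + 1, y), bx),
            ((x, y + 1), by),
            ((x - 1, y), dx),
            ((x, y - 1), dy),
        ]
        total = sum(r for _, r in moves)
        rows.append(i), cols.append(i), vals.append(total)
        b[i] = 1.0
        for target, rate in moves:
            if rate <= 0:
                continue
            if target == (0, 0):
                continue  # absorbing: tau = 0
            j = index[target]
            rows.append(i), cols.append(j), vals.append(-rate)
    a = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
    tau = spla.spsolve(a.tocsc(), b)
    return {s: tau[i] for s, i in index.items()}


class TestSimulate:
    PARAMS = ModelParams(mu=0.6, nu=0.8, delta=0.1)

    def test_deterministic_under_fixed_seed(self):
        a = gillespie.simulate(self.PARAMS, PopulationState(1, 0), 100.0, seed=7)
        b = gillespie.simulate(self.PARAMS, PopulationState(1, 0), 100.0, seed=7)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)

    def test_distinct_seeds_differ(self):
        a = gillespie.simulate(self.PARAMS, PopulationState(1, 0), 100.0, seed=1)
        b = gillespie.simulate(self.PARAMS, PopulationState(1, 0), 100.0, seed=2)
        assert not (
            len(a.times) == len(b.times) and np.allclose(a.times, b.times)
        )

    def test_empty_initial_condition(self):
        traj = gillespie.simulate(self.PARAMS, PopulationState(0, 0), 10.0, seed=3)
        assert traj.terminated_by == "extinction"
        assert traj.times[-1] == 0.0

    def test_buffer_replay_reproduces_trajectory(self):
        big = gillespie.simulate(self.PARAMS, PopulationState(1, 0), 200.0, seed=11)
        small = gillespie.simulate(
            self.PARAMS, PopulationState(1, 0), 200.0, seed=11, max_events=16
        )
        assert np.array_equal(big.times, small.times)
        assert np.array_equal(big.n, small.n)

    @pytest.mark.parametrize("seed", range(5))
    def test_event_bookkeeping(self, seed):
        """Consecutive states differ by +/-1 in exactly one count; no negatives."""
        traj = gillespie.simulate(self.PARAMS, PopulationState(1, 0), 500.0, seed=seed)
        assert (traj.x >= 0).all() and (traj.y >= 0).all()
        assert (np.diff(traj.times) > 0).all()
        dx = np.abs(np.diff(traj.x))
        dy = np.abs(np.diff(traj.y))
        assert np.array_equal(dx + dy, np.ones(len(traj.times) - 1))
        if traj.terminated_by == "extinction":
            assert traj.n[-1] == 0

    def test_sustained_activity_inside_active_region(self):
        """Strong excitation with moderate inhibition holds a plateau."""
        params = ModelParams.from_excitation(0.6, 0.6, 5e-4)
        survived = 0
        for seed in range(8):
            t = gillespie.simulate_extinction_time(
                params, PopulationState(1, 0), 1e3, seed
            )
            survived += t >= 1e3
        assert survived >= 3  # triggering succeeds often; then activity persists


class TestEnsemble:
    def test_cap_contract(self):
        params = ModelParams.from_excitation(0.2, 0.6, 5e-4)
        res = gillespie.run_ensemble(params, 20, cap=50.0, base_seed=1)
        assert (res.extinction_times <= 50.0).all()
        assert (res.extinction_times > 0).all()
        assert res.mean_T == pytest.approx(res.extinction_times.mean())

    def test_subcritical_point_dies_fast(self):
        params = ModelParams.from_excitation(0.0, 0.95, 5e-4)
        res = gillespie.run_ensemble(params, 30, cap=1e4, base_seed=2)
        assert res.mean_T < 100.0

    def test_mean_extinction_time_matches_ctmc_oracle(self):
        """Ensemble mean agrees with the truncated-CTMC linear solve (3 SE)."""
        params = ModelParams(mu=0.6, nu=0.8, delta=0.1)
        tau = ctmc_mean_extinction_time(params, max_n=60)
        exact = params.mu * tau[(1, 0)] + (1 - params.mu) * tau[(0, 1)]
        res = gillespie.run_ensemble(params, 10_000, cap=1e6, base_seed=3)
        assert abs(res.mean_T - exact) < 3 * res.se_T

    def test_mean_T_decreases_with_global_inhibition(self):
        means = []
        for nu in (0.6, 0.9):
            params = ModelParams.from_excitation(0.4, nu, 5e-4)
            means.append(
                gillespie.run_ensemble(params, 60, cap=2e3, base_seed=4).mean_T
            )
        assert means[0] > means[1]

    def test_adaptive_ensemble_stops_early_when_variance_low(self):
        params = ModelParams.from_excitation(0.0, 0.99, 5e-4)
        res = gillespie.run_ensemble_adaptive(
            params, cap=1e3, base_seed=5, batch=8, max_realizations=64
        )
        assert res.realizations <= 64


class TestResample:
    def test_step_function_sampling(self):
        traj = gillespie.Trajectory(
            times=np.array([0.0, 0.5]),
            x=np.array([1, 0]),
            y=np.array([0, 0]),
            params=ModelParams(mu=0.6, nu=0.5, delta=0.1),
            seed=0,
            terminated_by="extinction",
            horizon=1.0,
        )
        grid, vals = gillespie.resample(traj, 0.25, end=1.0)
        assert np.allclose(grid, [0.0, 0.25, 0.5, 0.75, 1.0])
        assert vals.tolist() == [1, 1, 0, 0, 0]

    def test_riemann_sum_converges_to_exact_integral(self):
        params = ModelParams(mu=0.6, nu=0.8, delta=0.05)
        traj = gillespie.simulate(params, PopulationState(2, 1), 100.0, seed=9)
        exact = traj.integrate(0.0, traj.times[-1])
        errs = []
        for bw in (0.1, 0.01):
            grid, vals = gillespie.resample(traj, bw)
            errs.append(abs(vals[:-1].sum() * bw - exact))
        assert errs[1] < errs[0]
        assert errs[1] < 0.02 * max(exact, 1.0)

    def test_integral_additive_over_subintervals(self):
        params = ModelParams(mu=0.6, nu=0.8, delta=0.05)
        traj = gillespie.simulate(params, PopulationState(2, 1), 50.0, seed=10)
        t_end = traj.times[-1]
        total = traj.integrate(0, t_end)
        split = traj.integrate(0, t_end / 3) + traj.integrate(t_end / 3, t_end)
        assert split == pytest.approx(total, rel=1e-9)
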