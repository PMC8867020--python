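"""Exact stochastic simulation of the contact process (direct method).

Events are sampled one at a time: the total rate ``R`` of the four
channels sets an exponential waiting time, a channel is picked with
probability proportional to its rate, and the corresponding count moves
by +/-1.  The hot loop is JIT-compiled; a trajectory of ``10**7`` events
simulates in a few seconds on one core.

Reproducibility: every public entry point takes an integer seed.
Per-realization seeds are derived with :class:`numpy.random.SeedSequence`
from ``(base_seed, realization_index)``, which is stable across platforms
and library versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ModelParams, PopulationState

__all__ = [
    "Trajectory",
    "EnsembleResult",
    "simulate",
    "simulate_extinction_time",
    "run_ensemble",
    "run_ensemble_adaptive",
    "resample",
]


@njit(cache=True)
def _phi_counts(x: int, y: int) -> float:
    n = x + y
    if n == 0:
        return 0.0
    if n == 1:
        return 1.0  # pure-population limit for a lone spike
    return (x * (x - 1.0) + y * (y - 1.0)) / (n * (n - 1.0))


@njit(cache=True)
def _sim_extinction(mu, nu, delta, x0, y0, cap, seed):
    """Extinction time from (x0, y0), truncated at `cap`; no recording."""
    np.random.seed(seed)
    x = x0
    y = y0
    t = 0.0
    while True:
        n = x + y
        if n == 0:
            return t
        p = _phi_counts(x, y)
        g = nu * p
        bx = mu * n
        by = (1.0 - mu) * n
        dx = (delta * x + g) * n if x > 0 else 0.0
        dy = (delta * y + g) * n if y > 0 else 0.0
        r = bx + by + dx + dy
        t_next = t + np.random.exponential() / r
        if t_next > cap:
            return cap
        t = t_next
        u = np.random.random() * r
        if u < bx:
            x += 1
        elif u < bx + by:
            y += 1
        elif u < bx + by + dx:
            x -= 1
        else:
            y -= 1


@njit(cache=True)
def _sim_record(mu, nu, delta, x0, y0, horizon, seed, times, xs, ys):
    """Record the full event trajectory into preallocated buffers.

    Returns (number of records, termination code) with codes
    0 = extinction, 1 = horizon reached, 2 = buffers full.
    """
    np.random.seed(seed)
    x = x0
    y = y0
    t = 0.0
    times[0] = 0.0
    xs[0] = x
    ys[0] = y
    k = 1
    cap_k = times.shape[0]
    while True:
        n = x + y
        if n == 0:
            return k, 0
        p = _phi_counts(x, y)
        g = nu * p
        bx = mu * n
        by = (1.0 - mu) * n
        dx = (delta * x + g) * n if x > 0 else 0.0
        dy = (delta * y + g) * n if y > 0 else 0.0
        r = bx + by + dx + dy
        t_next = t + np.random.exponential() / r
        if t_next > horizon:
            return k, 1
        if k >= cap_k:
            return k, 2
        t = t_next
        u = np.random.random() * r
        if u < bx:
            x += 1
        elif u < bx + by:
            y += 1
        elif u < bx + by + dx:
            x -= 1
        else:
            y -= 1
        times[k] = t
        xs[k] = x
        ys[k] = y
        k += 1


@njit(cache=True)
def _sim_excursion(mu, nu, delta, x0, y0, horizon, seed):
    """(T, area, peak N) of one realization, without recording events.

    The area accumulates the exact piecewise-constant integral of N; runs
    reaching `horizon` are truncated there (T = horizon).
    """
    np.random.seed(seed)
    x = x0
    y = y0
    t = 0.0
    area = 0.0
    peak = x + y
    while True:
        n = x + y
        if n == 0:
            return t, area, peak
        p = _phi_counts(x, y)
        g = nu * p
        bx = mu * n
        by = (1.0 - mu) * n
        dx = (delta * x + g) * n if x > 0 else 0.0
        dy = (delta * y + g) * n if y > 0 else 0.0
        r = bx + by + dx + dy
        dt = np.random.exponential() / r
        if t + dt > horizon:
            area += n * (horizon - t)
            return horizon, area, peak
        area += n * dt
        t += dt
        u = np.random.random() * r
        if u < bx:
            x += 1
        elif u < bx + by:
            y += 1
        elif u < bx + by + dx:
            x -= 1
        else:
            y -= 1
        if x + y > peak:
            peak = x + y


_TERMINATION = {0: "extinction", 1: "horizon"}


@dataclass
class Trajectory:
    """Event-driven record of one stochastic realization.

    ``times[i]`` is the time of the i-th event (``times[0] == 0`` holds the
    initial condition) and ``x[i], y[i]`` the counts immediately after it.
    ``N(u)`` is piecewise constant and right-continuous: between events the
    population holds the value set at the last event at or before ``u``.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    params: ModelParams
    seed: int
    terminated_by: str
    horizon: float
    _cum: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> np.ndarray:
        """Total spiking count after each event."""
        return self.x + self.y

    @property
    def extinction_time(self) -> float | None:
        """Time of absorption at N = 0, or None if the horizon was hit."""
        return float(self.times[-1]) if self.terminated_by == "extinction" else None

    def _cumulative(self) -> np.ndarray:
        if self._cum is None:
            n = self.n.astype(np.float64)
            dt = np.diff(self.times)
            self._cum = np.concatenate(([0.0], np.cumsum(n[:-1] * dt)))
        return self._cum

    def integrate(self, a: float, b: float) -> float:
        """Exact time integral of N over [a, b] (piecewise-constant area)."""
        if b < a:
            raise ValueError("integration bounds must satisfy a <= b")

        cum = self._cumulative()
        n = self.n.astype(np.float64)

        def antiderivative(t: float) -> float:
            k = int(np.searchsorted(self.times, t, side="right")) - 1
            if k < 0:
                return 0.0
            return cum[k] + n[k] * (t - self.times[k])

        return antiderivative(b) - antiderivative(a)

    def value_at(self, u: float) -> int:
        """N at time u (right-continuous; 0 before the first record)."""
        k = int(np.searchsorted(self.times, u, side="right")) - 1
        if k < 0:
            return 0
        return int(self.n[k])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) else 0.0


def simulate(
    params: ModelParams,
    initial: PopulationState,
    horizon: float,
    seed: int,
    max_events: int = 1 << 16,
) -> Trajectory:
    """One stochastic realization recorded event by event.

    The direct method terminates at extinction (N = 0) or at the first
    event time exceeding ``horizon``.  The same ``(params, initial,
    horizon, seed)`` always yields the identical trajectory; if the
    initial event buffer fills, the run is replayed from the same seed
    into a larger buffer, leaving the random stream unchanged.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if initial.n == 0:
        return Trajectory(
            times=np.zeros(1),
            x=np.zeros(1, dtype=np.int64),
            y=np.zeros(1, dtype=np.int64),
            params=params,
            seed=seed,
            terminated_by="extinction",
            horizon=horizon,
        )
    size = max(int(max_events), 16)
    while True:
        times = np.empty(size, dtype=np.float64)
        xs = np.empty(size, dtype=np.int64)
        ys = np.empty(size, dtype=np.int64)
        k, code = _sim_record(
            params.mu, params.nu, params.delta,
            initial.x, initial.y, horizon, seed, times, xs, ys,
        )
        if code != 2:
            return Trajectory(
                times=times[:k].copy(),
                x=xs[:k].copy(),
                y=ys[:k].copy(),
                params=params,
                seed=seed,
                terminated_by=_TERMINATION[code],
                horizon=horizon,
            )
        size *= 8  # replay deterministically with more room


def simulate_extinction_time(
    params: ModelParams, initial: PopulationState, cap: float, seed: int
) -> float:
    """Extinction time of one realization, truncated at ``cap``.

    Much faster than :func:`simulate` because nothing is recorded.
    """
    if initial.n == 0:
        return 0.0
    return float(
        _sim_extinction(params.mu, params.nu, params.delta, initial.x, initial.y, cap, seed)
    )


def simulate_excursion(
    params: ModelParams, initial: PopulationState, horizon: float, seed: int
) -> tuple[float, float, int]:
    """Lifetime, exact activity integral and peak count of one realization.

    Equivalent to ``simulate`` followed by integration over the whole
    span, but without storing the event record — the memory-light path
    for avalanche ensembles over many restarts.
    """
    if initial.n == 0:
        return 0.0, 0.0, 0
    t, area, peak = _sim_excursion(
        params.mu, params.nu, params.delta, initial.x, initial.y, horizon, seed
    )
    return float(t), float(area), int(peak)


def _realization_seeds(base_seed: int, index: int) -> tuple[int, float]:
    """(kernel seed, uniform draw for the initial-spike assignment)."""
    words = np.random.SeedSequence([int(base_seed), int(index)]).generate_state(2)
    return int(words[0]), float(words[1]) / 2.0**32


def initial_state(params: ModelParams, u: float, rule: str = "mu-weighted") -> PopulationState:
    """Single-spike initial condition N(0) = 1.

    ``mu-weighted`` (default) assigns the spike to the excited pool with
    probability ``mu`` — the same law as the excitation rule itself;
    ``uniform`` flips a fair coin.  ``u`` is a uniform [0, 1) variate.
    """
    if rule == "mu-weighted":
        p = params.mu
    elif rule == "uniform":
        p = 0.5
    else:
        raise ValueError(f"unknown initial rule {rule!r}")
    return PopulationState(x=1, y=0) if u < p else PopulationState(x=0, y=1)


@dataclass
class EnsembleResult:
    """Extinction times of an ensemble started from N(0) = 1."""

    extinction_times: np.ndarray
    params: ModelParams
    cap: float
    base_seed: int
    init_rule: str = "mu-weighted"

    @property
    def realizations(self) -> int:
        return len(self.extinction_times)

    @property
    def mean_T(self) -> float:
        return float(np.mean(self.extinction_times))

    @property
    def se_T(self) -> float:
        n = self.realizations
        if n < 2:
            return float("inf")
        return float(np.std(self.extinction_times, ddof=1) / np.sqrt(n))


def run_ensemble(
    params: ModelParams,
    n_realizations: int,
    cap: float = 1e4,
    base_seed: int = 0,
    init_rule: str = "mu-weighted",
    start_index: int = 0,
) -> EnsembleResult:
    """Ensemble of extinction times from single-spike initial conditions.

    Each realization ``i`` draws its kernel seed and its initial-spike
    assignment from ``SeedSequence([base_seed, start_index + i])``; each
    recorded T is ``min(extinction time, cap)``.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    ts = np.empty(n_realizations)
    for i in range(n_realizations):
        seed, u = _realization_seeds(base_seed, start_index + i)
        init = initial_state(params, u, init_rule)
        ts[i] = simulate_extinction_time(params, init, cap, seed)
    return EnsembleResult(ts, params, cap, base_seed, init_rule)


def run_ensemble_adaptive(
    params: ModelParams,
    cap: float = 1e4,
    base_seed: int = 0,
    batch: int = 8,
    max_realizations: int = 40,
    se_fraction: float = 0.05,
    init_rule: str = "mu-weighted",
) -> EnsembleResult:
    """Grow the ensemble in batches until the mean is well resolved.

    Batches of ``batch`` realizations are added until the standard error
    of ``mean_T`` falls below ``se_fraction`` of its value or
    ``max_realizations`` is reached.  Low-variability cells (deep plateau
    or deep valley) therefore stop early.
    """
    ts: list[float] = []
    while len(ts) < max_realizations:
        res = run_ensemble(
            params, batch, cap, base_seed, init_rule, start_index=len(ts)
        )
        ts.extend(res.extinction_times.tolist())
        arr = np.asarray(ts)
        if len(arr) >= 2:
            se = float(np.std(arr, ddof=1) / np.sqrt(len(arr)))
            if se <= se_fraction * float(np.mean(arr)):
                break
    return EnsembleResult(np.asarray(ts), params, cap, base_seed, init_rule)


def resample(traj: Trajectory, bin_width: float, end: float | None = None):
    """Sample N(u) on a uniform grid (right-continuous step convention).

    Returns ``(grid, values)`` where ``grid[j] = j * bin_width`` covers
    the trajectory span (or ``end`` if given).  The grid is used for peak
    *location*; avalanche areas are always computed from the exact event
    record, so the bin width never biases sizes.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(traj.times) == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    stop = traj.times[-1] if end is None else end
    n_bins = int(np.floor(stop / bin_width + 1e-9)) + 1
    grid = np.arange(n_bins) * bin_width
    idx = np.searchsorted(traj.times, grid, side="right") - 1
    vals = np.where(idx >= 0, traj.n[np.clip(idx, 0, None)], 0)
    return grid, vals.astype(np.int64)
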