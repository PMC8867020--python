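"""Synthetic inputs with known ground truth.

Every generator is deterministic given its parameters and seed, and
returns its ground truth alongside the data, so each downstream stage
(segmentation, exponent fitting, frontier extraction) can be tested
without running the full simulator.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParams
from .gillespie import Trajectory
from .avalanche import AvalancheRecord

__all__ = [
    "make_planted_trajectory",
    "sample_power_law",
    "mixture_samples",
    "step_phase_surface",
]

_DUMMY_PARAMS = ModelParams(mu=0.75, nu=0.0, delta=1e-3)


def make_planted_trajectory(
    shapes: list[tuple[int, int]], gap: int = 2, step: float = 1.0
) -> tuple[Trajectory, list[AvalancheRecord]]:
    """Piecewise-constant trajectory of well-separated triangular bumps.

    Each ``(height, width)`` bump rises by unit steps from 0 to
    ``height`` and back, holding each level for ``width`` time units of
    length ``step``, with ``gap`` zero-level steps between bumps.  The
    expected records carry exact step-function areas; expected windows
    run from the first zero sample after the previous bump (or the series
    start) to the first zero sample after the bump, matching the
    leftmost-trough convention of the segmenter.
    """
    if gap < 1:
        raise ValueError("bumps must be separated by at least one zero step (gap >= 1)")
    times = [0.0]
    levels = [0]
    t = 0.0

    def hold(level: int, n_steps: int):
        nonlocal t
        for _ in range(n_steps):
            t += step
            times.append(t)
            levels.append(level)

    expected: list[AvalancheRecord] = []
    prev_trough = 0.0
    for k, (height, width) in enumerate(shapes):
        if height < 1 or width < 1:
            raise ValueError("heights and widths must be >= 1")
        # ascend 1..height then descend back to 1; each level held `width` steps
        profile = list(range(1, height + 1)) + list(range(height - 1, 0, -1))
        area = 0.0
        for lvl in profile:
            area += lvl * width * step
            hold(lvl, width)
        hold(0, 1)
        end_trough = t  # time of the first zero sample after the bump
        expected.append(
            AvalancheRecord(
                start_u=prev_trough, end_u=end_trough,
                size_S=area, peak_value=height,
            )
        )
        prev_trough = end_trough
        if k < len(shapes) - 1:
            hold(0, gap - 1)

    times_arr = np.asarray(times)
    n_arr = np.asarray(levels, dtype=np.int64)
    traj = Trajectory(
        times=times_arr, x=n_arr, y=np.zeros_like(n_arr),
        params=_DUMMY_PARAMS, seed=0, terminated_by="extinction",
        horizon=float(times_arr[-1]) if len(times_arr) else 1.0,
    )
    return traj, expected


def sample_power_law(
    exponent: float, lo: float, n: int, seed: int
) -> np.ndarray:
    """Continuous Pareto samples, density ~ s**(-exponent) on [lo, inf).

    Inverse-transform sampling: ``s = lo * (1 - U) ** (-1/(exponent-1))``.
    """
    if exponent <= 1:
        raise ValueError("exponent must be > 1 for a normalizable tail")
    if lo <= 0:
        raise ValueError("lo must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return lo * (1.0 - u) ** (-1.0 / (exponent - 1.0))


def mixture_samples(
    exponent: float,
    lo: float,
    n_body: int,
    hump_center: float,
    hump_sd: float,
    n_hump: int,
    seed: int,
) -> np.ndarray:
    """Power-law body plus a Gaussian hump near the system size.

    Emulates a bimodal (supercritical) size distribution with known hump
    location; hump samples are truncated below at ``lo``.
    """
    rng = np.random.default_rng(seed)
    body = sample_power_law(exponent, lo, n_body, int(rng.integers(2**31)))
    hump = rng.normal(hump_center, hump_sd, n_hump)
    hump = np.abs(hump)
    hump = np.maximum(hump, lo)
    return np.concatenate([body, hump])


def step_phase_surface(
    nu_axis, nu_edge: float, plateau: float = 1e4, valley: float = 1.0
) -> np.ndarray:
    """Idealized cliff transect: plateau below ``nu_edge``, valley at/above.

    The true frontier crossing is the midpoint of the two grid points
    bracketing ``nu_edge``.
    """
    nu_axis = np.asarray(nu_axis, dtype=float)
    return np.where(nu_axis < nu_edge, plateau, valley)
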