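"""Extinction-time phase map and the transcritical bifurcation locus.

The mean extinction time T of single-spike realizations, mapped over the
(excitation, nu) plane, exhibits a plateau (activity sustained to the
recording cap) separated from a valley (rapid extinction) by a cliff-like
frontier.  The closed-form transcritical bifurcation locus

    2*mu - 1 = (2/3) * sqrt((1 - nu)**3 / (3 * nu))

degenerates to zero excitation as nu -> 1 and passes through
(excitation, nu) = (0.5, 0.25) and (~0.192, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours

from .model import ModelParams
from .gillespie import EnsembleResult, run_ensemble_adaptive

__all__ = [
    "PhaseGrid",
    "bifurcation_locus",
    "t_surface",
    "t_transect",
    "frontier_level",
    "extract_frontier",
    "frontier_crossing",
]


def bifurcation_locus(nu):
    """Excitation 2*mu - 1 on the transcritical bifurcation locus at ``nu``.

    Vectorized over ``nu`` in (0, 1].  Raw values above 1 (small nu) fall
    outside the unit parameter square; they are returned unclipped so the
    caller can flag them — use ``np.clip`` for plotting.
    """
    nu_arr = np.asarray(nu, dtype=float)
    if (nu_arr <= 0).any() or (nu_arr > 1).any():
        raise ValueError("nu must lie in (0, 1]")
    val = (2.0 / 3.0) * np.sqrt((1.0 - nu_arr) ** 3 / (3.0 * nu_arr))
    return float(val) if np.isscalar(nu) else val


@dataclass
class PhaseGrid:
    """Mean extinction time over a rectangular (excitation, nu) grid."""

    excitation_axis: np.ndarray
    nu_axis: np.ndarray
    mean_T: np.ndarray        # shape (len(excitation_axis), len(nu_axis))
    realizations: np.ndarray  # same shape, ensemble sizes actually used
    delta: float
    cap: float
    base_seed: int

    def __post_init__(self):
        expected = (len(self.excitation_axis), len(self.nu_axis))
        if self.mean_T.shape != expected:
            raise ValueError(f"mean_T shape {self.mean_T.shape} != axes {expected}")


def _cell_seed(base_seed: int, i: int, j: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), 7919, i, j]).generate_state(1)[0])


def t_surface(
    excitation_axis,
    nu_axis,
    delta: float,
    cap: float = 1e4,
    base_seed: int = 0,
    batch: int = 8,
    max_realizations: int = 40,
    se_fraction: float = 0.05,
    progress: bool = False,
) -> PhaseGrid:
    """Mean extinction time per grid cell, with adaptive ensemble sizes.

    Every cell derives its own deterministic seed from ``(base_seed, i,
    j)``, so the grid is reproducible cell by cell and refinements reuse
    no randomness.
    """
    excitation_axis = np.asarray(excitation_axis, dtype=float)
    nu_axis = np.asarray(nu_axis, dtype=float)
    mean_T = np.empty((len(excitation_axis), len(nu_axis)))
    nreal = np.empty_like(mean_T, dtype=np.int64)
    for i, exc in enumerate(excitation_axis):
        for j, nu in enumerate(nu_axis):
            params = ModelParams.from_excitation(exc, nu, delta)
            res = run_ensemble_adaptive(
                params, cap=cap, base_seed=_cell_seed(base_seed, i, j),
                batch=batch, max_realizations=max_realizations,
                se_fraction=se_fraction,
            )
            mean_T[i, j] = res.mean_T
            nreal[i, j] = res.realizations
        if progress:
            print(f"excitation {exc:.3f}: done")
    return PhaseGrid(excitation_axis, nu_axis, mean_T, nreal, delta, cap, base_seed)


def t_transect(
    excitation: float,
    nu_axis,
    delta: float,
    cap: float = 1e4,
    base_seed: int = 0,
    **kwargs,
) -> PhaseGrid:
    """One-row phase grid at fixed excitation (a transect across nu)."""
    return t_surface([excitation], nu_axis, delta, cap, base_seed, **kwargs)


def frontier_level(mean_T: np.ndarray) -> float:
    """Automatic contour level separating plateau from valley.

    Cells are split at the mid-range of log T; the level is the geometric
    mean of the plateau median and the valley median.  On a cliff-like
    surface any mid-level rule lands on the same cliff face.
    """
    log_t = np.log(np.maximum(mean_T, 1e-300))
    mid = 0.5 * (log_t.max() + log_t.min())
    plateau = log_t[log_t >= mid]
    valley = log_t[log_t < mid]
    if len(plateau) == 0 or len(valley) == 0:
        raise ValueError("grid does not span both plateau and valley")
    return float(np.exp(0.5 * (np.median(plateau) + np.median(valley))))


def extract_frontier(grid: PhaseGrid, level: float | None = None) -> list[np.ndarray]:
    """Contour polylines of mean T at ``level`` (auto by default).

    Returns a list of arrays of (excitation, nu) vertices, mapped from
    grid indices to axis coordinates by linear interpolation.
    """
    if level is None:
        level = frontier_level(grid.mean_T)
    contours = find_contours(np.log(np.maximum(grid.mean_T, 1e-300)), np.log(level))
    if not contours:
        raise ValueError("no frontier found at the requested level")
    out = []
    for c in contours:
        exc = np.interp(c[:, 0], np.arange(len(grid.excitation_axis)), grid.excitation_axis)
        nu = np.interp(c[:, 1], np.arange(len(grid.nu_axis)), grid.nu_axis)
        out.append(np.column_stack([exc, nu]))
    return out


def frontier_crossing(nu_axis, mean_T, level: float | None = None) -> float:
    """nu at which a transect's mean T crosses the frontier level.

    ``mean_T`` is a 1-D transect over ``nu_axis`` (at fixed excitation).
    The crossing is located by linear interpolation of log T between the
    bracketing grid points; with several crossings the first (lowest nu)
    is returned.
    """
    nu_axis = np.asarray(nu_axis, dtype=float)
    t = np.asarray(mean_T, dtype=float).ravel()
    if level is None:
        level = frontier_level(t)
    log_t = np.log(np.maximum(t, 1e-300))
    log_level = np.log(level)
    above = log_t >= log_level
    for k in range(len(t) - 1):
        if above[k] != above[k + 1]:
            f = (log_level - log_t[k]) / (log_t[k + 1] - log_t[k])
            return float(nu_axis[k] + f * (nu_axis[k + 1] - nu_axis[k]))
    raise ValueError("transect does not cross the frontier level")
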