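"""Two-type contact process for neuronal population activity.

The model tracks the number of currently spiking neurons split by origin:
``x`` spiked from the excited pool, ``y`` from the quiescent pool, with
``N = x + y``.  Spiking neurons recruit new spikes at unit rate per spiking
neuron, biased by the excitation probability ``mu`` toward the excited pool.
Two inhibitory mechanisms remove activity:

* **local** (density-dependent) inhibition with rate coefficient ``delta``;
  ``1/delta`` sets the characteristic system size, and
* **global** (composition-dependent) inhibition with coefficient ``nu``
  modulated by the diversity function :func:`phi`, the Simpson concentration
  of the two spiking subpopulations.

The net population drift is ``dN/du = [1 - delta*N - 2*nu*phi(x, y)] * N``,
with an absorbing state at ``N = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ModelParams",
    "PopulationState",
    "phi",
    "phi_real",
    "event_rates",
    "drift",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    Parameters
    ----------
    mu : float
        Probability that a spiking neuron recruits from the *excited*
        pool; must lie in [1/2, 1].  ``mu`` is the canonical stored
        parameter; the excitation parameter ``2*mu - 1`` is derived.
    nu : float
        Global (composition-dependent) inhibition coefficient, >= 0.
    delta : float
        Local (density-dependent) inhibition coefficient, > 0.  The
        characteristic system size is ``1/delta``.
    """

    mu: float
    nu: float
    delta: float

    def __post_init__(self) -> None:
        if not 0.5 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0.5, 1.0], got {self.mu}")
        if self.nu < 0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")

    @property
    def excitation(self) -> float:
        """Excitation parameter ``2*mu - 1`` in [0, 1]."""
        return 2.0 * self.mu - 1.0

    @property
    def system_size(self) -> float:
        """Characteristic population scale ``1/delta``."""
        return 1.0 / self.delta

    @classmethod
    def from_excitation(cls, excitation: float, nu: float, delta: float) -> "ModelParams":
        """Construct from the excitation parameter ``2*mu - 1``."""
        if not 0.0 <= excitation <= 1.0:
            raise ValueError(f"excitation must lie in [0, 1], got {excitation}")
        return cls(mu=(1.0 + excitation) / 2.0, nu=nu, delta=delta)


@dataclass(frozen=True)
class PopulationState:
    """Counts of spiking neurons by origin (``x`` excited, ``y`` quiescent)."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"counts must be nonnegative, got ({self.x}, {self.y})")

    @property
    def n(self) -> int:
        """Total number of spiking neurons."""
        return self.x + self.y


def phi(x: int, y: int) -> float:
    """Diversity-driven global-inhibition factor for integer counts.

    For any population of two or more spiking neurons this is the Simpson
    concentration index of the two subpopulations,
    ``(x*(x-1) + y*(y-1)) / ((x+y)*(x+y-1))`` — the probability that two
    spiking neurons drawn without replacement share an origin.  It equals
    1 for a pure population (one pool empty), ``(n-1)/(2n-1) -> 1/2`` on
    the balanced diagonal, and 0 at the minimal mixed state (1, 1): a
    pure population drives a feedback twice as strong as a perfectly
    mixed one.

    The index is undefined (0/0) for a single spike; we complete it by
    the pure-population limit, ``phi = 1`` at ``N = 1``, so that global
    inhibition already acts on a lone trigger spike and extinction from
    ``N = 1`` occurs at rate ``nu`` rather than only through the much
    slower local channel.  ``phi = 0`` at ``N = 0`` (no population, no
    feedback).  Symmetric in its arguments and bounded in [0, 1].
    """
    if x < 0 or y < 0:
        raise ValueError(f"counts must be nonnegative, got ({x}, {y})")
    n = x + y
    if n == 0:
        return 0.0
    if n == 1:
        return 1.0
    return (x * (x - 1) + y * (y - 1)) / (n * (n - 1))


def phi_real(x: float, y: float) -> float:
    """Single-valued extension of :func:`phi` to real arguments.

    Uses the Simpson-index branch whenever ``x + y > 1`` and 0 otherwise;
    this is the selection integrated by the deterministic (mean-field)
    solver.  The discontinuity set has measure zero and is never resolved
    by an adaptive integrator in practice.
    """
    if x < 0 or y < 0:
        raise ValueError(f"arguments must be nonnegative, got ({x}, {y})")
    n = x + y
    if n <= 1.0:
        return 0.0
    return (x * (x - 1.0) + y * (y - 1.0)) / (n * (n - 1.0))


def event_rates(state: PopulationState, params: ModelParams) -> tuple[float, float, float, float]:
    """Rates of the four elementary event channels.

    Returns ``(birth_x, birth_y, death_x, death_y)``:

    * ``birth_x = mu * N`` — a spiking neuron recruits an excited neuron,
    * ``birth_y = (1 - mu) * N`` — recruitment from the quiescent pool,
    * ``death_x = (delta * x + nu * phi(x, y)) * N`` — an x-origin spike
      silenced by local or global inhibition,
    * ``death_y = (delta * y + nu * phi(x, y)) * N``.

    This is the minimal decomposition in which every term of the net
    drift is a distinct elementary event.  A death channel can only
    remove an existing spike: when one pool is empty its death rate is
    zero (the global-inhibition term has no victim there), so counts can
    never go negative.  On every state with both pools occupied the
    signed channel rates sum exactly to the net population drift
    ``[1 - delta*N - 2*nu*phi] * N``.  All rates vanish at ``N = 0``
    (absorbing state).
    """
    n = state.n
    if n == 0:
        return (0.0, 0.0, 0.0, 0.0)
    p = phi(state.x, state.y)
    death_x = (params.delta * state.x + params.nu * p) * n if state.x > 0 else 0.0
    death_y = (params.delta * state.y + params.nu * p) * n if state.y > 0 else 0.0
    return (params.mu * n, (1.0 - params.mu) * n, death_x, death_y)


def drift(x: float, y: float, params: ModelParams) -> tuple[float, float]:
    """Deterministic drift of the real-valued (mean-field) dynamics.

    ``dx/du = (mu - delta*x - nu*phi) * N`` and
    ``dy/du = (1 - mu - delta*y - nu*phi) * N`` with ``N = x + y`` and
    :func:`phi_real` as the inhibition factor.
    """
    p = phi_real(x, y)
    n = x + y
    return (
        (params.mu - params.delta * x - params.nu * p) * n,
        ((1.0 - params.mu) - params.delta * y - params.nu * p) * n,
    )
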