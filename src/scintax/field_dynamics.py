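"""Intentional planning fields over normalized tract-variable axes.

An intentional planning field is a 1-D distribution of activation u(x) over
a tract-variable parameter axis x in [0, 1].  Gestural systems exert signed
Gaussian force distributions on the field; activation decays at rate alpha
and is clamped non-negative after every step.  The activation centroid is
read out as the *dynamic target* that drives the tract variable.

The field obeys

    du/dt = -alpha * u(x) + F(x, t),        u(x, t) >= 0,

with F the summed (gated, weighted, signed) gestural forces plus the
constant neutral-attractor force.  The default integrator treats the force
as constant over a step and advances the linear part exactly
(exponential-Euler); an explicit Euler scheme is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace

import numpy as np

from .errors import DegenerateFieldError, IntegrationError, ParameterError

__all__ = [
    "IntentionalField",
    "NeutralAttractor",
    "make_grid",
    "unit_peak_gaussian",
    "field_step",
    "centroid_target",
    "steady_state_field",
]

DEFAULT_N_GRID = 101


def make_grid(n_grid: int = DEFAULT_N_GRID) -> np.ndarray:
    """Uniform, strictly increasing grid spanning [0, 1]."""
    if n_grid < 2:
        raise ParameterError(f"n_grid must be >= 2, got {n_grid}")
    return np.linspace(0.0, 1.0, n_grid)


def unit_peak_gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Gaussian with maximum value 1 at x = mu.

    Unit-peak (not unit-area) normalization makes a gesture's weight read
    directly as its maximal force amplitude.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class NeutralAttractor:
    """Constant, ungated excitatory force drawing a field toward rest.

    The neutral attractor is a permanent Gaussian force on the field: it is
    never gated and its strength is constant over an utterance.  A positive
    strength guarantees total field activation never reaches zero, so the
    centroid readout is always defined.
    """

    center: float = 0.5
    width: float = 0.1
    strength: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 1.0:
            raise ParameterError(f"neutral attractor center must be in [0,1], got {self.center}")
        if self.width <= 0:
            raise ParameterError(f"neutral attractor width must be > 0, got {self.width}")
        if self.strength <= 0:
            raise ParameterError(
                f"neutral attractor strength must be > 0, got {self.strength}"
            )

    def force(self, grid: np.ndarray) -> np.ndarray:
        return self.strength * unit_peak_gaussian(grid, self.center, self.width)


@dataclass(frozen=True)
class IntentionalField:
    """Discretized activation distribution over one tract-variable axis.

    Parameters
    ----------
    tract_variable_id : str
        Identifier of the tract variable this field plans (e.g. ``"VEL"``).
    grid : ndarray
        Strictly increasing sample points spanning [0, 1].
    u : ndarray
        Non-negative activation per grid point (dimensionless).
    alpha : float
        Decay gain (1/ms).  Sets the field's relaxation time 1/alpha.
    beta_plus, beta_minus : float
        Gains on the summed excitatory and inhibitory gestural forces.
    """

    tract_variable_id: str
    grid: np.ndarray = _dc_field(default_factory=make_grid)
    u: np.ndarray | None = None
    alpha: float = 0.05
    beta_plus: float = 1.0
    beta_minus: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ParameterError("grid must be a strictly increasing 1-D array")
        if not (np.isclose(grid[0], 0.0) and np.isclose(grid[-1], 1.0)):
            raise ParameterError("grid must span [0, 1]")
        u = self.u
        u = np.zeros_like(grid) if u is None else np.asarray(u, dtype=float)
        object.__setattr__(self, "u", u)
        if u.shape != grid.shape:
            raise ParameterError("u must have the same shape as grid")
        if np.any(u < 0):
            raise ParameterError("field activation u must be non-negative")
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")

    @property
    def n_grid(self) -> int:
        return int(self.grid.size)


def _check_force(force: np.ndarray, field: IntentionalField) -> np.ndarray:
    force = np.asarray(force, dtype=float)
    if force.shape != field.grid.shape:
        raise IntegrationError(
            f"force length {force.shape} does not match field grid {field.grid.shape}"
        )
    bad = ~np.isfinite(force)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise IntegrationError(
            f"non-finite force value at grid index {idx} "
            f"(x={field.grid[idx]:.4f}) on field '{field.tract_variable_id}'"
        )
    return force


def field_step(
    field: IntentionalField,
    total_force: np.ndarray,
    dt: float,
    scheme: str = "exponential",
) -> IntentionalField:
    """Advance the field one time step under a constant total force.

    The non-negativity condition u >= 0 is imposed after the full step.
    ``scheme="exponential"`` (default) advances the decay exactly and is
    unconditionally stable; ``scheme="euler"`` is the plain explicit update
    u + dt*(-alpha*u + F).  Returns a new field; the input is not mutated.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    force = _check_force(total_force, field)
    if scheme == "exponential":
        decay = np.exp(-field.alpha * dt)
        u_new = field.u * decay + force * (1.0 - decay) / field.alpha
    elif scheme == "euler":
        u_new = field.u + dt * (-field.alpha * field.u + force)
    else:
        raise ParameterError(f"unknown integration scheme {scheme!r}")
    np.clip(u_new, 0.0, None, out=u_new)
    return replace(field, u=u_new)


def centroid_target(field: IntentionalField) -> float:
    """Activation-weighted mean parameter value (the dynamic target).

    T = sum(x * u(x)) / sum(u(x)).  Raises if total activation is zero,
    which a configured neutral attractor makes unreachable.
    """
    total = float(np.sum(field.u))
    if total <= 0.0:
        raise DegenerateFieldError(
            f"field '{field.tract_variable_id}' has zero total activation; "
            "centroid target is undefined (is the neutral attractor missing?)"
        )
    return float(np.dot(field.grid, field.u) / total)


def steady_state_field(
    forces: np.ndarray,
    alpha: float,
    tract_variable_id: str = "TV",
    grid: np.ndarray | None = None,
    **kwargs,
) -> IntentionalField:
    """Fixed point of the field equation under constant forcing.

    With constant force F the field relaxes to u* = clamp0(F / alpha); this
    closed form is the analytic oracle for the time-stepped integrator.
    """
    if alpha <= 0:
        raise ParameterError(f"alpha must be > 0, got {alpha}")
    forces = np.asarray(forces, dtype=float)
    if grid is None:
        grid = make_grid(forces.size)
    u_star = np.clip(forces / alpha, 0.0, None)
    return IntentionalField(
        tract_variable_id=tract_variable_id, grid=grid, u=u_star, alpha=alpha, **kwargs
    )
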