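"""Second-order tract-variable dynamics and the legacy blending rule.

Each tract variable x follows a damped mass-spring (point-attractor) law

    x'' = k * (T - x) - b * x'

driven by the dynamic target T(t).  In the full model T is produced
exclusively by the intentional-field centroid readout; the weighted-average
blending rule ``blend_targets`` is retained as the baseline mechanism it
replaces, for comparison and worked examples.

The default stepper advances the linear system exactly over a step
(piecewise-constant T) using the cached matrix exponential, so a constant-T
trajectory matches the closed-form damped response to machine precision and
critical damping shows zero overshoot.  A semi-implicit Euler scheme is
available for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from .errors import ParameterError, PropagationError, UndefinedBlendError

__all__ = ["TractVariableState", "td_step", "blend_targets", "critical_damping"]

#: Default stiffness (1/ms^2): ~100 ms to 90% of a step under critical damping.
DEFAULT_STIFFNESS = 0.0015


def critical_damping(stiffness_k: float) -> float:
    """Damping gain b = 2*sqrt(k) at which the step response is monotone."""
    if stiffness_k <= 0:
        raise ParameterError(f"stiffness_k must be > 0, got {stiffness_k}")
    return 2.0 * math.sqrt(stiffness_k)


@dataclass(frozen=True)
class TractVariableState:
    """State of one tract variable: value, velocity, and gains.

    ``damping=None`` selects critical damping 2*sqrt(k).
    """

    tract_variable_id: str
    value: float = 0.0
    velocity: float = 0.0
    stiffness_k: float = DEFAULT_STIFFNESS
    damping: float | None = None

    def __post_init__(self) -> None:
        if self.stiffness_k <= 0:
            raise ParameterError(f"stiffness_k must be > 0, got {self.stiffness_k}")
        if self.damping is None:
            object.__setattr__(self, "damping", critical_damping(self.stiffness_k))
        if self.damping < 0:
            raise ParameterError(f"damping must be >= 0, got {self.damping}")
        if not (math.isfinite(self.value) and math.isfinite(self.velocity)):
            raise ParameterError(
                f"tract variable {self.tract_variable_id} state must be finite"
            )


@lru_cache(maxsize=256)
def _propagator(k: float, b: float, dt: float) -> tuple[float, float, float, float]:
    """exp(A*dt) for A = [[0, 1], [-k, -b]] acting on [x - T, v]."""
    m = expm(np.array([[0.0, 1.0], [-k, -b]]) * dt)
    return (float(m[0, 0]), float(m[0, 1]), float(m[1, 0]), float(m[1, 1]))


def td_step(
    state: TractVariableState,
    T: float,
    dt: float,
    scheme: str = "exact",
) -> TractVariableState:
    """Advance the tract variable one step toward dynamic target T.

    The equilibrium of the update is x = T, v = 0 for constant T.  Raises
    :class:`PropagationError` naming the source field if T is non-finite.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    if not math.isfinite(T):
        raise PropagationError(
            f"non-finite dynamic target ({T!r}) propagated from field "
            f"'{state.tract_variable_id}'"
        )
    k, b = state.stiffness_k, state.damping
    if scheme == "exact":
        a11, a12, a21, a22 = _propagator(k, b, dt)
        dx = state.value - T
        new_dx = a11 * dx + a12 * state.velocity
        new_v = a21 * dx + a22 * state.velocity
        return replace(state, value=T + new_dx, velocity=new_v)
    if scheme == "semi_implicit":
        v = state.velocity + dt * (k * (T - state.value) - b * state.velocity)
        x = state.value + dt * v
        return replace(state, value=x, velocity=v)
    raise ParameterError(f"unknown integration scheme {scheme!r}")


def blend_targets(targets, weights) -> float:
    """Weighted-average blended target T = sum(T_i w_i) / sum(w_i).

    The baseline target-composition rule for co-active gestures.  Negative
    weights are admitted (they produce dissimilatory, even hyper-assimilatory
    blends), but the blend is undefined when the weights cancel: a zero
    weight sum raises :class:`UndefinedBlendError` explicitly.
    """
    t = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise ParameterError("targets and weights must be 1-D sequences of equal length")
    if t.size == 0:
        raise ParameterError("blend_targets requires at least one target")
    total = float(np.sum(w))
    if total == 0.0:
        raise UndefinedBlendError(
            "blending weights sum to zero; the weighted-average target is undefined"
        )
    return float(np.dot(t, w) / total)
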