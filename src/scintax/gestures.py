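"""Excitatory/inhibitory gestural systems and their force distributions.

An Articulatory-Phonology "gesture" is represented here as a +/- pair of
gestural systems acting on the same intentional planning field: the
excitatory member drives activation toward its target region, the
inhibitory member suppresses activation in a complementary region.  The
two members may share one excitation trace but can be dissociated.

A gesture's force on its field is

    +/- weight * G(e) * N(x; mu, sigma)

where G is a logistic gating function of the gesture's excitation e and N
is a unit-peak Gaussian.  "Strong" gating passes negligible force below
the selection threshold; "leaky" gating passes substantial sub-threshold
force, which is what produces anticipatory posturing and agreement
harmonies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np

from .errors import ContractError, ParameterError, WiringError
from .field_dynamics import IntentionalField, unit_peak_gaussian

__all__ = [
    "GatingFunction",
    "strong_gating",
    "leaky_gating",
    "Gesture",
    "ExcitationTrace",
    "gate",
    "gesture_force",
    "is_antagonist",
]

#: Default selection threshold on the excitation scale.
SELECTION_THRESHOLD = 0.9


@dataclass(frozen=True)
class GatingFunction:
    """Logistic map from excitation to force amplitude in (0, 1).

    amplitude = 1 / (1 + exp(-slope * (e - midpoint)))

    Strictly increasing in excitation for slope > 0.  Midpoint and slope
    are both free: raising the midpoint or steepening the slope makes the
    gate "stronger" (less sub-threshold leak).
    """

    midpoint: float
    slope: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ParameterError(f"gating slope must be > 0, got {self.slope}")

    def __call__(self, e: float | np.ndarray) -> float | np.ndarray:
        out = 1.0 / (1.0 + np.exp(-self.slope * (np.asarray(e, dtype=float) - self.midpoint)))
        return float(out) if out.ndim == 0 else out


def strong_gating(threshold: float = SELECTION_THRESHOLD, slope: float = 50.0) -> GatingFunction:
    """Gate centered at the selection threshold with a steep slope."""
    return GatingFunction(midpoint=threshold, slope=slope)


def leaky_gating(
    threshold: float = SELECTION_THRESHOLD, drop: float = 0.3, slope: float = 10.0
) -> GatingFunction:
    """Gate with lowered midpoint and shallow slope: sub-threshold leak."""
    return GatingFunction(midpoint=threshold - drop, slope=slope)


def gate(g: GatingFunction, e: float) -> float:
    """Force amplitude in (0, 1) for excitation e."""
    return float(g(e))


@dataclass(frozen=True)
class Gesture:
    """One excitatory (+) or inhibitory (-) gestural force source.

    Parameters
    ----------
    id : str
        Identifier, conventionally "<TV> <label><polarity>", e.g. "VEL op+".
    tract_variable_id : str
        Field the gesture forces.
    polarity : str
        "+" (excitatory) or "-" (inhibitory); fixed for the gesture's life.
    mu, sigma : float
        Center and width of the Gaussian force distribution in field
        coordinates.  Inhibitory distributions are conventionally broader
        than their paired excitatory ones (about 2x by default in the
        scenario library).
    weight : float
        Connectivity weight >= 0; maximal force amplitude when fully gated.
    gating : GatingFunction
        Sigmoid gate from excitation to amplitude.
    target_value : float | None
        Canonical achieved tract-variable value, used for achievement
        detection; defaults to mu for + gestures.
    pair_id : str | None
        Shared identifier linking the +/- members of one AP gesture.
    """

    id: str
    tract_variable_id: str
    polarity: str
    mu: float
    sigma: float
    weight: float = 1.0
    gating: GatingFunction = _dc_field(default_factory=strong_gating)
    target_value: float | None = None
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ParameterError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ParameterError(f"gesture {self.id}: mu must be in [0,1], got {self.mu}")
        if self.sigma <= 0:
            raise ParameterError(f"gesture {self.id}: sigma must be > 0, got {self.sigma}")
        if self.weight < 0:
            raise ParameterError(f"gesture {self.id}: weight must be >= 0, got {self.weight}")
        if self.target_value is None and self.polarity == "+":
            object.__setattr__(self, "target_value", self.mu)

    @property
    def excitatory(self) -> bool:
        return self.polarity == "+"


@dataclass(frozen=True)
class ExcitationTrace:
    """Excitation value per time step for one gestural system, in [0, 1]."""

    gesture_id: str
    times: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "e", e)
        if times.shape != e.shape:
            raise ParameterError("excitation trace times and values must align")
        if np.any((e < 0) | (e > 1)):
            raise ParameterError(
                f"excitation values for {self.gesture_id} must lie in [0, 1]"
            )


def gesture_force(
    gesture: Gesture, e: float, grid: np.ndarray, field: IntentionalField | None = None
) -> np.ndarray:
    """Signed force distribution the gesture exerts at excitation e.

    Positive everywhere for + gestures, negative for - gestures.  If the
    receiving field is supplied, its tract variable must match.
    """
    if field is not None and field.tract_variable_id != gesture.tract_variable_id:
        raise WiringError(
            f"gesture {gesture.id} targets tract variable "
            f"'{gesture.tract_variable_id}' but was applied to field "
            f"'{field.tract_variable_id}'"
        )
    sign = 1.0 if gesture.excitatory else -1.0
    amp = gesture.weight * gate(gesture.gating, e)
    return sign * amp * unit_peak_gaussian(grid, gesture.mu, gesture.sigma)


def is_antagonist(
    g_inh: Gesture,
    g_exc: Gesture,
    declared: set[tuple[str, str]] | None = None,
) -> bool:
    """Whether the inhibitory gesture antagonizes the excitatory one.

    True iff both act on the same tract variable and the inhibitory force
    distribution overlaps the region the excitatory gesture most strongly
    excites: |mu_inh - mu_exc| < sigma_inh + sigma_exc.  An explicit
    ``declared`` set of (inhibitor_id, excitor_id) pairs from config
    augments the geometric rule.
    """
    if g_inh.polarity != "-" or g_exc.polarity != "+":
        raise ContractError(
            "is_antagonist expects an inhibitory first argument and an "
            f"excitatory second argument, got {g_inh.id}({g_inh.polarity}) "
            f"and {g_exc.id}({g_exc.polarity})"
        )
    if declared and (g_inh.id, g_exc.id) in declared:
        return True
    if g_inh.tract_variable_id != g_exc.tract_variable_id:
        return False
    return abs(g_inh.mu - g_exc.mu) < (g_inh.sigma + g_exc.sigma)
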