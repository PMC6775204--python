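"""Outcome metrics: assimilation indices, shifts vs. control, and the
spreading/blocking/agreement classifier.

All metrics compare a simulation run against a *control* run generated
from the same scenario with the manipulated (trigger/distractor) gestures
deleted, all else fixed.  Shifts are oriented so that displacement toward
the trigger's target is positive (assimilation) and displacement away is
negative (dissimilation).

The harmony classifier distinguishes the two mechanisms for non-local
patterns: *spreading* (the trigger gesture is selected outside its
canonical epoch, via a dissociation directive), *blocked* (a dissociation
was refused because an antagonist was selected), and *agreement* (the
trigger is never selected out of epoch, but its sub-threshold leaky-gated
force displaces the dynamic target in some other epoch).  Epochs in which
an antagonist is selected and the displacement stays below tolerance are
flagged transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .gestures import is_antagonist
from .scenarios import SimulationResult

__all__ = [
    "AssimilationIndex",
    "OutcomeReport",
    "assimilation_index",
    "shift_vs_control",
    "classify_harmony_outcome",
]

#: Below this oriented target displacement (field units) an epoch counts as
#: unaffected; sits between integration noise and the smallest demonstrated
#: leaky-gating shift.
DEFAULT_TOL = 0.01

#: Fraction of each epoch (its final part) used as the measurement window,
#: so that field transients from the previous epoch have decayed.
EPOCH_WINDOW_FRAC = 1.0 / 3.0


@dataclass(frozen=True)
class AssimilationIndex:
    """Fractional progress from a neutral value toward a gestural target.

    0 = at neutral, 1 = at target.  ``value`` is clipped to [-1, 2] for
    reporting; ``raw`` retains the unclipped quantity.
    """

    raw: float
    value: float

    def __float__(self) -> float:
        return self.value


def assimilation_index(
    observed: float, neutral_value: float, gesture_target: float
) -> AssimilationIndex:
    """(observed - neutral) / (target - neutral), clip-reported on [-1, 2]."""
    denom = gesture_target - neutral_value
    if denom == 0:
        raise ContractError(
            "assimilation index undefined: neutral value equals the gesture target"
        )
    raw = (observed - neutral_value) / denom
    return AssimilationIndex(raw=raw, value=float(np.clip(raw, -1.0, 2.0)))


def shift_vs_control(
    result: SimulationResult,
    control_result: SimulationResult,
    field_id: str,
    window: tuple[float, float],
    orient_toward: float | None = None,
) -> float:
    """Mean dynamic-target displacement of a run vs. its control.

    Averages T_result - T_control over the window.  If ``orient_toward``
    (the distractor/trigger target) is given, the sign is flipped when the
    trigger target lies below the control baseline, so that positive always
    means displacement toward the trigger.
    """
    if result.times.shape != control_result.times.shape or not np.allclose(
        result.times, control_result.times
    ):
        raise ContractError(
            "result and control runs do not share a time base; "
            "controls must be run on the identical timeline"
        )
    t0, t1 = window
    mask = result.window_mask(t0, t1)
    if not mask.any():
        raise ContractError(f"empty measurement window [{t0}, {t1})")
    raw = float(
        np.mean(result.targets[field_id][mask] - control_result.targets[field_id][mask])
    )
    if orient_toward is None:
        return raw
    baseline = float(np.mean(control_result.targets[field_id][mask]))
    return raw if orient_toward >= baseline else -raw


@dataclass(frozen=True)
class OutcomeReport:
    """Classification of a run plus per-epoch diagnostics.

    classification is exactly one of {"spreading", "blocked", "agreement",
    "none"}.  ``per_epoch_shift`` holds the oriented target displacement of
    each epoch's settled window; ``transparent_epochs`` are epochs where an
    antagonist of the trigger was selected and the displacement stayed
    within tolerance.
    """

    classification: str
    trigger_gesture_id: str
    canonical_epoch: int
    selected_epochs: tuple[int, ...]
    per_epoch_shift: dict[int, float]
    assimilation: dict[int, AssimilationIndex]
    transparent_epochs: tuple[int, ...]
    tol: float


def classify_harmony_outcome(
    result: SimulationResult,
    control_result: SimulationResult,
    trigger_gesture_id: str,
    tol: float = DEFAULT_TOL,
    window_frac: float = EPOCH_WINDOW_FRAC,
) -> OutcomeReport:
    """Classify a run as spreading, blocked, agreement, or none.

    - spreading: the trigger is selected outside its canonical epoch;
    - blocked: a dissociation directive for the trigger was refused by the
      antagonist blocking rule and no out-of-epoch selection occurred;
    - agreement: never selected out of epoch, but the oriented target
      displacement exceeds ``tol`` in at least one non-canonical epoch;
    - none: otherwise.
    """
    trace = result.selection_trace
    if trace is None:
        raise ContractError("classification requires a word-form run with a selection trace")
    inv = result.scenario.inventory_map
    if trigger_gesture_id not in inv:
        raise ContractError(f"trigger gesture '{trigger_gesture_id}' not in the inventory")
    trigger = inv[trigger_gesture_id]
    try:
        canonical = trace.word_form.rank_of(trigger_gesture_id)
    except Exception as exc:
        raise ContractError(
            f"trigger gesture '{trigger_gesture_id}' has no canonical epoch "
            "in the word form"
        ) from exc

    fid = trigger.tract_variable_id
    neutral = result.scenario.field_spec(fid).neutral.center
    target = trigger.target_value if trigger.target_value is not None else trigger.mu
    declared = set(result.scenario.declared_antagonists) or None

    per_epoch_shift: dict[int, float] = {}
    assim: dict[int, AssimilationIndex] = {}
    antagonist_in: dict[int, bool] = {}
    for ep in trace.epochs:
        w0 = ep.end - (ep.end - ep.start) * window_frac
        per_epoch_shift[ep.index] = shift_vs_control(
            result, control_result, fid, (w0, ep.end), orient_toward=target
        )
        assim[ep.index] = assimilation_index(
            result.mean_target(fid, w0, ep.end), neutral, target
        )
        antagonist_in[ep.index] = any(
            inv[gid].polarity == "-" and is_antagonist(inv[gid], trigger, declared)
            for gid in ep.members
            if gid in inv and gid != trigger_gesture_id
        )

    selected = tuple(trace.selected_epochs(trigger_gesture_id))
    out_of_epoch = [k for k in selected if k != canonical]
    refused = any(
        ev.gesture_id == trigger_gesture_id and ev.reason == "antagonist"
        for ev in trace.events
    )
    shifted = [
        k for k, s in per_epoch_shift.items() if k != canonical and abs(s) > tol
    ]
    if out_of_epoch:
        classification = "spreading"
    elif refused:
        classification = "blocked"
    elif shifted:
        classification = "agreement"
    else:
        classification = "none"

    transparent = tuple(
        k
        for k in per_epoch_shift
        if antagonist_in[k] and abs(per_epoch_shift[k]) <= tol
    )
    return OutcomeReport(
        classification=classification,
        trigger_gesture_id=trigger_gesture_id,
        canonical_epoch=canonical,
        selected_epochs=selected,
        per_epoch_shift=per_epoch_shift,
        assimilation=assim,
        transparent_epochs=transparent,
        tol=tol,
    )
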