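"""Competitive selection of gesture sets in a step potential.

A word form is an ordered list of competitively selected gesture sets
(roughly, syllables).  Before the response, the sets hold a stable ladder
of sub-threshold excitation levels ordered by canonical rank.  Response
initiation promotes the first set above the selection threshold; feedback
about target achievement triggers reorganizations in which the selected
set is demoted to the lowest level and the next set is promoted.  The
cycle iterates until every set has been selected and suppressed.

Individual gestures can dissociate from their set's schedule: *early
promotion* selects a gesture one or more epochs before its canonical
epoch, *late demotion* keeps it selected afterwards.  Dissociated
selection of an excitatory gesture is refused in any epoch in which an
antagonistic inhibitory gesture is selected (the blocking rule); because a
dissociation can only extend a gesture's single selected interval, refusal
in a middle epoch truncates the span so that per-gesture selected time
remains one contiguous interval.

Epoch boundaries come from one of three feedback regimes: ``external``
(reorganize a fixed delay after sensed target achievement), ``internal``
(reorganize a fixed lead *before* predicted achievement, allowing
anticipatory overlap), or ``fixed_epochs`` (scripted durations).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Protocol, Sequence

import numpy as np

from .errors import ConfigError, ContractError, UnachievedTargetError
from .gestures import ExcitationTrace, Gesture, is_antagonist

__all__ = [
    "GestureSet",
    "WordForm",
    "DissociationDirective",
    "SelectionConfig",
    "SelectionState",
    "BlockEvent",
    "EpochRecord",
    "SelectionTrace",
    "EpochMonitor",
    "init_hierarchy",
    "reorganize",
    "check_blocking",
    "epoch_membership",
    "excitation_levels",
    "run_selection",
    "excitation_trace",
]

FEEDBACK_MODES = ("external", "internal", "fixed_epochs")
DISSOCIATION_MODES = ("early_promotion", "late_demotion")


@dataclass(frozen=True)
class GestureSet:
    """A competitively selected set of gestures with a canonical rank."""

    id: str
    member_gesture_ids: tuple[str, ...]
    canonical_rank: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_gesture_ids", tuple(self.member_gesture_ids))
        if not self.member_gesture_ids:
            raise ConfigError(f"gesture set '{self.id}' has no members")
        if self.canonical_rank < 1:
            raise ConfigError(
                f"gesture set '{self.id}': canonical_rank must be >= 1"
            )


@dataclass(frozen=True)
class DissociationDirective:
    """Early promotion or late demotion of one gesture, spanning >= 1 epochs."""

    gesture_id: str
    mode: str
    span: int = 1

    def __post_init__(self) -> None:
        if self.mode not in DISSOCIATION_MODES:
            raise ConfigError(
                f"directive for '{self.gesture_id}': mode must be one of "
                f"{DISSOCIATION_MODES}, got {self.mode!r}"
            )
        if self.span < 1:
            raise ConfigError(
                f"directive for '{self.gesture_id}': span must be >= 1, got {self.span}"
            )


@dataclass(frozen=True)
class WordForm:
    """Ordered gesture sets plus dissociation directives."""

    sets: tuple[GestureSet, ...]
    dissociations: tuple[DissociationDirective, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        object.__setattr__(self, "dissociations", tuple(self.dissociations))
        if not self.sets:
            raise ConfigError("word form has no gesture sets")
        ranks = [s.canonical_rank for s in self.sets]
        if sorted(ranks) != list(range(1, len(self.sets) + 1)):
            raise ConfigError(
                f"canonical ranks must be a permutation of 1..{len(self.sets)}, got {ranks}"
            )
        if ranks != sorted(ranks):
            raise ConfigError("word form sets must be listed in canonical rank order")
        seen: dict[str, str] = {}
        for s in self.sets:
            for gid in s.member_gesture_ids:
                if gid in seen:
                    raise ConfigError(
                        f"gesture '{gid}' appears in sets '{seen[gid]}' and '{s.id}'; "
                        "membership must be unique"
                    )
                seen[gid] = s.id
        for d in self.dissociations:
            if d.gesture_id not in seen:
                raise ConfigError(
                    f"directive references gesture '{d.gesture_id}' which is in no set"
                )

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def gesture_ids(self) -> list[str]:
        return [gid for s in self.sets for gid in s.member_gesture_ids]

    def rank_of(self, gesture_id: str) -> int:
        for s in self.sets:
            if gesture_id in s.member_gesture_ids:
                return s.canonical_rank
        raise ConfigError(f"gesture '{gesture_id}' is in no set of this word form")


@dataclass(frozen=True)
class SelectionConfig:
    """Level ladder, feedback timing, and achievement-detection parameters.

    The ladder is ordinal in the model; the numeric values matter only
    through the gating function.  The default queue levels sit 0.3+ below
    the threshold so a strongly gated queued gesture leaks negligible force
    while a leaky-gated one leaks substantially.
    """

    threshold: float = 0.9
    selected_level: float = 1.0
    queue_levels: tuple[float, ...] = (0.6, 0.45, 0.3)
    suppressed_level: float = 0.1
    max_sets: int = 8
    achievement_eps: float = 0.05
    sustain_ms: float = 10.0
    external_delay_ms: float = 50.0
    internal_lead_ms: float = 60.0
    min_epoch_ms: float = 1.0
    timeout_ms: float = 2000.0
    epoch_ms: float | tuple[float, ...] = 150.0
    ramp_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.selected_level > self.threshold:
            raise ConfigError("selected_level must exceed the selection threshold")
        levels = (self.selected_level, *self.queue_levels, self.suppressed_level)
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ConfigError(
                "levels must be strictly decreasing: selected > queue... > suppressed"
            )
        if any(q > self.threshold for q in self.queue_levels):
            raise ConfigError("queue levels must not exceed the selection threshold")

    def queue_level(self, offset: int) -> float:
        """Sub-threshold level for a set `offset` ranks behind the next one."""
        if offset < 0:
            raise ConfigError(f"queue offset must be >= 0, got {offset}")
        return self.queue_levels[min(offset, len(self.queue_levels) - 1)]

    def epoch_duration(self, epoch_index: int) -> float:
        if isinstance(self.epoch_ms, (int, float)):
            return float(self.epoch_ms)
        return float(self.epoch_ms[epoch_index - 1])


@dataclass(frozen=True)
class SelectionState:
    """Excitation level per gesture at one epoch of the step potential."""

    epoch_index: int
    level_of: dict[str, float]
    threshold: float

    def selected(self, gesture_id: str) -> bool:
        return self.level_of.get(gesture_id, 0.0) > self.threshold

    def selected_ids(self) -> frozenset[str]:
        return frozenset(g for g, lv in self.level_of.items() if lv > self.threshold)


@dataclass(frozen=True)
class BlockEvent:
    """A refused dissociated selection (and why)."""

    gesture_id: str
    epoch: int
    reason: str  # "antagonist" | "contiguity" | "paired"


@dataclass(frozen=True)
class EpochRecord:
    index: int
    start: float
    end: float
    members: frozenset[str]
    boundary_event: str  # "external_feedback" | "internal_feedback" | "forced"


@dataclass(frozen=True)
class SelectionTrace:
    """Selected intervals per gesture plus the epoch schedule and event log."""

    word_form: WordForm
    epochs: tuple[EpochRecord, ...]
    intervals: dict[str, tuple[tuple[float, float], ...]]
    events: tuple[BlockEvent, ...]

    @property
    def t_start(self) -> float:
        return self.epochs[0].start

    @property
    def t_end(self) -> float:
        return self.epochs[-1].end

    def selected_epochs(self, gesture_id: str) -> list[int]:
        return [e.index for e in self.epochs if gesture_id in e.members]


class EpochMonitor(Protocol):
    """Supplies per-set target-achievement times to :func:`run_selection`.

    The coupled simulator implements this over live field/tract dynamics;
    tests may script it.  ``run_epoch`` advances from ``t_start`` under the
    given excitations and returns the detected achievement time (or None on
    timeout); ``advance_to``/``rewind_to`` move the monitor's clock to the
    chosen epoch boundary.
    """

    def run_epoch(
        self,
        epoch_index: int,
        members: frozenset[str],
        excitations: dict[str, float],
        t_start: float,
        timeout_ms: float,
    ) -> float | None: ...

    def advance_to(self, t: float, excitations: dict[str, float]) -> None: ...

    def rewind_to(self, t: float) -> None: ...


def check_blocking(
    candidate: str,
    epoch_members: frozenset[str] | set[str],
    inventory: dict[str, Gesture],
    declared: set[tuple[str, str]] | None = None,
) -> str:
    """Whether a + gesture may be dissociatedly selected into an epoch.

    Returns ``"blocked"`` iff any selected inhibitory gesture in the epoch
    is an antagonist of the candidate, else ``"allowed"``.
    """
    g = inventory[candidate]
    if g.polarity != "+":
        raise ContractError(
            f"check_blocking applies to excitatory gestures; '{candidate}' is '-'"
        )
    for gid in epoch_members:
        if gid == candidate:
            continue
        other = inventory[gid]
        if other.polarity == "-" and is_antagonist(other, g, declared):
            return "blocked"
    return "allowed"


def epoch_membership(
    word_form: WordForm,
    inventory: dict[str, Gesture] | None = None,
    declared: set[tuple[str, str]] | None = None,
) -> tuple[list[frozenset[str]], list[BlockEvent]]:
    """Selected-gesture membership for each epoch 1..K.

    Starts from canonical membership and applies dissociation directives
    subject to the blocking rule.  Excitatory directives are applied first;
    an inhibitory gesture whose paired + member carries a same-mode
    directive inherits exactly the epochs admitted for the + member, so the
    pair dissociates (or is refused) together.
    """
    K = word_form.n_sets
    members: list[set[str]] = [set(s.member_gesture_ids) for s in word_form.sets]
    events: list[BlockEvent] = []
    if word_form.dissociations and inventory is None:
        raise ConfigError("an inventory is required to apply dissociation directives")

    admitted: dict[tuple[str, str], list[int]] = {}

    def candidate_epochs(rank: int, mode: str, span: int) -> list[int]:
        if mode == "early_promotion":
            return list(range(max(1, rank - span), rank))
        return list(range(rank + 1, min(K, rank + span) + 1))

    def apply_plus(d: DissociationDirective) -> None:
        g = inventory[d.gesture_id]
        rank = word_form.rank_of(d.gesture_id)
        epochs = candidate_epochs(rank, d.mode, d.span)
        blocked = {
            k
            for k in epochs
            if check_blocking(d.gesture_id, members[k - 1], inventory, declared) == "blocked"
        }
        ok: list[int] = []
        if d.mode == "early_promotion":
            start = max(blocked) + 1 if blocked else (epochs[0] if epochs else rank)
            for k in epochs:
                if k in blocked:
                    events.append(BlockEvent(d.gesture_id, k, "antagonist"))
                elif k < start:
                    events.append(BlockEvent(d.gesture_id, k, "contiguity"))
                else:
                    ok.append(k)
        else:
            end = min(blocked) - 1 if blocked else (epochs[-1] if epochs else rank)
            for k in epochs:
                if k in blocked:
                    events.append(BlockEvent(d.gesture_id, k, "antagonist"))
                elif k > end:
                    events.append(BlockEvent(d.gesture_id, k, "contiguity"))
                else:
                    ok.append(k)
        for k in ok:
            members[k - 1].add(d.gesture_id)
        admitted[(d.gesture_id, d.mode)] = ok

    def apply_minus(d: DissociationDirective) -> None:
        g = inventory[d.gesture_id]
        rank = word_form.rank_of(d.gesture_id)
        epochs = candidate_epochs(rank, d.mode, d.span)
        partner_ok: list[int] | None = None
        if g.pair_id is not None:
            for (pid, mode), ok in admitted.items():
                if mode == d.mode and inventory[pid].pair_id == g.pair_id:
                    partner_ok = ok
                    break
        for k in epochs:
            if partner_ok is not None and k not in partner_ok:
                events.append(BlockEvent(d.gesture_id, k, "paired"))
            else:
                members[k - 1].add(d.gesture_id)

    plus = [d for d in word_form.dissociations if inventory[d.gesture_id].polarity == "+"] if inventory else []
    minus = [d for d in word_form.dissociations if inventory[d.gesture_id].polarity == "-"] if inventory else []
    for d in plus:
        apply_plus(d)
    for d in minus:
        apply_minus(d)
    return [frozenset(m) for m in members], events


def _selected_span(
    gesture_id: str, epochs_members: Sequence[frozenset[str]]
) -> tuple[int, int]:
    """First and last epoch (1-based) in which the gesture is selected."""
    ks = [k for k, m in enumerate(epochs_members, start=1) if gesture_id in m]
    if not ks:
        raise ConfigError(f"gesture '{gesture_id}' is selected in no epoch")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ConfigError(
            f"gesture '{gesture_id}' selected epochs {ks} are not contiguous"
        )
    return ks[0], ks[-1]


def excitation_levels(
    word_form: WordForm,
    epochs_members: Sequence[frozenset[str]],
    config: SelectionConfig,
) -> list[dict[str, float]]:
    """Numeric excitation level per gesture for epochs 0..K+1.

    Index 0 is the pre-response (ready) organization, indices 1..K the
    selection epochs, index K+1 the terminal all-suppressed organization.
    Queue levels descend with the number of epochs remaining before a
    gesture's first selection; post-suppression excitation is strictly
    below every queue level.
    """
    K = len(epochs_members)
    spans = {gid: _selected_span(gid, epochs_members) for gid in word_form.gesture_ids()}
    out: list[dict[str, float]] = []
    for k in range(0, K + 2):
        levels: dict[str, float] = {}
        for gid, (f, l) in spans.items():
            if f <= k <= l:
                levels[gid] = config.selected_level
            elif k > l:
                levels[gid] = config.suppressed_level
            else:
                levels[gid] = config.queue_level(f - k - 1)
        out.append(levels)
    return out


def init_hierarchy(word_form: WordForm, config: SelectionConfig | None = None,
                   inventory: dict[str, Gesture] | None = None) -> SelectionState:
    """Pre-response organization: ranked sub-threshold levels, none selected."""
    config = config or SelectionConfig()
    if word_form.n_sets > config.max_sets:
        raise ConfigError(
            f"word form has {word_form.n_sets} sets; maximum is {config.max_sets}"
        )
    epochs_members, _ = epoch_membership(word_form, inventory)
    levels = excitation_levels(word_form, epochs_members, config)[0]
    return SelectionState(epoch_index=0, level_of=levels, threshold=config.threshold)


def reorganize(
    state: SelectionState,
    word_form: WordForm,
    event: str = "suppression",
    inventory: dict[str, Gesture] | None = None,
    config: SelectionConfig | None = None,
    declared: set[tuple[str, str]] | None = None,
) -> SelectionState:
    """Advance the step potential one epoch.

    Demotes currently selected gestures to the lowest level (except those
    held by an active late-demotion directive), promotes the next set
    (plus early-promoted gestures) above threshold, subject to blocking.
    Reorganizing past the last set yields the terminal all-suppressed
    state rather than an error.
    """
    if event not in ("suppression", "response_initiation"):
        raise ContractError(f"unknown reorganization event {event!r}")
    config = config or SelectionConfig()
    epochs_members, _ = epoch_membership(word_form, inventory, declared)
    k = min(state.epoch_index + 1, len(epochs_members) + 1)
    levels = excitation_levels(word_form, epochs_members, config)[k]
    return replace(state, epoch_index=k, level_of=levels)


def run_selection(
    word_form: WordForm,
    feedback_mode: str,
    achievement_monitor: EpochMonitor | None,
    config: SelectionConfig | None = None,
    inventory: dict[str, Gesture] | None = None,
    t0: float = 0.0,
    declared: set[tuple[str, str]] | None = None,
) -> SelectionTrace:
    """Run the competition-execution-suppression cycle over all sets.

    Every set is selected exactly once, in canonical order.  Epoch
    boundaries fall at achievement + delay (``external``), at achievement
    minus the internal lead (``internal``, never earlier than a minimal
    epoch duration), or at configured durations (``fixed_epochs``).
    """
    if feedback_mode not in FEEDBACK_MODES:
        raise ConfigError(
            f"feedback_mode must be one of {FEEDBACK_MODES}, got {feedback_mode!r}"
        )
    config = config or SelectionConfig()
    if word_form.n_sets > config.max_sets:
        raise ConfigError(
            f"word form has {word_form.n_sets} sets; maximum is {config.max_sets}"
        )
    if feedback_mode != "fixed_epochs" and achievement_monitor is None:
        raise ConfigError(f"feedback_mode {feedback_mode!r} requires an achievement monitor")

    epochs_members, events = epoch_membership(word_form, inventory, declared)
    levels = excitation_levels(word_form, epochs_members, config)
    records: list[EpochRecord] = []
    t = float(t0)
    for k, members in enumerate(epochs_members, start=1):
        exc = levels[k]
        if feedback_mode == "fixed_epochs":
            end = t + config.epoch_duration(k)
            if achievement_monitor is not None:
                achievement_monitor.advance_to(end, exc)
            boundary = "forced"
        else:
            t_ach = achievement_monitor.run_epoch(k, members, exc, t, config.timeout_ms)
            if t_ach is None:
                raise UnachievedTargetError(
                    f"set '{word_form.sets[k - 1].id}' (epoch {k}) did not achieve "
                    f"its targets within {config.timeout_ms} ms"
                )
            if feedback_mode == "external":
                end = t_ach + config.external_delay_ms
                achievement_monitor.advance_to(end, exc)
                boundary = "external_feedback"
            else:
                end = max(t_ach - config.internal_lead_ms, t + config.min_epoch_ms)
                achievement_monitor.rewind_to(end)
                boundary = "internal_feedback"
        records.append(EpochRecord(k, t, end, members, boundary))
        t = end

    intervals: dict[str, tuple[tuple[float, float], ...]] = {}
    for gid in word_form.gesture_ids():
        f, l = _selected_span(gid, epochs_members)
        intervals[gid] = ((records[f - 1].start, records[l - 1].end),)
    return SelectionTrace(
        word_form=word_form,
        epochs=tuple(records),
        intervals=intervals,
        events=tuple(events),
    )


def excitation_trace(
    trace: SelectionTrace,
    config: SelectionConfig,
    times: np.ndarray,
    gesture_ids: Sequence[str] | None = None,
) -> dict[str, ExcitationTrace]:
    """Numeric excitation time series per gesture from a selection trace.

    Piecewise constant at the ladder levels; times before the first epoch
    get the ready-phase queue levels, times after the last epoch the
    post-suppression level.  ``config.ramp_ms > 0`` applies linear ramps
    centered on each reorganization.  Gestures not in the word form get a
    flat zero trace.
    """
    times = np.asarray(times, dtype=float)
    epochs_members = [e.members for e in trace.epochs]
    levels = excitation_levels(trace.word_form, epochs_members, config)
    in_form = set(trace.word_form.gesture_ids())
    gesture_ids = list(gesture_ids) if gesture_ids is not None else sorted(in_form)

    boundaries = [trace.epochs[0].start] + [e.end for e in trace.epochs]
    out: dict[str, ExcitationTrace] = {}
    for gid in gesture_ids:
        if gid not in in_form:
            out[gid] = ExcitationTrace(gid, times, np.zeros_like(times))
            continue
        # step levels: before boundaries[0] -> levels[0]; epoch k -> levels[k]
        lv = np.array([levels[0][gid]] + [levels[k][gid] for k in range(1, len(levels))])
        idx = np.searchsorted(boundaries, times, side="right")
        e = lv[np.clip(idx, 0, len(lv) - 1)]
        if config.ramp_ms > 0:
            half = config.ramp_ms / 2.0
            e = e.astype(float)
            for b_i, b in enumerate(boundaries):
                lo, hi = lv[b_i], lv[min(b_i + 1, len(lv) - 1)]
                mask = (times >= b - half) & (times <= b + half)
                if mask.any() and hi != lo:
                    frac = (times[mask] - (b - half)) / config.ramp_ms
                    e[mask] = lo + (hi - lo) * np.clip(frac, 0.0, 1.0)
        out[gid] = ExcitationTrace(gid, times, e)
    return out
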