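"""Scenario definition and the coupled simulator.

A :class:`Scenario` bundles an inventory of gestures, one intentional
planning field per tract variable, an optional word form with dissociation
directives, and timeline settings.  :func:`run_simulation` composes the
pieces per time step: excitation levels (from the selection engine or from
fixed "free" excitations) gate gestural forces onto each field, the field
integrates, its centroid is read out as the dynamic target, and the target
drives the tract variable's damped mass-spring dynamics.

Epoch boundaries in feedback-driven modes come from achievement detection
on the live tract variables: a set's targets count as achieved when every
excitatory member's tract variable has stayed within a small band of its
target value for a sustained interval.  In the internal-feedback regime
the boundary precedes detected achievement by a fixed lead, which the
simulator realizes by rewinding the stored trajectory to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .field_dynamics import IntentionalField, NeutralAttractor, centroid_target, field_step, make_grid
from .gestures import Gesture, gesture_force
from .selection import (
    EpochRecord,
    SelectionConfig,
    SelectionTrace,
    WordForm,
    epoch_membership,
    excitation_levels,
    run_selection,
)
from .task_dynamics import DEFAULT_STIFFNESS, TractVariableState, td_step

__all__ = [
    "FieldSpec",
    "TimelineConfig",
    "Scenario",
    "SimulationResult",
    "run_simulation",
]


@dataclass(frozen=True)
class FieldSpec:
    """Configuration of one intentional field and its tract variable."""

    tract_variable_id: str
    n_grid: int = 101
    alpha: float = 0.05
    beta_plus: float = 1.0
    beta_minus: float = 1.0
    neutral: NeutralAttractor = _dc_field(default_factory=NeutralAttractor)
    initial_value: float | None = None  # defaults to the neutral center
    stiffness_k: float = DEFAULT_STIFFNESS
    damping: float | None = None


@dataclass(frozen=True)
class TimelineConfig:
    """Time base and phase durations (all in ms)."""

    dt: float = 1.0
    ready_ms: float = 200.0
    tail_ms: float = 200.0
    duration_ms: float | None = None  # pure-field scenarios (no word form)
    feedback_mode: str = "fixed_epochs"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError(f"timeline.dt must be > 0, got {self.dt}")


@dataclass(frozen=True)
class Scenario:
    """A fully parameterized simulation setup."""

    name: str
    fields: tuple[FieldSpec, ...]
    inventory: tuple[Gesture, ...]
    word_form: WordForm | None = None
    free_excitations: dict[str, float] = _dc_field(default_factory=dict)
    timeline: TimelineConfig = _dc_field(default_factory=TimelineConfig)
    selection: SelectionConfig = _dc_field(default_factory=SelectionConfig)
    manipulated_gesture_ids: tuple[str, ...] = ()
    trigger_gesture_id: str | None = None
    declared_antagonists: frozenset[tuple[str, str]] = frozenset()
    noise_sigma: float = 0.0
    probes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fields", tuple(self.fields))
        object.__setattr__(self, "inventory", tuple(self.inventory))
        object.__setattr__(self, "manipulated_gesture_ids", tuple(self.manipulated_gesture_ids))
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        field_ids = [f.tract_variable_id for f in self.fields]
        if not field_ids:
            raise ConfigError(f"scenario '{self.name}': fields: at least one field required")
        if len(set(field_ids)) != len(field_ids):
            raise ConfigError(f"scenario '{self.name}': fields: duplicate tract variable ids")
        gids = [g.id for g in self.inventory]
        if len(set(gids)) != len(gids):
            raise ConfigError(f"scenario '{self.name}': inventory: duplicate gesture ids")
        for i, g in enumerate(self.inventory):
            if g.tract_variable_id not in field_ids:
                raise ConfigError(
                    f"scenario '{self.name}': inventory[{i}] ('{g.id}') references "
                    f"undeclared field '{g.tract_variable_id}'"
                )
        known = set(gids)
        if self.word_form is not None:
            for s in self.word_form.sets:
                for gid in s.member_gesture_ids:
                    if gid not in known:
                        raise ConfigError(
                            f"scenario '{self.name}': word_form set '{s.id}' references "
                            f"unknown gesture '{gid}'"
                        )
        else:
            if self.timeline.duration_ms is None:
                raise ConfigError(
                    f"scenario '{self.name}': timeline.duration_ms is required "
                    "when there is no word form"
                )
        for gid in self.free_excitations:
            if gid not in known:
                raise ConfigError(
                    f"scenario '{self.name}': free_excitations references unknown "
                    f"gesture '{gid}'"
                )
        for gid in self.manipulated_gesture_ids:
            if gid not in known:
                raise ConfigError(
                    f"scenario '{self.name}': manipulated references unknown gesture '{gid}'"
                )
        if self.trigger_gesture_id is not None and self.trigger_gesture_id not in known:
            raise ConfigError(
                f"scenario '{self.name}': trigger gesture "
                f"'{self.trigger_gesture_id}' is not in the inventory"
            )

    # -- helpers --------------------------------------------------------
    @property
    def inventory_map(self) -> dict[str, Gesture]:
        return {g.id: g for g in self.inventory}

    def field_spec(self, tract_variable_id: str) -> FieldSpec:
        for f in self.fields:
            if f.tract_variable_id == tract_variable_id:
                return f
        raise ConfigError(f"no field '{tract_variable_id}' in scenario '{self.name}'")

    def control(self) -> "Scenario":
        """No-trigger control: the manipulated gestures removed, all else fixed."""
        drop = set(self.manipulated_gesture_ids)
        if not drop:
            raise ConfigError(
                f"scenario '{self.name}' declares no manipulated gestures; "
                "cannot derive a control run"
            )
        inventory = tuple(g for g in self.inventory if g.id not in drop)
        word_form = self.word_form
        if word_form is not None:
            sets = []
            for s in word_form.sets:
                members = tuple(m for m in s.member_gesture_ids if m not in drop)
                if not members:
                    raise ConfigError(
                        f"scenario '{self.name}': removing manipulated gestures empties "
                        f"set '{s.id}'"
                    )
                sets.append(replace(s, member_gesture_ids=members))
            diss = tuple(d for d in word_form.dissociations if d.gesture_id not in drop)
            word_form = WordForm(sets=tuple(sets), dissociations=diss)
        free = {k: v for k, v in self.free_excitations.items() if k not in drop}
        return replace(
            self,
            name=f"{self.name}__control",
            inventory=inventory,
            word_form=word_form,
            free_excitations=free,
            manipulated_gesture_ids=(),
            trigger_gesture_id=None,
        )


# ---------------------------------------------------------------------------
# simulation result


@dataclass
class SimulationResult:
    """Aligned time series from one simulation run (units: ms, field units)."""

    scenario: Scenario
    times: np.ndarray
    grids: dict[str, np.ndarray]
    field_activation: dict[str, np.ndarray]  # (n_times, n_grid) per field
    targets: dict[str, np.ndarray]
    tract: dict[str, np.ndarray]
    tract_velocity: dict[str, np.ndarray]
    excitations: dict[str, np.ndarray]
    selection_trace: SelectionTrace | None = None

    @property
    def events(self):
        return self.selection_trace.events if self.selection_trace else ()

    @property
    def epochs(self) -> tuple[EpochRecord, ...]:
        return self.selection_trace.epochs if self.selection_trace else ()

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        return (self.times >= t0) & (self.times < t1)

    def mean_target(self, field_id: str, t0: float, t1: float) -> float:
        m = self.window_mask(t0, t1)
        if not m.any():
            raise ConfigError(f"empty measurement window [{t0}, {t1})")
        return float(np.mean(self.targets[field_id][m]))

    # -- tabular export -------------------------------------------------
    def field_frame(self, field_id: str) -> pd.DataFrame:
        grid = self.grids[field_id]
        u = self.field_activation[field_id]
        n_t, n_x = u.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n_x),
                "grid_index": np.tile(np.arange(n_x), n_t),
                "x": np.tile(grid, n_t),
                "u": u.ravel(),
            }
        )

    def target_frame(self) -> pd.DataFrame:
        rows = []
        for fid, T in sorted(self.targets.items()):
            rows.append(
                pd.DataFrame({"time": self.times, "tract_variable_id": fid, "target": T})
            )
        return pd.concat(rows, ignore_index=True)

    def tract_frame(self) -> pd.DataFrame:
        rows = []
        for fid in sorted(self.tract):
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "tract_variable_id": fid,
                        "target": self.targets[fid],
                        "value": self.tract[fid],
                        "velocity": self.tract_velocity[fid],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def excitation_frame(self) -> pd.DataFrame:
        rows = []
        for gid in sorted(self.excitations):
            rows.append(
                pd.DataFrame({"time": self.times, "gesture_id": gid, "e": self.excitations[gid]})
            )
        return pd.concat(rows, ignore_index=True)

    def score_frame(self) -> pd.DataFrame:
        """Score-style interval table: selected intervals and blocked attempts."""
        rows = []
        if self.selection_trace is not None:
            for ep in self.selection_trace.epochs:
                for gid in sorted(ep.members):
                    rows.append(
                        dict(gesture_id=gid, start_ms=ep.start, end_ms=ep.end,
                             epoch=ep.index, status="selected")
                    )
            for ev in self.selection_trace.events:
                ep = self.selection_trace.epochs[ev.epoch - 1]
                rows.append(
                    dict(gesture_id=ev.gesture_id, start_ms=ep.start, end_ms=ep.end,
                         epoch=ev.epoch, status="blocked_attempt")
                )
        return pd.DataFrame(rows, columns=["gesture_id", "start_ms", "end_ms", "epoch", "status"])


# ---------------------------------------------------------------------------
# the coupled physics engine


class _Physics:
    """Field + tract-variable integrator with trajectory storage and rewind."""

    def __init__(self, scenario: Scenario, rng: np.random.Generator):
        self.scenario = scenario
        self.rng = rng
        self.dt = scenario.timeline.dt
        self.inventory = scenario.inventory_map
        self.fields: dict[str, IntentionalField] = {}
        self.tvs: dict[str, TractVariableState] = {}
        self.neutral_force: dict[str, np.ndarray] = {}
        self.by_field: dict[str, list[Gesture]] = {}
        for fs in scenario.fields:
            grid = make_grid(fs.n_grid)
            nf = fs.neutral.force(grid)
            # start from the neutral-only resting field and posture
            u0 = nf / fs.alpha
            self.fields[fs.tract_variable_id] = IntentionalField(
                tract_variable_id=fs.tract_variable_id,
                grid=grid,
                u=u0,
                alpha=fs.alpha,
                beta_plus=fs.beta_plus,
                beta_minus=fs.beta_minus,
            )
            x0 = fs.initial_value if fs.initial_value is not None else fs.neutral.center
            self.tvs[fs.tract_variable_id] = TractVariableState(
                tract_variable_id=fs.tract_variable_id,
                value=x0,
                velocity=0.0,
                stiffness_k=fs.stiffness_k,
                damping=fs.damping,
            )
            self.neutral_force[fs.tract_variable_id] = nf
            self.by_field[fs.tract_variable_id] = [
                g for g in scenario.inventory if g.tract_variable_id == fs.tract_variable_id
            ]
        self.time = 0.0
        self._times: list[float] = []
        self._u: dict[str, list[np.ndarray]] = {f: [] for f in self.fields}
        self._T: dict[str, list[float]] = {f: [] for f in self.fields}
        self._x: dict[str, list[float]] = {f: [] for f in self.fields}
        self._v: dict[str, list[float]] = {f: [] for f in self.fields}
        self._e: dict[str, list[float]] = {g.id: [] for g in scenario.inventory}
        self._record({g.id: 0.0 for g in scenario.inventory})

    def _record(self, excitations: dict[str, float]) -> None:
        self._times.append(self.time)
        for fid in self.fields:
            self._u[fid].append(self.fields[fid].u.copy())
            self._T[fid].append(centroid_target(self.fields[fid]))
            self._x[fid].append(self.tvs[fid].value)
            self._v[fid].append(self.tvs[fid].velocity)
        for gid in self._e:
            self._e[gid].append(float(excitations.get(gid, 0.0)))

    def effective_excitations(self, excitations: dict[str, float]) -> dict[str, float]:
        if self.scenario.noise_sigma <= 0:
            return excitations
        out = {}
        for gid, e in excitations.items():
            out[gid] = float(np.clip(e + self.rng.normal(0.0, self.scenario.noise_sigma), 0.0, 1.0))
        return out

    def step(self, excitations: dict[str, float]) -> None:
        exc = self.effective_excitations(excitations)
        for fid, fld in self.fields.items():
            pos = np.zeros_like(fld.grid)
            neg = np.zeros_like(fld.grid)
            for g in self.by_field[fid]:
                f = gesture_force(g, exc.get(g.id, 0.0), fld.grid, fld)
                if g.excitatory:
                    pos += f
                else:
                    neg += f
            total = self.neutral_force[fid] + fld.beta_plus * pos + fld.beta_minus * neg
            new_field = field_step(fld, total, self.dt)
            T = centroid_target(new_field)
            self.fields[fid] = new_field
            self.tvs[fid] = td_step(self.tvs[fid], T, self.dt)
        self.time += self.dt
        self._record(exc)

    def run_until(self, t_end: float, excitations: dict[str, float]) -> None:
        while self.time < t_end - 1e-9:
            self.step(excitations)

    def rewind_to(self, t: float) -> None:
        idx = int(round(t / self.dt))
        if idx >= len(self._times):
            raise ConfigError(f"cannot rewind forward to t={t}")
        keep = idx + 1
        self._times = self._times[:keep]
        for fid in self.fields:
            self._u[fid] = self._u[fid][:keep]
            self._T[fid] = self._T[fid][:keep]
            self._x[fid] = self._x[fid][:keep]
            self._v[fid] = self._v[fid][:keep]
            self.fields[fid] = replace(self.fields[fid], u=self._u[fid][-1].copy())
            self.tvs[fid] = replace(
                self.tvs[fid], value=self._x[fid][-1], velocity=self._v[fid][-1]
            )
        for gid in self._e:
            self._e[gid] = self._e[gid][:keep]
        self.time = self._times[-1]

    def result(self, trace: SelectionTrace | None) -> SimulationResult:
        return SimulationResult(
            scenario=self.scenario,
            times=np.asarray(self._times),
            grids={f: self.fields[f].grid for f in self.fields},
            field_activation={f: np.vstack(self._u[f]) for f in self.fields},
            targets={f: np.asarray(self._T[f]) for f in self.fields},
            tract={f: np.asarray(self._x[f]) for f in self.fields},
            tract_velocity={f: np.asarray(self._v[f]) for f in self.fields},
            excitations={g: np.asarray(self._e[g]) for g in self._e},
            selection_trace=trace,
        )


class CoupledAchievementMonitor:
    """Achievement detection over the live physics (EpochMonitor protocol).

    A set's targets are achieved when every excitatory canonical member's
    tract variable has been within ``achievement_eps`` of its target value
    for ``sustain_ms``; the achievement time reported is the entry into the
    sustained band.
    """

    def __init__(self, physics: _Physics, word_form: WordForm, config: SelectionConfig,
                 extra_excitations: dict[str, float] | None = None):
        self.physics = physics
        self.word_form = word_form
        self.config = config
        self.extra = dict(extra_excitations or {})

    def _merged(self, excitations: dict[str, float]) -> dict[str, float]:
        return {**self.extra, **excitations}

    def _requirements(self, epoch_index: int) -> list[tuple[str, float]]:
        inv = self.physics.inventory
        out = []
        for gid in self.word_form.sets[epoch_index - 1].member_gesture_ids:
            g = inv.get(gid)
            if g is not None and g.excitatory and g.target_value is not None:
                out.append((g.tract_variable_id, g.target_value))
        return out

    def run_epoch(self, epoch_index, members, excitations, t_start, timeout_ms):
        exc = self._merged(excitations)
        reqs = self._requirements(epoch_index)
        if not reqs:
            return float(t_start)
        eps, sustain = self.config.achievement_eps, self.config.sustain_ms
        t_enter: float | None = None
        while self.physics.time - t_start < timeout_ms:
            self.physics.step(exc)
            ok = all(abs(self.physics.tvs[f].value - tgt) <= eps for f, tgt in reqs)
            if ok:
                if t_enter is None:
                    t_enter = self.physics.time
                if self.physics.time - t_enter >= sustain:
                    return t_enter
            else:
                t_enter = None
        return None

    def advance_to(self, t, excitations):
        self.physics.run_until(t, self._merged(excitations))

    def rewind_to(self, t):
        self.physics.rewind_to(t)


def run_simulation(scenario: Scenario, seed: int = 0) -> SimulationResult:
    """Run a scenario deterministically for a fixed seed.

    Pure-field scenarios (no word form) integrate for ``duration_ms`` under
    the fixed free excitations.  Word-form scenarios simulate a ready phase
    at pre-response excitation levels, run the selection cycle with
    coupled achievement monitoring, and append a tail phase at
    post-suppression levels.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    phys = _Physics(scenario, rng)
    if scenario.word_form is None:
        exc = {g.id: float(scenario.free_excitations.get(g.id, 0.0)) for g in scenario.inventory}
        phys.run_until(scenario.timeline.duration_ms, exc)
        return phys.result(None)

    inv = scenario.inventory_map
    declared = set(scenario.declared_antagonists) or None
    epochs_members, _ = epoch_membership(scenario.word_form, inv, declared)
    levels = excitation_levels(scenario.word_form, epochs_members, scenario.selection)
    free = {k: float(v) for k, v in scenario.free_excitations.items()}
    ready_exc = {**free, **levels[0]}
    phys.run_until(scenario.timeline.ready_ms, ready_exc)
    monitor = CoupledAchievementMonitor(phys, scenario.word_form, scenario.selection, free)
    trace = run_selection(
        scenario.word_form,
        scenario.timeline.feedback_mode,
        monitor,
        scenario.selection,
        inv,
        t0=scenario.timeline.ready_ms,
        declared=declared,
    )
    terminal_exc = {**free, **levels[-1]}
    phys.run_until(trace.t_end + scenario.timeline.tail_ms, terminal_exc)
    return phys.result(trace)
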