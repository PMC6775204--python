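"""Scenario config (YAML/JSON) parsing, validation, and result export.

Config files have sections ``fields``, ``inventory``, ``word_form``,
``timeline``, ``selection``, plus optional ``free_excitations``,
``manipulated``, ``trigger``, ``noise_sigma`` and ``probes``.  Validation
errors name the offending config path (e.g. ``inventory[2].sigma``).

Results are exported as plain CSV trace tables (fields, targets, tract
variables, excitations), a score-style interval table, and a ``meta.json``
holding the scenario, epoch schedule and event log, from which a result
can be reloaded for classification.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .field_dynamics import NeutralAttractor
from .gestures import Gesture, GatingFunction
from .selection import (
    BlockEvent,
    DissociationDirective,
    EpochRecord,
    GestureSet,
    SelectionConfig,
    SelectionTrace,
    WordForm,
)
from .scenarios import FieldSpec, Scenario, SimulationResult, TimelineConfig

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
    "save_result",
    "load_result",
]


def _get(d: dict, key: str, path: str, required: bool = True, default=None):
    if key not in d:
        if required:
            raise ConfigError(f"{path}.{key}: missing required key")
        return default
    return d[key]


def _num(value, path: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{path}: expected a number, got {value!r}")
    return float(value)


# ---------------------------------------------------------------------------
# scenario <-> dict


def scenario_to_dict(s: Scenario) -> dict:
    def gesture_dict(g: Gesture) -> dict:
        return {
            "id": g.id,
            "tract_variable": g.tract_variable_id,
            "polarity": g.polarity,
            "mu": g.mu,
            "sigma": g.sigma,
            "weight": g.weight,
            "gating": {"midpoint": g.gating.midpoint, "slope": g.gating.slope},
            "target_value": g.target_value,
            "pair": g.pair_id,
        }

    def field_dict(f: FieldSpec) -> dict:
        return {
            "tract_variable": f.tract_variable_id,
            "n_grid": f.n_grid,
            "alpha": f.alpha,
            "beta_plus": f.beta_plus,
            "beta_minus": f.beta_minus,
            "neutral": asdict(f.neutral),
            "initial_value": f.initial_value,
            "stiffness_k": f.stiffness_k,
            "damping": f.damping,
        }

    out = {
        "name": s.name,
        "fields": [field_dict(f) for f in s.fields],
        "inventory": [gesture_dict(g) for g in s.inventory],
        "timeline": asdict(s.timeline),
        "selection": {**asdict(s.selection), "epoch_ms": (
            list(s.selection.epoch_ms)
            if isinstance(s.selection.epoch_ms, tuple)
            else s.selection.epoch_ms
        )},
        "free_excitations": dict(s.free_excitations),
        "manipulated": list(s.manipulated_gesture_ids),
        "trigger": s.trigger_gesture_id,
        "declared_antagonists": sorted(list(p) for p in s.declared_antagonists),
        "noise_sigma": s.noise_sigma,
        "probes": list(s.probes),
    }
    if s.word_form is not None:
        out["word_form"] = {
            "sets": [
                {"id": gs.id, "members": list(gs.member_gesture_ids)}
                for gs in s.word_form.sets
            ],
            "dissociations": [
                {"gesture": d.gesture_id, "mode": d.mode, "span": d.span}
                for d in s.word_form.dissociations
            ],
        }
    return out


def _parse_field(d: dict, path: str) -> FieldSpec:
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping")
    ncfg = _get(d, "neutral", path, required=False, default={}) or {}
    neutral = NeutralAttractor(
        center=_num(ncfg.get("center", 0.5), f"{path}.neutral.center"),
        width=_num(ncfg.get("width", 0.1), f"{path}.neutral.width"),
        strength=_num(ncfg.get("strength", 0.1), f"{path}.neutral.strength"),
    )
    return FieldSpec(
        tract_variable_id=str(_get(d, "tract_variable", path)),
        n_grid=int(d.get("n_grid", 101)),
        alpha=_num(d.get("alpha", 0.05), f"{path}.alpha"),
        beta_plus=_num(d.get("beta_plus", 1.0), f"{path}.beta_plus"),
        beta_minus=_num(d.get("beta_minus", 1.0), f"{path}.beta_minus"),
        neutral=neutral,
        initial_value=(None if d.get("initial_value") is None
                       else _num(d["initial_value"], f"{path}.initial_value")),
        stiffness_k=_num(d.get("stiffness_k", 0.0015), f"{path}.stiffness_k"),
        damping=(None if d.get("damping") is None
                 else _num(d["damping"], f"{path}.damping")),
    )


def _parse_gesture(d: dict, path: str) -> Gesture:
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping")
    gcfg = _get(d, "gating", path, required=False, default={}) or {}
    gating = GatingFunction(
        midpoint=_num(gcfg.get("midpoint", 0.9), f"{path}.gating.midpoint"),
        slope=_num(gcfg.get("slope", 50.0), f"{path}.gating.slope"),
    )
    polarity = str(_get(d, "polarity", path))
    return Gesture(
        id=str(_get(d, "id", path)),
        tract_variable_id=str(_get(d, "tract_variable", path)),
        polarity=polarity,
        mu=_num(_get(d, "mu", path), f"{path}.mu"),
        sigma=_num(_get(d, "sigma", path), f"{path}.sigma"),
        weight=_num(d.get("weight", 1.0), f"{path}.weight"),
        gating=gating,
        target_value=(None if d.get("target_value") is None
                      else _num(d["target_value"], f"{path}.target_value")),
        pair_id=(None if d.get("pair") is None else str(d["pair"])),
    )


def scenario_from_dict(cfg: dict, path: str = "config") -> Scenario:
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    fields = [
        _parse_field(f, f"{path}.fields[{i}]")
        for i, f in enumerate(_get(cfg, "fields", path))
    ]
    inventory = [
        _parse_gesture(g, f"{path}.inventory[{i}]")
        for i, g in enumerate(_get(cfg, "inventory", path))
    ]
    word_form = None
    if cfg.get("word_form") is not None:
        wf = cfg["word_form"]
        sets = []
        for i, sd in enumerate(_get(wf, "sets", f"{path}.word_form")):
            sets.append(
                GestureSet(
                    id=str(_get(sd, "id", f"{path}.word_form.sets[{i}]")),
                    member_gesture_ids=tuple(
                        _get(sd, "members", f"{path}.word_form.sets[{i}]")
                    ),
                    canonical_rank=int(sd.get("rank", i + 1)),
                )
            )
        diss = []
        for i, dd in enumerate(wf.get("dissociations", []) or []):
            diss.append(
                DissociationDirective(
                    gesture_id=str(_get(dd, "gesture", f"{path}.word_form.dissociations[{i}]")),
                    mode=str(_get(dd, "mode", f"{path}.word_form.dissociations[{i}]")),
                    span=int(dd.get("span", 1)),
                )
            )
        word_form = WordForm(sets=tuple(sets), dissociations=tuple(diss))

    tl = cfg.get("timeline", {}) or {}
    timeline = TimelineConfig(
        dt=_num(tl.get("dt", 1.0), f"{path}.timeline.dt"),
        ready_ms=_num(tl.get("ready_ms", 200.0), f"{path}.timeline.ready_ms"),
        tail_ms=_num(tl.get("tail_ms", 200.0), f"{path}.timeline.tail_ms"),
        duration_ms=(None if tl.get("duration_ms") is None
                     else _num(tl["duration_ms"], f"{path}.timeline.duration_ms")),
        feedback_mode=str(tl.get("feedback_mode", "fixed_epochs")),
    )
    sl = dict(cfg.get("selection", {}) or {})
    if "queue_levels" in sl:
        sl["queue_levels"] = tuple(sl["queue_levels"])
    if isinstance(sl.get("epoch_ms"), list):
        sl["epoch_ms"] = tuple(sl["epoch_ms"])
    try:
        selection = SelectionConfig(**sl)
    except TypeError as exc:
        raise ConfigError(f"{path}.selection: {exc}") from exc

    declared = frozenset(
        (str(a), str(b)) for a, b in (cfg.get("declared_antagonists") or [])
    )
    return Scenario(
        name=str(cfg.get("name", "scenario")),
        fields=tuple(fields),
        inventory=tuple(inventory),
        word_form=word_form,
        free_excitations={
            str(k): _num(v, f"{path}.free_excitations.{k}")
            for k, v in (cfg.get("free_excitations") or {}).items()
        },
        timeline=timeline,
        selection=selection,
        manipulated_gesture_ids=tuple(cfg.get("manipulated") or ()),
        trigger_gesture_id=cfg.get("trigger"),
        declared_antagonists=declared,
        noise_sigma=_num(cfg.get("noise_sigma", 0.0), f"{path}.noise_sigma"),
        probes=tuple(cfg.get("probes") or ()),
    )


def load_scenario(path: str | Path) -> Scenario:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            cfg = json.load(fh)
        else:
            cfg = yaml.safe_load(fh)
    return scenario_from_dict(cfg, path=str(path))


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    cfg = scenario_to_dict(scenario)
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(cfg, fh, indent=2)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# result export / reload


def save_result(result: SimulationResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for fid in sorted(result.grids):
        f = result.field_frame(fid)
        f.insert(0, "tract_variable_id", fid)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(out / "fields.csv", index=False)
    result.target_frame().to_csv(out / "targets.csv", index=False)
    result.tract_frame().to_csv(out / "tract_variables.csv", index=False)
    result.excitation_frame().to_csv(out / "excitations.csv", index=False)
    result.score_frame().to_csv(out / "score_intervals.csv", index=False)
    meta = {"scenario": scenario_to_dict(result.scenario)}
    if result.selection_trace is not None:
        meta["epochs"] = [
            {
                "index": e.index,
                "start": e.start,
                "end": e.end,
                "members": sorted(e.members),
                "boundary_event": e.boundary_event,
            }
            for e in result.selection_trace.epochs
        ]
        meta["events"] = [asdict(ev) for ev in result.selection_trace.events]
        meta["intervals"] = {
            gid: [list(iv) for iv in ivs]
            for gid, ivs in result.selection_trace.intervals.items()
        }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return out


def load_result(run_dir: str | Path) -> SimulationResult:
    """Reload a saved run into a :class:`SimulationResult`."""
    run = Path(run_dir)
    with open(run / "meta.json") as fh:
        meta = json.load(fh)
    scenario = scenario_from_dict(meta["scenario"], path=str(run / "meta.json"))
    tract = pd.read_csv(run / "tract_variables.csv")
    exc = pd.read_csv(run / "excitations.csv")
    fields_tab = pd.read_csv(run / "fields.csv")

    times = np.sort(tract["time"].unique())
    grids, activation, targets, values, velocity = {}, {}, {}, {}, {}
    for fid, sub in tract.groupby("tract_variable_id"):
        sub = sub.sort_values("time")
        targets[fid] = sub["target"].to_numpy()
        values[fid] = sub["value"].to_numpy()
        velocity[fid] = sub["velocity"].to_numpy()
    for fid, sub in fields_tab.groupby("tract_variable_id"):
        n_x = int(sub["grid_index"].max()) + 1
        grids[fid] = np.sort(sub["x"].unique())
        u = sub.sort_values(["time", "grid_index"])["u"].to_numpy()
        activation[fid] = u.reshape(-1, n_x)
    excitations = {
        gid: sub.sort_values("time")["e"].to_numpy() for gid, sub in exc.groupby("gesture_id")
    }
    trace = None
    if "epochs" in meta and scenario.word_form is not None:
        epochs = tuple(
            EpochRecord(
                index=e["index"],
                start=e["start"],
                end=e["end"],
                members=frozenset(e["members"]),
                boundary_event=e["boundary_event"],
            )
            for e in meta["epochs"]
        )
        events = tuple(BlockEvent(**ev) for ev in meta.get("events", []))
        intervals = {
            gid: tuple(tuple(iv) for iv in ivs)
            for gid, ivs in meta.get("intervals", {}).items()
        }
        trace = SelectionTrace(
            word_form=scenario.word_form, epochs=epochs, intervals=intervals, events=events
        )
    return SimulationResult(
        scenario=scenario,
        times=times,
        grids=grids,
        field_activation=activation,
        targets=targets,
        tract=values,
        tract_velocity=velocity,
        excitations=excitations,
        selection_trace=trace,
    )
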