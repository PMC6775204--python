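"""Named scenario fixtures for the model's demonstration phenomena.

Each entry is a fully parameterized :class:`~scintax.scenarios.Scenario`
reproducing one of the model's qualitative demonstrations: neutral-attractor
release behavior, distractor-target assimilation/dissimilation in planning
fields, anticipatory posturing under leaky gating, and the
spreading/blocking/agreement harmony trajectories.

Conventions used throughout the library (field units in [0, 1], ms):

- tract-variable axes are oriented so larger values mean more constricted
  (oral fields, rest 0.5) or more open (velum, rest 0.3 = mostly closed);
- excitatory force distributions have sigma 0.08; inhibitory ones are
  broader and sit at the opposite end of the axis from their paired
  excitatory member (complementary single-mode distributions);
- the neutral attractor strength is 0.1, one tenth of a fully gated
  gesture's amplitude, so active gestures dominate rest forces;
- word-form fixtures use scripted 150 ms epochs so that a run and its
  control share epoch boundaries exactly; the anticipatory-posturing
  fixture uses external feedback with live achievement detection.
"""

from __future__ import annotations

from dataclasses import replace

from .errors import ConfigError
from .field_dynamics import NeutralAttractor
from .gestures import Gesture, GatingFunction, leaky_gating, strong_gating
from .selection import DissociationDirective, GestureSet, SelectionConfig, WordForm
from .scenarios import FieldSpec, Scenario, TimelineConfig

__all__ = ["SCENARIO_NAMES", "make_scenario", "directionality_scenarios"]

SCENARIO_NAMES = (
    "neutral_weak_release",
    "neutral_strong_undershoot",
    "split_gesture_release",
    "assimilation_fig5a",
    "dissimilation_fig5b",
    "anticipatory_posture_fig10",
    "spreading_persev_fig11a",
    "spreading_antic_fig11b",
    "blocking_fig11c",
    "blocking_fig11d",
    "agreement_fig12a",
    "agreement_phonologized_fig12b",
)

_ORAL_NEUTRAL = NeutralAttractor(center=0.5, width=0.1, strength=0.1)
_VEL_NEUTRAL = NeutralAttractor(center=0.3, width=0.1, strength=0.1)


def _oral_field(tv: str = "TTCD", strength: float = 0.1) -> FieldSpec:
    return FieldSpec(tv, neutral=NeutralAttractor(center=0.5, width=0.1, strength=strength))


def _vel_field() -> FieldSpec:
    return FieldSpec("VEL", neutral=_VEL_NEUTRAL)


def _gating(kind: str) -> GatingFunction:
    if kind == "leaky":
        return leaky_gating()
    if kind == "strong":
        return strong_gating()
    raise ConfigError(f"gating must be 'leaky' or 'strong', got {kind!r}")


# ---------------------------------------------------------------------------
# release / undershoot demonstrations (single tract variable)


def _release_scenario(name: str, neutral_strength: float, with_release_gesture: bool) -> Scenario:
    nar = Gesture("TTCD nar+", "TTCD", "+", mu=0.9, sigma=0.08, weight=1.0,
                  gating=strong_gating(), pair_id="nar")
    nar_i = Gesture("TTCD nar-", "TTCD", "-", mu=0.1, sigma=0.2, weight=1.0,
                    gating=strong_gating(), pair_id="nar")
    inventory = [nar, nar_i]
    sets = [GestureSet("S1", ("TTCD nar+", "TTCD nar-"), 1)]
    epoch_ms: tuple[float, ...] | float = 250.0
    if with_release_gesture:
        op = Gesture("TTCD op+", "TTCD", "+", mu=0.1, sigma=0.08, weight=1.0,
                     gating=strong_gating(), pair_id="op")
        inventory.append(op)
        sets.append(GestureSet("S2", ("TTCD op+",), 2))
        epoch_ms = (250.0, 300.0)
    return Scenario(
        name=name,
        fields=(_oral_field("TTCD", neutral_strength),),
        inventory=tuple(inventory),
        word_form=WordForm(sets=tuple(sets)),
        timeline=TimelineConfig(ready_ms=100.0, tail_ms=600.0, feedback_mode="fixed_epochs"),
        selection=SelectionConfig(epoch_ms=epoch_ms),
    )


# ---------------------------------------------------------------------------
# distractor-target planning fields (no word form)


def _field_paradigm(name: str, inventory, excitations, manipulated, trigger) -> Scenario:
    return Scenario(
        name=name,
        fields=(FieldSpec("TV", neutral=_ORAL_NEUTRAL),),
        inventory=tuple(inventory),
        free_excitations=dict(excitations),
        timeline=TimelineConfig(duration_ms=400.0),
        manipulated_gesture_ids=tuple(manipulated),
        trigger_gesture_id=trigger,
    )


def _assimilation_fig5a() -> Scenario:
    a = Gesture("A+", "TV", "+", mu=0.4, sigma=0.08, weight=1.0, gating=strong_gating())
    b = Gesture("B+", "TV", "+", mu=0.6, sigma=0.08, weight=1.0, gating=leaky_gating())
    return _field_paradigm(
        "assimilation_fig5a", [a, b], {"A+": 1.0, "B+": 0.8}, ["B+"], "B+"
    )


def _dissimilation_fig5b() -> Scenario:
    # distal distractor C+ elicits a strong, broad inhibitory response A-
    # centered on the distractor's region; both are absent from the control
    a = Gesture("A+", "TV", "+", mu=0.4, sigma=0.08, weight=1.0, gating=strong_gating())
    c = Gesture("C+", "TV", "+", mu=0.8, sigma=0.08, weight=1.0, gating=leaky_gating())
    a_inh = Gesture("A-", "TV", "-", mu=0.8, sigma=0.2, weight=1.5, gating=strong_gating())
    return _field_paradigm(
        "dissimilation_fig5b",
        [a, c, a_inh],
        {"A+": 1.0, "C+": 0.8, "A-": 1.0},
        ["C+", "A-"],
        "C+",
    )


# ---------------------------------------------------------------------------
# anticipatory posturing (/na/, ready phase)


def _anticipatory_posture_fig10(gating: str = "leaky") -> Scenario:
    g = _gating(gating)
    inventory = (
        Gesture("TTCD clo+", "TTCD", "+", mu=0.9, sigma=0.08, weight=1.0,
                gating=strong_gating(), pair_id="clo"),
        Gesture("TTCD clo-", "TTCD", "-", mu=0.1, sigma=0.2, weight=1.0,
                gating=strong_gating(), pair_id="clo"),
        Gesture("VEL op+", "VEL", "+", mu=0.9, sigma=0.08, weight=1.0,
                gating=g, pair_id="op", target_value=0.9),
        Gesture("VEL op-", "VEL", "-", mu=0.0, sigma=0.14, weight=1.0,
                gating=g, pair_id="op"),
    )
    word_form = WordForm(
        sets=(GestureSet("na", tuple(x.id for x in inventory), 1),)
    )
    return Scenario(
        name="anticipatory_posture_fig10",
        fields=(_oral_field("TTCD"), _vel_field()),
        inventory=inventory,
        word_form=word_form,
        timeline=TimelineConfig(ready_ms=400.0, tail_ms=200.0, feedback_mode="external"),
        selection=SelectionConfig(),
        trigger_gesture_id="VEL op+",
    )


# ---------------------------------------------------------------------------
# harmony trajectories (3-set word forms, fixed 150 ms epochs)


def _oral_gesture(gid: str, mu: float) -> Gesture:
    return Gesture(gid, "ORAL", "+", mu=mu, sigma=0.08, weight=1.0, gating=strong_gating())


def _x_pair(gating_plus: GatingFunction) -> tuple[Gesture, Gesture]:
    return (
        Gesture("x+", "VEL", "+", mu=0.9, sigma=0.08, weight=1.0,
                gating=gating_plus, pair_id="x", target_value=0.9),
        Gesture("x-", "VEL", "-", mu=0.0, sigma=0.12, weight=1.0,
                gating=strong_gating(), pair_id="x"),
    )


def _y_pair() -> tuple[Gesture, Gesture]:
    return (
        Gesture("y+", "VEL", "+", mu=0.1, sigma=0.08, weight=1.0,
                gating=strong_gating(), pair_id="y", target_value=0.1),
        Gesture("y-", "VEL", "-", mu=0.9, sigma=0.16, weight=1.5,
                gating=strong_gating(), pair_id="y"),
    )


def _harmony_scenario(
    name: str,
    x_epoch: int,
    y_epoch: int | None,
    dissociation_mode: str | None,
    x_gating: str = "strong",
) -> Scenario:
    """Three-set word form with the trigger pair x+/x- in set ``x_epoch``
    and, optionally, the antagonist pair y+/y- in set ``y_epoch``."""
    a, b, c = (_oral_gesture(g, m) for g, m in (("a+", 0.3), ("b+", 0.5), ("c+", 0.7)))
    xp, xm = _x_pair(_gating(x_gating))
    inventory = [a, b, c, xp, xm]
    members: dict[int, list[str]] = {1: ["a+"], 2: ["b+"], 3: ["c+"]}
    members[x_epoch] += ["x+", "x-"]
    if y_epoch is not None:
        yp, ym = _y_pair()
        inventory += [yp, ym]
        members[y_epoch] += ["y+", "y-"]
    sets = tuple(
        GestureSet(f"S{k}", tuple(members[k]), k) for k in (1, 2, 3)
    )
    diss = ()
    if dissociation_mode is not None:
        diss = (
            DissociationDirective("x+", dissociation_mode, span=1),
            DissociationDirective("x-", dissociation_mode, span=1),
        )
    return Scenario(
        name=name,
        fields=(FieldSpec("ORAL", neutral=_ORAL_NEUTRAL), _vel_field()),
        inventory=tuple(inventory),
        word_form=WordForm(sets=sets, dissociations=diss),
        timeline=TimelineConfig(ready_ms=200.0, tail_ms=200.0, feedback_mode="fixed_epochs"),
        selection=SelectionConfig(epoch_ms=150.0),
        manipulated_gesture_ids=("x+", "x-"),
        trigger_gesture_id="x+",
    )


def _agreement_phonologized_fig12b(x_gating: str = "leaky") -> Scenario:
    base = _harmony_scenario(
        "agreement_phonologized_fig12b", 3, 2, None, x_gating=x_gating
    )
    # the phonologized stage: a second copy of the trigger pair is a
    # canonical member of the first set
    x1p = replace(base.inventory_map["x+"], id="x1+", pair_id="x1")
    x1m = replace(base.inventory_map["x-"], id="x1-", pair_id="x1")
    inventory = base.inventory + (x1p, x1m)
    sets = list(base.word_form.sets)
    sets[0] = replace(sets[0], member_gesture_ids=sets[0].member_gesture_ids + ("x1+", "x1-"))
    return replace(
        base,
        inventory=inventory,
        word_form=WordForm(sets=tuple(sets), dissociations=()),
    )


def make_scenario(name: str, gating: str | None = None) -> Scenario:
    """Return a named library scenario.

    ``gating`` overrides the trigger's gating regime ("leaky" or "strong")
    for the anticipatory-posturing and agreement fixtures; other fixtures
    define their own regimes.
    """
    builders = {
        "neutral_weak_release": lambda: _release_scenario("neutral_weak_release", 0.05, False),
        "neutral_strong_undershoot": lambda: _release_scenario(
            "neutral_strong_undershoot", 1.0, False
        ),
        "split_gesture_release": lambda: _release_scenario("split_gesture_release", 0.05, True),
        "assimilation_fig5a": _assimilation_fig5a,
        "dissimilation_fig5b": _dissimilation_fig5b,
        "anticipatory_posture_fig10": lambda: _anticipatory_posture_fig10(gating or "leaky"),
        "spreading_persev_fig11a": lambda: _harmony_scenario(
            "spreading_persev_fig11a", 2, None, "late_demotion"
        ),
        "spreading_antic_fig11b": lambda: _harmony_scenario(
            "spreading_antic_fig11b", 2, None, "early_promotion"
        ),
        "blocking_fig11c": lambda: _harmony_scenario(
            "blocking_fig11c", 1, 2, "late_demotion"
        ),
        "blocking_fig11d": lambda: _harmony_scenario(
            "blocking_fig11d", 2, 1, "early_promotion"
        ),
        "agreement_fig12a": lambda: _harmony_scenario(
            "agreement_fig12a", 3, 2, None, x_gating=gating or "leaky"
        ),
        "agreement_phonologized_fig12b": lambda: _agreement_phonologized_fig12b(
            gating or "leaky"
        ),
    }
    if name not in builders:
        available = ", ".join(SCENARIO_NAMES)
        raise ConfigError(f"unknown scenario '{name}'; available: {available}")
    return builders[name]()


def directionality_scenarios() -> tuple[Scenario, Scenario]:
    """Mirrored agreement configurations for the directionality contrast.

    Returns (anticipatory, perseveratory): the trigger pair sits in the
    last vs. the first set of a three-set form, with no antagonists and no
    directives; the relevant measurement epoch is the middle one in both.
    """
    antic = _harmony_scenario("agreement_anticipatory", 3, None, None, x_gating="leaky")
    persev = _harmony_scenario("agreement_perseveratory", 1, None, None, x_gating="leaky")
    return antic, persev
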