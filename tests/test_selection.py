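"""Competitive queuing: hierarchy, reorganization, dissociation, blocking."""

import itertools

import numpy as np
import pytest

import scintax as sx
from scintax.errors import ConfigError, ContractError, UnachievedTargetError
from scintax.selection import excitation_levels


def vel_exc(gid, mu=0.9):
    return sx.Gesture(gid, "VEL", "+", mu=mu, sigma=0.08, pair_id=gid.rstrip("+-"))


def vel_inh(gid, mu=0.0, sigma=0.12, pair=None):
    return sx.Gesture(gid, "VEL", "-", mu=mu, sigma=sigma,
                      pair_id=pair or gid.rstrip("+-"))


def oral(gid, mu=0.5):
    return sx.Gesture(gid, "ORAL", "+", mu=mu, sigma=0.08)


def three_set_form(extra=(), dissociations=()):
    members = {1: ["a+"], 2: ["b+", "x+", "x-"], 3: ["c+"]}
    for gid, epoch in extra:
        members[epoch].append(gid)
    sets = tuple(
        sx.GestureSet(f"S{k}", tuple(members[k]), k) for k in (1, 2, 3)
    )
    return sx.WordForm(sets=sets, dissociations=tuple(dissociations))


@pytest.fixture
def inventory():
    inv = [
        oral("a+", 0.3), oral("b+", 0.5), oral("c+", 0.7),
        vel_exc("x+"), vel_inh("x-"),
        sx.Gesture("y-", "VEL", "-", mu=0.9, sigma=0.16, pair_id="y"),
        sx.Gesture("y+", "VEL", "+", mu=0.1, sigma=0.08, pair_id="y"),
    ]
    return {g.id: g for g in inv}


class ScriptedMonitor:
    """Achievement monitor with scripted per-epoch achievement delays."""

    def __init__(self, delay_ms=100.0):
        self.delay_ms = delay_ms
        self.rewinds = []
        self.advances = []

    def run_epoch(self, epoch_index, members, excitations, t_start, timeout_ms):
        if self.delay_ms > timeout_ms:
            return None
        return t_start + self.delay_ms

    def advance_to(self, t, excitations):
        self.advances.append(t)

    def rewind_to(self, t):
        self.rewinds.append(t)


class TestWordFormValidation:
    def test_empty_word_form_is_config_error(self):
        with pytest.raises(ConfigError):
            sx.WordForm(sets=())

    def test_duplicate_membership_across_sets_rejected(self):
        sets = (
            sx.GestureSet("A", ("g1",), 1),
            sx.GestureSet("B", ("g1", "g2"), 2),
        )
        with pytest.raises(ConfigError, match="g1"):
            sx.WordForm(sets=sets)

    def test_ranks_must_be_permutation(self):
        sets = (sx.GestureSet("A", ("g1",), 1), sx.GestureSet("B", ("g2",), 3))
        with pytest.raises(ConfigError):
            sx.WordForm(sets=sets)

    def test_directive_must_reference_a_member(self):
        with pytest.raises(ConfigError):
            sx.WordForm(
                sets=(sx.GestureSet("A", ("g1",), 1),),
                dissociations=(sx.DissociationDirective("zz", "early_promotion"),),
            )


class TestHierarchy:
    def test_three_sets_get_descending_subthreshold_levels(self, inventory):
        state = sx.init_hierarchy(three_set_form(), inventory=inventory)
        cfg = sx.SelectionConfig()
        l1, l2, l3 = (state.level_of[g] for g in ("a+", "b+", "c+"))
        assert l1 > l2 > l3
        assert max(state.level_of.values()) <= cfg.threshold
        assert not state.selected_ids()

    def test_single_set_sits_below_threshold(self):
        wf = sx.WordForm(sets=(sx.GestureSet("A", ("a+",), 1),))
        state = sx.init_hierarchy(wf)
        assert 0 < state.level_of["a+"] <= sx.SelectionConfig().threshold

    def test_reorganize_walks_canonical_order_then_terminates(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig()
        state = sx.init_hierarchy(wf, cfg, inventory)
        seen = []
        for _ in range(3):
            state = sx.reorganize(state, wf, inventory=inventory, config=cfg)
            seen.append(state.selected_ids())
        assert seen[0] == {"a+"}
        assert seen[1] == {"b+", "x+", "x-"}
        assert seen[2] == {"c+"}
        # suppressed gestures sit at the lowest level
        assert state.level_of["a+"] == cfg.suppressed_level
        terminal = sx.reorganize(state, wf, inventory=inventory, config=cfg)
        assert not terminal.selected_ids()


class TestBlockingRule:
    def test_antagonist_in_epoch_blocks_candidate(self, inventory):
        assert sx.check_blocking("x+", {"y-", "b+"}, inventory) == "blocked"

    def test_no_antagonist_allows_candidate(self, inventory):
        assert sx.check_blocking("x+", {"b+", "y+"}, inventory) == "allowed"

    def test_disjoint_tract_variables_allowed(self, inventory):
        assert sx.check_blocking("x+", {"a+", "c+"}, inventory) == "allowed"

    def test_inhibitory_candidate_is_contract_error(self, inventory):
        with pytest.raises(ContractError):
            sx.check_blocking("x-", {"b+"}, inventory)


class TestDissociation:
    def test_early_promotion_extends_selection_backward(self, inventory):
        wf = three_set_form(
            dissociations=[sx.DissociationDirective("x+", "early_promotion", 1),
                           sx.DissociationDirective("x-", "early_promotion", 1)]
        )
        members, events = sx.epoch_membership(wf, inventory)
        assert "x+" in members[0] and "x+" in members[1] and "x+" not in members[2]
        assert "x-" in members[0]
        assert not events

    def test_late_demotion_extends_selection_forward(self, inventory):
        wf = three_set_form(
            dissociations=[sx.DissociationDirective("x+", "late_demotion", 1),
                           sx.DissociationDirective("x-", "late_demotion", 1)]
        )
        members, _ = sx.epoch_membership(wf, inventory)
        assert "x+" in members[1] and "x+" in members[2]

    def test_selected_antagonist_refuses_promotion_of_pair(self, inventory):
        wf = three_set_form(
            extra=[("y-", 1), ("y+", 1)],
            dissociations=[sx.DissociationDirective("x+", "early_promotion", 1),
                           sx.DissociationDirective("x-", "early_promotion", 1)],
        )
        members, events = sx.epoch_membership(wf, inventory)
        assert "x+" not in members[0] and "x-" not in members[0]
        reasons = {(e.gesture_id, e.reason) for e in events}
        assert ("x+", "antagonist") in reasons
        assert ("x-", "paired") in reasons

    def test_mid_span_blocker_truncates_early_promotion_contiguously(self, inventory):
        """A blocker two epochs before the canonical set forbids selection
        there, and contiguity truncates the span at the blocked epoch."""
        members_map = {1: ["a+", "y-", "y+"], 2: ["b+"], 3: ["c+", "x+", "x-"]}
        wf = sx.WordForm(
            sets=tuple(sx.GestureSet(f"S{k}", tuple(members_map[k]), k) for k in (1, 2, 3)),
            dissociations=(sx.DissociationDirective("x+", "early_promotion", 2),),
        )
        members, events = sx.epoch_membership(wf, inventory)
        assert "x+" not in members[0]
        assert "x+" in members[1] and "x+" in members[2]

    @pytest.mark.parametrize(
        "combo", list(itertools.product([False, True], repeat=3))
    )
    def test_blocking_soundness_and_contiguity_all_antagonist_placements(
        self, inventory, combo
    ):
        """Exhaustive antagonist placement: wherever an antagonist pair is a
        canonical member, a dissociated x+ is never co-selected with the
        inhibitor, selection order is canonical, and selected epochs are
        contiguous."""
        inventory = dict(inventory)
        extra = []
        for k, on in enumerate(combo):
            if not on:
                continue
            ym = sx.Gesture(f"y{k + 1}-", "VEL", "-", mu=0.9, sigma=0.16, pair_id=f"y{k + 1}")
            yp = sx.Gesture(f"y{k + 1}+", "VEL", "+", mu=0.1, sigma=0.08, pair_id=f"y{k + 1}")
            inventory[ym.id] = ym
            inventory[yp.id] = yp
            extra += [(ym.id, k + 1), (yp.id, k + 1)]
        wf = three_set_form(
            extra=extra,
            dissociations=[
                sx.DissociationDirective("x+", "early_promotion", 1),
                sx.DissociationDirective("x-", "early_promotion", 1),
                sx.DissociationDirective("x+", "late_demotion", 1),
                sx.DissociationDirective("x-", "late_demotion", 1),
            ],
        )
        trace = sx.run_selection(
            wf, "fixed_epochs", None, sx.SelectionConfig(), inventory
        )
        # soundness: no dissociated co-selection of x+ with a selected
        # antagonist (canonical co-selection in epoch 2 is permitted)
        for ep in trace.epochs:
            has_inhibitor = any(m.endswith("-") and m.startswith("y") for m in ep.members)
            if has_inhibitor and ep.index != 2:
                assert "x+" not in ep.members
        # canonical order preservation
        firsts = [min(trace.selected_epochs(g)) for g in ("a+", "b+", "c+")]
        assert firsts == sorted(firsts)
        # contiguity: one interval per gesture
        for gid, ivs in trace.intervals.items():
            assert len(ivs) == 1


class TestRunSelection:
    def test_external_feedback_boundaries_follow_achievement(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig(external_delay_ms=50.0)
        mon = ScriptedMonitor(delay_ms=100.0)
        trace = sx.run_selection(wf, "external", mon, cfg, inventory)
        for ep in trace.epochs:
            assert ep.end == pytest.approx(ep.start + 150.0)
            assert ep.boundary_event == "external_feedback"
        # boundary strictly after achievement: a gap >= 0 between target
        # achievement and the next selection
        assert all(ep.end - (ep.start + 100.0) >= 0 for ep in trace.epochs)

    def test_internal_feedback_boundaries_precede_achievement(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig(internal_lead_ms=60.0)
        mon = ScriptedMonitor(delay_ms=100.0)
        trace = sx.run_selection(wf, "internal", mon, cfg, inventory)
        for ep in trace.epochs:
            assert ep.end == pytest.approx(ep.start + 40.0)
            assert ep.boundary_event == "internal_feedback"
        assert mon.rewinds  # trajectory rewound to each anticipated boundary

    def test_fixed_epochs_use_configured_durations(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig(epoch_ms=(100.0, 150.0, 200.0))
        trace = sx.run_selection(wf, "fixed_epochs", None, cfg, inventory)
        durations = [ep.end - ep.start for ep in trace.epochs]
        assert durations == [100.0, 150.0, 200.0]
        assert [ep.index for ep in trace.epochs] == [1, 2, 3]

    def test_timeout_names_the_unachieved_set(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig(timeout_ms=50.0)
        mon = ScriptedMonitor(delay_ms=100.0)
        with pytest.raises(UnachievedTargetError, match="S1"):
            sx.run_selection(wf, "external", mon, cfg, inventory)


class TestExcitationTrace:
    def test_levels_selected_queue_and_suppressed(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig()
        trace = sx.run_selection(wf, "fixed_epochs", None, cfg, inventory)
        times = np.arange(0.0, trace.t_end + 200.0, 1.0)
        traces = sx.excitation_trace(trace, cfg, times, ["a+", "b+", "c+", "zz"])
        a, b = traces["a+"].e, traces["b+"].e
        in_e1 = (times >= trace.epochs[0].start) & (times < trace.epochs[0].end)
        assert np.all(a[in_e1] == cfg.selected_level)
        # post-suppression excitation is strictly below every queue level
        after = times >= trace.epochs[0].end
        assert np.all(a[after] == cfg.suppressed_level)
        assert cfg.suppressed_level < min(cfg.queue_levels)
        # ready phase: descending queue levels by rank
        ready = times < trace.epochs[0].start
        assert np.all(a[ready] > b[ready])
        # a gesture outside the word form is flat zero
        assert np.all(traces["zz"].e == 0.0)

    def test_optional_ramps_stay_within_level_range(self, inventory):
        wf = three_set_form()
        cfg = sx.SelectionConfig(ramp_ms=10.0)
        trace = sx.run_selection(wf, "fixed_epochs", None, cfg, inventory)
        times = np.arange(0.0, trace.t_end + 100.0, 1.0)
        e = sx.excitation_trace(trace, cfg, times, ["b+"])["b+"].e
        assert e.min() >= cfg.suppressed_level - 1e-12
        assert e.max() <= cfg.selected_level + 1e-12
        # ramps make the trace continuous: no jump exceeds ramp slope * dt
        max_jump = (cfg.selected_level - cfg.suppressed_level) / cfg.ramp_ms * 1.0
        assert np.max(np.abs(np.diff(e))) <= max_jump + 1e-12
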