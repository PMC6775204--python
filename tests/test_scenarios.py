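"""End-to-end simulation runs, scenario library behavior, and I/O."""

from dataclasses import replace

import numpy as np
import pytest

import scintax as sx
from scintax.config_io import (
    load_result,
    load_scenario,
    save_result,
    save_scenario,
    scenario_from_dict,
    scenario_to_dict,
)
from scintax.errors import ConfigError


def neutral_only_scenario():
    return sx.Scenario(
        name="neutral_only",
        fields=(
            sx.FieldSpec("TTCD", neutral=sx.NeutralAttractor(0.5, 0.1, 0.1)),
            sx.FieldSpec("VEL", neutral=sx.NeutralAttractor(0.3, 0.1, 0.1)),
        ),
        inventory=(),
        timeline=sx.TimelineConfig(duration_ms=300.0),
    )


class TestRunSimulation:
    def test_no_gestures_targets_sit_at_neutral_centers(self):
        r = sx.run_simulation(neutral_only_scenario(), seed=0)
        assert r.targets["TTCD"][-1] == pytest.approx(0.5, abs=1e-6)
        # off-center attractors carry a small grid-truncation bias
        assert r.targets["VEL"][-1] == pytest.approx(0.3, abs=1e-3)
        assert r.tract["VEL"][-1] == pytest.approx(0.3, abs=2e-3)

    def test_identical_seeds_give_bit_identical_tables(self, run_cache):
        sc = sx.make_scenario("agreement_fig12a")
        r1 = sx.run_simulation(sc, seed=7)
        r2 = sx.run_simulation(sc, seed=7)
        assert np.array_equal(r1.targets["VEL"], r2.targets["VEL"])
        assert np.array_equal(r1.field_activation["VEL"], r2.field_activation["VEL"])
        assert r1.tract_frame().equals(r2.tract_frame())

    def test_all_library_scenarios_run_and_keep_traces_aligned(self, run_cache):
        for name in sx.SCENARIO_NAMES:
            r = run_cache(name)
            n = r.times.size
            for fid in r.grids:
                assert r.targets[fid].size == n
                assert r.tract[fid].size == n
                assert r.field_activation[fid].shape[0] == n
                assert np.all(r.field_activation[fid] >= 0)

    def test_unknown_scenario_name_lists_available(self):
        with pytest.raises(ConfigError, match="neutral_weak_release"):
            sx.make_scenario("nope")

    def test_undeclared_field_reference_reports_config_path(self):
        with pytest.raises(ConfigError, match=r"inventory\[0\]"):
            sx.Scenario(
                name="bad",
                fields=(sx.FieldSpec("TTCD"),),
                inventory=(sx.Gesture("g+", "LA", "+", mu=0.5, sigma=0.08),),
                timeline=sx.TimelineConfig(duration_ms=100.0),
            )


class TestReleaseDemos:
    def test_strong_constant_neutral_causes_target_undershoot(self, run_cache):
        r = run_cache("neutral_strong_undershoot")
        peak = r.tract["TTCD"].max()
        assert peak < 0.9 - 0.05  # misses the constriction target

    def test_weak_neutral_avoids_undershoot(self, run_cache):
        r = run_cache("neutral_weak_release")
        assert r.tract["TTCD"].max() > 0.9 - 0.05

    def test_active_release_gesture_beats_weak_neutral_release(self, run_cache):
        """Constriction release driven by an opening gesture is faster than
        passive relaxation toward a weak neutral attractor."""

        def release_time(r):
            end = r.epochs[0].end  # suppression of the constriction set
            after = r.times >= end
            below = r.tract["TTCD"][after] <= 0.55
            assert below.any()
            return r.times[after][np.argmax(below)] - end

        assert release_time(run_cache("split_gesture_release")) < release_time(
            run_cache("neutral_weak_release")
        )


class TestSubSelectionInfluence:
    def test_strong_gating_makes_unselected_gestures_negligible(self):
        sc = sx.make_scenario("assimilation_fig5a")
        strong_b = replace(
            sc.inventory_map["B+"], gating=sx.strong_gating()
        )
        # sub-selection excitation sits at the top queue level of the ladder
        queue = sx.SelectionConfig().queue_levels[0]
        sc2 = replace(
            sc,
            inventory=(sc.inventory_map["A+"], strong_b),
            free_excitations={**sc.free_excitations, "B+": queue},
        )
        r = sx.run_simulation(sc2, 0)
        c = sx.run_simulation(sc2.control(), 0)
        shift = sx.shift_vs_control(r, c, "TV", (300, 400))
        assert abs(shift) < 1e-3

    def test_leaky_gating_makes_unselected_gestures_material(self, run_cache):
        r = run_cache("assimilation_fig5a")
        c = run_cache("assimilation_fig5a", control=True)
        assert abs(sx.shift_vs_control(r, c, "TV", (300, 400))) > 0.01


class TestFeedbackModes:
    def test_internal_mode_boundary_precedes_external_boundary(self):
        base = sx.make_scenario("anticipatory_posture_fig10")
        internal = replace(
            base, timeline=replace(base.timeline, feedback_mode="internal")
        )
        r_ext = sx.run_simulation(base, 0)
        r_int = sx.run_simulation(internal, 0)
        assert r_int.epochs[0].end < r_ext.epochs[0].end
        # internal boundary precedes achievement: the tract variable is not
        # yet inside the achievement band at the boundary
        t_b = r_int.epochs[0].end
        i = int(np.searchsorted(r_int.times, t_b))
        assert abs(r_int.tract["TTCD"][i] - 0.9) > 0.05

    def test_achievement_timeout_is_reported(self):
        sc = sx.make_scenario("anticipatory_posture_fig10")
        sc = replace(sc, selection=replace(sc.selection, timeout_ms=20.0))
        with pytest.raises(sx.UnachievedTargetError, match="na"):
            sx.run_simulation(sc, 0)


class TestConfigIO:
    def test_dict_roundtrip_preserves_scenario(self):
        sc = sx.make_scenario("agreement_fig12a")
        d = scenario_to_dict(sc)
        sc2 = scenario_from_dict(d)
        assert scenario_to_dict(sc2) == d

    @pytest.mark.parametrize("ext", ["yaml", "json"])
    def test_file_roundtrip(self, tmp_path, ext):
        sc = sx.make_scenario("blocking_fig11d")
        path = tmp_path / f"scenario.{ext}"
        save_scenario(sc, path)
        sc2 = load_scenario(path)
        assert scenario_to_dict(sc2) == scenario_to_dict(sc)

    def test_invalid_config_names_path(self):
        with pytest.raises(ConfigError, match=r"fields\[0\]\.tract_variable"):
            scenario_from_dict({"fields": [{}], "inventory": []}, path="config")

    def test_saved_run_reloads_with_equal_classification(self, tmp_path, run_cache):
        r = run_cache("agreement_fig12a")
        c = run_cache("agreement_fig12a", control=True)
        save_result(r, tmp_path / "run")
        save_result(c, tmp_path / "control")
        r2 = load_result(tmp_path / "run")
        c2 = load_result(tmp_path / "control")
        rep = sx.classify_harmony_outcome(r2, c2, "x+")
        assert rep.classification == "agreement"
        assert rep.transparent_epochs == (2,)

    def test_score_frame_has_selected_and_blocked_rows(self, run_cache):
        frame = run_cache("blocking_fig11d").score_frame()
        assert set(frame["status"]) == {"selected", "blocked_attempt"}
        blocked = frame[frame["status"] == "blocked_attempt"]
        assert "x+" in set(blocked["gesture_id"])


class TestCLI:
    def test_scenario_run_and_classify(self, tmp_path):
        from click.testing import CliRunner

        from scintax.cli import main

        runner = CliRunner()
        out_run = tmp_path / "run"
        out_ctl = tmp_path / "ctl"
        for args in (
            ["scenario", "agreement_fig12a", "--out", str(out_run)],
            ["scenario", "agreement_fig12a", "--control", "--out", str(out_ctl)],
        ):
            res = runner.invoke(main, args, catch_exceptions=False)
            assert res.exit_code == 0, res.output
        res = runner.invoke(
            main,
            ["classify", "--run", str(out_run), "--control", str(out_ctl)],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        assert '"classification": "agreement"' in res.output

    def test_simulate_from_config_file(self, tmp_path):
        from click.testing import CliRunner

        from scintax.cli import main

        save_scenario(sx.make_scenario("assimilation_fig5a"), tmp_path / "cfg.yaml")
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["simulate", "--config", str(tmp_path / "cfg.yaml"),
             "--out", str(tmp_path / "out"), "--seed", "3"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        assert (tmp_path / "out" / "targets.csv").exists()

    def test_list_names_all_scenarios(self):
        from click.testing import CliRunner

        from scintax.cli import main

        res = CliRunner().invoke(main, ["list"])
        for name in sx.SCENARIO_NAMES:
            assert name in res.output


def test_field_heatmap_smoke(tmp_path, run_cache):
    from scintax.plotting import field_heatmap

    ax = field_heatmap(run_cache("agreement_fig12a"), "VEL")
    ax.figure.savefig(tmp_path / "heat.png", dpi=50)
    assert (tmp_path / "heat.png").stat().st_size > 0
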