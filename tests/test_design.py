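"""The CMA-ES optimiser, the iterative 3-step designer and its variants."""

import numpy as np
import pytest

from vcdesign.cmaes import cmaes_minimize
from vcdesign.design import (
    DesignConfig,
    _SpacefillEvaluator,
    iterative_design,
    optimise_unit,
    spacefill_design,
    squarewave_discrimination_design,
)
from vcdesign.gating import beattie_model
from vcdesign.objectives import (
    PhaseGrid,
    beattie_phase_trajectory,
    model_discrimination_objective,
    phase_coverage,
)
from vcdesign.protocols import common_head

FAST = dict(n_restarts=1, max_iter=10, popsize=6)


class TestCmaes:
    def test_recovers_quadratic_optimum(self, rng):
        target = np.array([0.3, -1.2, 2.5])
        res = cmaes_minimize(lambda x: np.sum((x - target) ** 2),
                             np.zeros(3), 1.0 / 6.0,
                             np.array([-5.0, -5.0, -5.0]),
                             np.array([5.0, 5.0, 5.0]),
                             rng, max_iter=300)
        assert np.abs(res.x - target).max() < 1e-3

    def test_respects_box_constraints(self, rng):
        res = cmaes_minimize(lambda x: float(np.sum(x)), np.array([0.5]),
                             1.0 / 6.0, np.array([-1.0]), np.array([1.0]),
                             rng, max_iter=100)
        assert -1.0 <= res.x[0] <= 1.0
        assert res.fun == pytest.approx(-1.0, abs=1e-6)

    def test_deterministic_given_generator_state(self):
        f = lambda x: float(np.sum(x ** 2))
        runs = [cmaes_minimize(f, np.full(2, 0.7), 1 / 6,
                               np.full(2, -2.0), np.full(2, 2.0),
                               np.random.default_rng(99), max_iter=50)
                for _ in range(2)]
        assert np.array_equal(runs[0].x, runs[1].x)


class _QuadraticEvaluator:
    """Toy unit evaluator with a known in-bounds maximiser."""

    def __init__(self, v_opt=(-20.0, 10.0, 30.0), dt_opt=(100.0, 400.0, 700.0)):
        self.v_opt = np.asarray(v_opt)
        self.dt_opt = np.asarray(dt_opt)

    def evaluate(self, voltages, durations):
        dv = (np.asarray(voltages) - self.v_opt) / 180.0
        ddt = (np.asarray(durations) - self.dt_opt) / 950.0
        return -float(np.sum(dv ** 2) + np.sum(ddt ** 2))

    def accept(self, voltages, durations):
        pass


class TestOptimiseUnit:
    def test_recovers_known_maximiser_on_rounding_grid(self):
        cfg = DesignConfig(n_restarts=3, max_iter=150, popsize=8, seed=5)
        ev = _QuadraticEvaluator()
        unit, score = optimise_unit(ev, cfg, np.random.default_rng(5))
        assert np.abs(np.array(unit.voltages) - ev.v_opt).max() <= 0.1 + 1e-9
        assert np.abs(np.array(unit.durations) - ev.dt_opt).max() <= 0.5

    def test_constant_objective_returns_valid_unit(self):
        class Flat:
            def evaluate(self, v, d):
                return 1.0

            def accept(self, v, d):
                pass

        cfg = DesignConfig(**FAST, seed=0)
        unit, score = optimise_unit(Flat(), cfg, np.random.default_rng(0))
        assert score == 1.0
        assert all(-120.0 <= v <= 60.0 for v in unit.voltages)
        assert all(50.0 <= d <= 1000.0 for d in unit.durations)

    def test_rounded_to_hardware_resolution(self):
        cfg = DesignConfig(**FAST, seed=1)
        unit, _ = optimise_unit(_QuadraticEvaluator(), cfg,
                                np.random.default_rng(1))
        for x in unit.voltages + unit.durations:
            assert round(x * 10) == pytest.approx(x * 10, abs=1e-9)

    def test_gibbs_freezes_durations(self):
        cfg = DesignConfig(**FAST, seed=3, gibbs_mode="random_dt",
                           random_dt_range=(50.0, 500.0))
        rng = np.random.default_rng(3)
        ref_draw = np.round(np.random.default_rng(3).uniform(-120, 60, 3), 1)  # V draw first
        unit, _ = optimise_unit(_QuadraticEvaluator(), cfg, rng)
        assert unit.free_mask == (True, True, True, False, False, False)
        assert all(50.0 <= d <= 500.0 for d in unit.durations)
        # frozen scalars appear in the output exactly as drawn (0.1 grid)
        rng2 = np.random.default_rng(3)
        np.round(rng2.uniform(-120, 60, 3), 1)
        expected_dt = np.round(rng2.uniform(50, 500, 3) / 0.1) * 0.1
        assert np.array_equal(np.array(unit.durations), expected_dt)


class TestIterativeDesign:
    def test_seventeen_units_give_51_steps_and_64_commands(self):
        cfg = DesignConfig(objective="spacefill", n_units=17, seed=2,
                           n_restarts=1, max_iter=3, popsize=4)
        res = iterative_design(cfg)
        assert len(res.body) == 51
        assert res.n_commands == 64
        res.protocol.validate_for_hardware()

    def test_reproducible_from_seed(self):
        cfg = DesignConfig(objective="spacefill", n_units=2, seed=42, **FAST)
        a = iterative_design(cfg)
        b = iterative_design(cfg)
        assert a.units == b.units
        assert a.unit_scores == b.unit_scores

    def test_per_parameter_objective_defaults_to_parameter_count(self):
        cfg = DesignConfig(objective="local_sens", seed=1,
                           n_restarts=1, max_iter=2, popsize=4)
        res = iterative_design(cfg)
        assert len(res.units) == 8  # one unit per kinetic parameter
        assert all(0.0 <= s <= 1.0 for s in res.unit_scores)

    def test_alternating_gibbs_mask_pattern(self):
        cfg = DesignConfig(objective="discrim", n_units=4, seed=7,
                           gibbs_mode="alternating", n_restarts=1,
                           max_iter=2, popsize=4)
        res = iterative_design(cfg)
        masks = [u.free_mask for u in res.units]
        # odd (1-based) units optimise voltages, even units durations
        assert masks[0] == (True, True, True, False, False, False)
        assert masks[1] == (False, False, False, True, True, True)
        assert masks[2] == masks[0] and masks[3] == masks[1]

    def test_spacefill_scores_match_final_protocol_recount(self, beattie):
        # cumulative new-box counts re-derivable from the exported protocol
        cfg = DesignConfig(objective="spacefill", n_units=3, seed=9, **FAST)
        res = iterative_design(cfg)
        head = common_head()
        grid = PhaseGrid()
        _, visited_head = phase_coverage(
            beattie_phase_trajectory(beattie, head), grid)
        head_body = head.concat(res.body)
        _, visited_all = phase_coverage(
            beattie_phase_trajectory(beattie, head_body), grid)
        assert sum(res.unit_scores) == len(visited_all) - len(visited_head)

    def test_discrim_score_matches_objective_reevaluation(self, beattie, wang):
        cfg = DesignConfig(objective="discrim", n_units=2, seed=11, **FAST)
        res = iterative_design(cfg)
        context = common_head().concat(res.units[0].as_protocol())
        ref = model_discrimination_objective(res.units[1], context, beattie, wang)
        assert res.unit_scores[1] == pytest.approx(ref, abs=1e-6)


class TestSpacefillSelection:
    def test_selection_criteria_and_bounds(self):
        cfg = DesignConfig(objective="spacefill", n_units=2, seed=3,
                           sample_m=10, **FAST)
        sel = spacefill_design(cfg, n_runs=2)
        assert len(sel.results) == 2
        assert all(0 < c <= 216 for c in sel.coverages)
        assert sel.coverages[sel.best_by_coverage] == max(sel.coverages)
        assert sel.discrimination[sel.best_by_discrimination] == max(sel.discrimination)
        assert sel.spread[sel.best_by_spread] == max(sel.spread)

    def test_identical_models_tie_broken_by_run_index(self):
        cfg = DesignConfig(objective="spacefill", model_b="beattie",
                           n_units=1, seed=3, sample_m=5, **FAST)
        sel = spacefill_design(cfg, n_runs=2)
        assert all(d == 0.0 for d in sel.discrimination)
        assert sel.best_by_discrimination == 0

    def test_invalid_run_count(self):
        with pytest.raises(ValueError, match="n_runs"):
            spacefill_design(DesignConfig(), n_runs=0)

    def test_cumulative_coverage_non_decreasing(self, beattie):
        cfg = DesignConfig(objective="spacefill", n_units=3, seed=4, **FAST)
        ev = _SpacefillEvaluator(beattie, common_head(), cfg)
        before = ev.coverage
        for unit_v, unit_dt in (((-40.0, 20.0, -100.0), (60.0, 60.0, 60.0)),
                                ((0.0, 0.0, 0.0), (100.0, 100.0, 100.0))):
            ev.accept(unit_v, unit_dt)
            assert ev.coverage >= before
            before = ev.coverage


class TestSquareWaveDesign:
    CHEAP = dict(duration=200.0, n_components=2)

    def test_identical_models_score_zero(self):
        cfg = DesignConfig(model_b="beattie", seed=1, n_restarts=1,
                           max_iter=3, popsize=4)
        res = squarewave_discrimination_design(cfg, **self.CHEAP)
        assert res.score == 0.0

    def test_score_matches_from_scratch_recomputation(self, beattie, wang):
        from vcdesign.protocols import common_head
        from vcdesign.simulation import simulate
        cfg = DesignConfig(seed=2, n_restarts=1, max_iter=3, popsize=4)
        res = squarewave_discrimination_design(cfg, **self.CHEAP)
        protocol = common_head().concat(res.body)
        t_head = common_head().total_duration
        ia = simulate(beattie, protocol).current
        ib = simulate(wang, protocol).current
        times = np.arange(len(ia)) * 1.0
        window = times >= t_head
        from vcdesign.simulation import rmsd
        assert res.score == pytest.approx(rmsd(ia[window], ib[window]), abs=1e-6)

    def test_boundary_hit_warning_fires(self):
        # squeeze the amplitude box so the optimum must sit on a bound
        cfg = DesignConfig(seed=3, n_restarts=1, max_iter=5, popsize=4)
        with pytest.warns(UserWarning, match="bounds"):
            res = squarewave_discrimination_design(
                cfg, duration=200.0, n_components=1,
                amplitude_bounds=(1.0, 2.0))
        assert res.boundary_hit

    def test_offset_fixed(self):
        cfg = DesignConfig(seed=4, n_restarts=1, max_iter=2, popsize=4)
        res = squarewave_discrimination_design(cfg, **self.CHEAP)
        assert res.spec.offset == -30.0
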