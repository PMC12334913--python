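"""Design objectives: sensitivity shares, Sobol estimator, spread, coverage."""

import numpy as np
import pytest

from vcdesign.objectives import (
    DesignUnit,
    PhaseGrid,
    brute_force_spread_objective,
    local_sensitivity_objective,
    model_discrimination_objective,
    pairwise_rmsd_spread,
    phase_coverage,
    saltelli_sample,
    sample_parameters,
    sobol_first_order_indices,
    sobol_first_order_objective,
)

UNIT = DesignUnit((40.0, -40.0, -80.0), (200.0, 200.0, 200.0))


class TestLocalSensitivityObjective:
    def test_partition_of_unity(self, beattie, head):
        shares = [local_sensitivity_objective(i, UNIT, head, beattie)
                  for i in range(8)]
        assert all(0.0 <= s <= 1.0 for s in shares)
        assert sum(shares) == pytest.approx(1.0, abs=1e-12)

    def test_informative_unit_beats_closed_unit(self, beattie, head):
        # a unit pinned at -120 mV keeps the channel shut, so the share of
        # the recovery-rate prefactor is no better than with a tail-current
        # provoking +40/-40 pair
        closed = DesignUnit((-120.0, -120.0, -120.0), (200.0, 200.0, 200.0))
        active = DesignUnit((40.0, -40.0, -40.0), (500.0, 100.0, 200.0))
        i_p7 = 6
        assert (local_sensitivity_objective(i_p7, closed, head, beattie)
                <= local_sensitivity_objective(i_p7, active, head, beattie))

    def test_invalid_index_rejected(self, beattie, head):
        with pytest.raises(IndexError):
            local_sensitivity_objective(8, UNIT, head, beattie)


class TestSobolEstimator:
    def test_linear_model_analytic_indices(self):
        # Y = sum c_k Z_k with independent uniform Z_k: the first-order
        # index of Z_k is c_k^2 Var(Z_k) / sum_j c_j^2 Var(Z_j)
        c = np.array([3.0, 2.0, 1.0, 0.5])
        lower = np.array([1.0, 1.0, 1.0, 1.0])
        upper = np.array([3.0, 5.0, 2.0, 4.0])
        n_base = 4096
        x = saltelli_sample(lower, upper, n_base, seed=7, scale="linear")
        y = (x * c).sum(axis=1, keepdims=True)
        est = sobol_first_order_indices(y, n_base, 4)[:, 0]
        var_z = (upper - lower) ** 2 / 12.0
        expected = c ** 2 * var_z / np.sum(c ** 2 * var_z)
        assert np.abs(est - expected).max() < 0.02

    def test_single_parameter_dependence(self):
        lower = np.full(3, 0.1)
        upper = np.full(3, 2.0)
        n_base = 1024
        x = saltelli_sample(lower, upper, n_base, seed=3, scale="linear")
        y = np.sin(x[:, [1]])
        est = sobol_first_order_indices(y, n_base, 3)[:, 0]
        assert abs(est[1] - 1.0) < 0.05
        assert abs(est[0]) < 0.05 and abs(est[2]) < 0.05

    def test_seed_stability(self):
        c = np.array([2.0, 1.0])
        lower, upper = np.array([0.0, 0.0]) + 1e-6, np.array([1.0, 1.0])
        ests = []
        for seed in (1, 2):
            x = saltelli_sample(lower, upper, 4096, seed=seed, scale="linear")
            y = (x * c).sum(axis=1, keepdims=True)
            ests.append(sobol_first_order_indices(y, 4096, 2)[:, 0])
        assert np.abs(ests[0] - ests[1]).max() < 0.05

    def test_objective_bounded_and_deterministic(self, beattie, head):
        kwargs = dict(n_base=16, seed=5)
        a = sobol_first_order_objective(0, UNIT, head, beattie, **kwargs)
        b = sobol_first_order_objective(0, UNIT, head, beattie, **kwargs)
        assert a == b
        assert 0.0 <= a <= 1.0

    def test_block_structure_enforced(self):
        with pytest.raises(ValueError, match="Saltelli"):
            sobol_first_order_indices(np.zeros((10, 1)), 4, 2)


class TestSpreadObjective:
    def test_hand_value_on_constant_traces(self):
        # three constant traces 0, 1, 2: 2/9 * (1 + 2 + 1) = 8/9
        traces = np.repeat(np.array([[0.0], [1.0], [2.0]]), 5, axis=1)
        assert pairwise_rmsd_spread(traces) == pytest.approx(8.0 / 9.0)

    def test_two_traces_half_rmsd(self, rng):
        x = rng.normal(size=(2, 64))
        from vcdesign.simulation import rmsd
        assert pairwise_rmsd_spread(x) == pytest.approx(rmsd(x[0], x[1]) / 2.0)

    def test_identical_traces_zero(self):
        assert pairwise_rmsd_spread(np.ones((5, 10))) == 0.0

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=(6, 32))
        perm = rng.permutation(6)
        assert pairwise_rmsd_spread(x[perm]) == pytest.approx(
            pairwise_rmsd_spread(x), rel=1e-12)

    def test_identical_parameter_samples_score_zero(self, beattie, head):
        from vcdesign.objectives import ParameterSampleSet
        values = np.repeat(beattie.params.values[None, :], 3, axis=0)
        samples = ParameterSampleSet(values, "linear", 0)
        assert brute_force_spread_objective(UNIT, head, beattie, samples) == \
            pytest.approx(0.0, abs=1e-12)

    def test_m_below_two_rejected(self):
        from vcdesign.objectives import ParameterSampleSet
        with pytest.raises(ValueError, match="M=2"):
            ParameterSampleSet(np.ones((1, 8)), "log", 0)


class TestParameterSampling:
    def test_samples_within_bounds(self, beattie):
        s = sample_parameters(beattie.ranges, 200, seed=11)
        assert np.all(s.values >= beattie.ranges.lower)
        assert np.all(s.values <= beattie.ranges.upper)

    def test_log_sampling_reaches_lower_decades(self, wang):
        # kb spans ~5 decades; log-uniform draws must populate the bottom
        # decade which linear draws would essentially never hit
        lo = wang.ranges.lower[0]
        log_s = sample_parameters(wang.ranges, 500, seed=11, scale="log")
        lin_s = sample_parameters(wang.ranges, 500, seed=11, scale="linear")
        frac_log = np.mean(log_s.values[:, 0] < 10 * lo)
        frac_lin = np.mean(lin_s.values[:, 0] < 10 * lo)
        assert frac_log > 0.1
        assert frac_lin < 0.01

    def test_reproducibility(self, beattie):
        a = sample_parameters(beattie.ranges, 50, seed=4)
        b = sample_parameters(beattie.ranges, 50, seed=4)
        assert np.array_equal(a.values, b.values)


class TestDiscriminationObjective:
    def test_same_model_scores_zero(self, beattie, head):
        assert model_discrimination_objective(UNIT, head, beattie, beattie) == 0.0

    def test_symmetric_in_model_order(self, beattie, wang, head):
        ab = model_discrimination_objective(UNIT, head, beattie, wang)
        ba = model_discrimination_objective(UNIT, head, wang, beattie)
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_flicker_beats_rest(self, beattie, wang, head):
        flicker = DesignUnit((40.0, -120.0, 40.0), (50.0, 50.0, 50.0))
        rest = DesignUnit((-80.0, -80.0, -80.0), (200.0, 200.0, 200.0))
        assert (model_discrimination_objective(flicker, head, beattie, wang)
                > model_discrimination_objective(rest, head, beattie, wang))


class TestPhaseGrid:
    def test_box_count(self):
        assert PhaseGrid().n_boxes == 216

    def test_constant_trajectory_covers_one_box(self):
        traj = np.tile([0.3, 0.7, -50.0], (100, 1))
        count, visited = phase_coverage(traj, PhaseGrid())
        assert count == 1 and len(visited) == 1

    def test_visited_set_accumulates(self):
        grid = PhaseGrid()
        t1 = np.array([[0.05, 0.05, -110.0]])
        t2 = np.array([[0.05, 0.05, -110.0], [0.95, 0.95, 50.0]])
        c1, visited = phase_coverage(t1, grid)
        c2, visited = phase_coverage(t2, grid, visited)
        assert (c1, c2) == (1, 1)
        assert len(visited) == 2

    def test_vectorised_binning_matches_per_point_loop(self, rng):
        grid = PhaseGrid()
        pts = np.column_stack([rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000),
                               rng.uniform(-120, 60, 1000)])
        vec = set(int(b) for b in grid.box_indices(pts))
        loop = set()
        for a, r, v in pts:
            ia = min(int(a * 6), 5)
            ir = min(int(r * 6), 5)
            iv = min(int((v + 120.0) / 180.0 * 6), 5)
            loop.add((ia * 6 + ir) * 6 + iv)
        assert vec == loop

    def test_top_edges_closed(self):
        grid = PhaseGrid()
        idx = grid.box_indices(np.array([[1.0, 1.0, 60.0]]))
        assert idx[0] == 216 - 1

    def test_out_of_bounds_clamped_with_warning(self):
        grid = PhaseGrid()
        with pytest.warns(UserWarning, match="clamped"):
            idx = grid.box_indices(np.array([[1.2, -0.1, 200.0]]))
        assert 0 <= idx[0] < 216
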