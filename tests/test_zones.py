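import math

import numpy as np
import pytest

from triloci import (
    SurvivalZoneModel,
    apply_random_frames,
    default_grid,
    fix_centers,
    grid_size,
    model_objective,
    pca_norm,
    sample_configurations,
    solve_zones,
)
from triloci.errors import DegenerateInputError
from triloci.geometry import triangle_variables
from triloci.zones import experimental_correlations


class TestPCANorm:
    def test_perfectly_correlated_columns(self, rng):
        x = rng.normal(size=100)
        nc = pca_norm(np.column_stack([x, 2 * x + 1, -0.5 * x]))
        np.testing.assert_allclose(np.abs(nc.C), 1.0, atol=1e-12)
        np.testing.assert_allclose(nc.P, [3.0, 0.0, 0.0], atol=1e-9)

    def test_independent_columns(self, rng):
        nc = pca_norm(rng.normal(size=(10_000, 3)))
        off = nc.C[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        np.testing.assert_allclose(nc.P, 1.0, atol=0.05)

    def test_trace_is_three(self, rng):
        nc = pca_norm(rng.uniform(size=(50, 3)))
        assert np.trace(nc.C) == pytest.approx(3.0)
        assert nc.P.sum() == pytest.approx(3.0, abs=1e-9)

    def test_zero_variance_column_named(self, rng):
        bad = rng.normal(size=(50, 3))
        bad[:, 1] = 7.0
        with pytest.raises(DegenerateInputError, match="d_i2"):
            pca_norm(bad)


class TestFixCenters:
    def test_equal_means_symmetric_apex(self):
        m = fix_centers(1.0, 1.0, 1.0)
        np.testing.assert_allclose(m.centers[0], [0.0, 0.0])
        np.testing.assert_allclose(m.centers[2], [5.0, 0.0])
        np.testing.assert_allclose(m.centers[1], [2.5, 5 * math.sqrt(3) / 2], atol=1e-12)
        assert m.provenance["r0"] == pytest.approx(5.0)

    def test_three_four_five_triangle(self):
        m = fix_centers(3.0, 4.0, 5.0)
        assert m.provenance == {"r0": pytest.approx(3.0), "r1": pytest.approx(4.0)}
        np.testing.assert_allclose(m.centers[1], [1.8, 2.4], atol=1e-12)

    def test_degenerate_collinear_means(self, caplog):
        m = fix_centers(1.0, 1.0, 2.0)
        np.testing.assert_allclose(m.centers[1], [2.5, 0.0], atol=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fix_centers(0.0, 1.0, 1.0)


class TestSampleConfigurations:
    def test_zero_halfwidths_collapse_to_centers(self):
        m = fix_centers(1.0, 1.0, 1.0)
        cfg = sample_configurations(m, 20, seed=0)
        np.testing.assert_allclose(cfg.configs, np.broadcast_to(m.centers, (20, 3, 2)))

    def test_containment_and_uniform_variance(self):
        centers = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 0.0]])
        eps = np.array([1.0, 0.5, 3.0, 2.0, 1.5, 0.25])
        m = SurvivalZoneModel.from_eps(centers, eps)
        cfg = sample_configurations(m, 10_000, seed=3)
        for i, zone in enumerate(m.zones):
            assert zone.contains(cfg.configs[:, i, :]).all()
        # per-axis variance of U[c-e, c+e] is e^2/3
        var = cfg.configs.var(axis=0)
        np.testing.assert_allclose(var, (eps.reshape(3, 2) ** 2) / 3.0, rtol=0.05)

    def test_seed_reproducibility(self):
        m = SurvivalZoneModel.from_eps(np.zeros((3, 2)) + [[0, 0], [2, 2], [5, 0]],
                                       np.ones(6))
        a = sample_configurations(m, 50, seed=9).configs
        b = sample_configurations(m, 50, seed=9).configs
        c = sample_configurations(m, 50, seed=10).configs
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestObjective:
    def _model(self):
        centers = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 0.0]])
        return SurvivalZoneModel.from_eps(centers, [1, 1, 3, 3, 1.5, 1.5])

    def test_identity_is_zero(self):
        cfg = sample_configurations(self._model(), 500, seed=1)
        expC = experimental_correlations(triangle_variables(cfg.configs))
        assert model_objective(expC, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_offdiagonal_perturbation_adds_sqrt2_delta(self):
        cfg = sample_configurations(self._model(), 500, seed=1)
        expC = experimental_correlations(triangle_variables(cfg.configs))
        delta = 0.07
        expC[0].C[0, 1] += delta
        expC[0].C[1, 0] += delta
        assert model_objective(expC, cfg) == pytest.approx(math.sqrt(2) * delta)

    def test_nonnegative(self):
        cfg = sample_configurations(self._model(), 400, seed=2)
        other = sample_configurations(self._model(), 400, seed=3)
        expC = experimental_correlations(triangle_variables(other.configs))
        assert model_objective(expC, cfg) >= 0.0


class TestGrid:
    def test_trivial_sizes(self):
        assert grid_size([np.array([1.0])] * 6) == 1
        assert grid_size([np.array([1.0, 2.0, 3.0])] * 2 + [np.array([1.0])] * 4) == 3**2

    def test_publication_default_cardinality(self):
        assert grid_size(default_grid()) == 5**12

    def test_default_grid_excludes_zero(self):
        grid = default_grid()
        for axis in grid:
            assert axis[0] == pytest.approx(0.2)
            assert axis[-1] == pytest.approx(5.0)
            assert len(axis) == 25


class TestSolver:
    def test_single_candidate_grid(self, moderate_dataset):
        grid = [np.array([v]) for v in (1.0, 1.0, 3.0, 3.0, 1.5, 1.5)]
        res = solve_zones(moderate_dataset, grid=grid, m_configs=500, seed=0)
        np.testing.assert_allclose(res.best_eps, [1, 1, 3, 3, 1.5, 1.5])
        assert res.evaluations == 1

    def test_determinism_and_worker_independence(self, moderate_dataset):
        grid = [np.array([1.0, 3.0])] * 6
        res1 = solve_zones(moderate_dataset, grid=grid, m_configs=500, seed=4)
        res2 = solve_zones(moderate_dataset, grid=grid, m_configs=500, seed=4)
        res3 = solve_zones(moderate_dataset, grid=grid, m_configs=500, seed=4, workers=2)
        np.testing.assert_array_equal(res1.best_eps, res2.best_eps)
        assert res1.best_objective == res2.best_objective
        np.testing.assert_array_equal(res1.best_eps, res3.best_eps)
        assert res1.best_objective == res3.best_objective
        assert res1.evaluations == 2**6

    def test_objective_invariant_under_rigid_transform(self, moderate_dataset):
        grid = [np.array([v]) for v in (1.0, 2.0, 3.0, 3.0, 1.0, 2.0)]
        res_a = solve_zones(moderate_dataset, grid=grid, m_configs=400, seed=6,
                            parsimony_z=0)
        moved = apply_random_frames(moderate_dataset, seed=123)
        res_b = solve_zones(moved, grid=grid, m_configs=400, seed=6, parsimony_z=0)
        assert res_a.best_objective == pytest.approx(res_b.best_objective, abs=1e-9)

    def test_empty_grid_rejected(self, moderate_dataset):
        with pytest.raises(ValueError):
            solve_zones(moderate_dataset, grid=[np.array([])] * 6)

    def test_result_serializes(self, moderate_dataset):
        import json

        grid = [np.array([1.0])] * 6
        res = solve_zones(moderate_dataset, grid=grid, m_configs=200, seed=1)
        blob = json.dumps(res.to_dict())
        assert "best_eps" in blob
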