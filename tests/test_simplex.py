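"""Box-constrained Nelder-Mead: geometry, step logic and convergence."""

import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize

from hrfit.simplex import (
    NMConfig,
    OptimizationError,
    Simplex,
    centroid,
    initial_simplex,
    minimize,
    nm_step,
    order_vertices,
)


def unit_box(n):
    return np.tile([0.0, 1.0], (n, 1))


class TestInitialSimplex:
    @pytest.mark.parametrize("n", [2, 12])
    def test_spendley_edges_all_have_length_a(self, n):
        a = 1.0
        verts = initial_simplex(np.zeros(n), a)
        assert verts.shape == (n + 1, n)
        for i in range(n + 1):
            for j in range(i + 1, n + 1):
                assert np.linalg.norm(verts[i] - verts[j]) == pytest.approx(
                    a, abs=1e-12
                )

    def test_offsets_scale_linearly_with_a(self):
        x0 = np.full(3, 0.5)
        v1 = initial_simplex(x0, 0.1)
        v2 = initial_simplex(x0, 0.3)
        assert np.allclose(v2 - x0, 3.0 * (v1 - x0), rtol=1e-12)

    def test_anchor_point_is_a_vertex(self):
        x0 = np.array([0.2, 0.7])
        verts = initial_simplex(x0, 0.1)
        assert np.allclose(verts[-1], x0)

    def test_clipping_keeps_vertices_inside_the_box(self):
        b = unit_box(4)
        verts = initial_simplex(np.ones(4), 0.5, bounds=b)  # anchored on a face
        assert np.all(verts >= 0.0) and np.all(verts <= 1.0)

    def test_nonpositive_size_is_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            initial_simplex(np.zeros(2), 0.0)


class TestOrderingAndCentroid:
    def test_best_second_worst(self):
        s = Simplex(np.zeros((3, 2)), np.array([3.0, 1.0, 2.0]))
        il, is_, ih = order_vertices(s)
        assert (il, is_, ih) == (1, 2, 0)

    def test_ties_break_by_vertex_index(self):
        s = Simplex(np.zeros((3, 2)), np.array([1.0, 1.0, 1.0]))
        il, _, ih = order_vertices(s)
        assert il == 0 and ih == 2

    def test_ordering_matches_sort_oracle(self, rng):
        vals = rng.normal(size=13)
        s = Simplex(rng.normal(size=(13, 12)), vals)
        il, is_, ih = order_vertices(s)
        order = np.argsort(vals)
        assert il == order[0] and is_ == order[-2] and ih == order[-1]

    def test_centroid_excludes_the_worst(self):
        verts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        s = Simplex(verts, np.array([0.0, 1.0, 5.0]))
        assert np.allclose(centroid(s, 2), [1.0, 0.0])

    def test_degenerate_simplex_centroid(self):
        verts = np.tile([0.3, 0.4], (3, 1))
        s = Simplex(verts, np.zeros(3))
        assert np.allclose(centroid(s, 0), [0.3, 0.4])

    def test_centroid_matches_loop_oracle(self, rng):
        verts = rng.normal(size=(13, 12))
        s = Simplex(verts, rng.normal(size=13))
        out = centroid(s, 7)
        oracle = sum(verts[i] for i in range(13) if i != 7) / 12.0
        assert np.allclose(out, oracle, rtol=1e-12)


class TestNmStep:
    def _simplex(self, f, verts):
        return Simplex(np.asarray(verts, float), np.array([f(v) for v in verts]))

    def test_reflection_improves_on_convex_geometry(self):
        f = lambda x: float((x[0] - 0.5) ** 2 + (x[1] - 0.5) ** 2)
        s = self._simplex(f, [[0.4, 0.4], [0.6, 0.4], [0.9, 0.9]])
        s2, _ = nm_step(s, NMConfig(), f)
        assert s2.values.min() <= s.values.min()
        assert s2.values.max() < s.values.max()

    def test_candidates_are_clipped_to_the_box(self):
        # worst vertex at the centre, reflection would leave the box
        f = lambda x: float(-np.sum(x))
        b = unit_box(2)
        s = self._simplex(f, [[1.0, 0.9], [0.9, 1.0], [0.1, 0.1]])
        s2, _ = nm_step(s, NMConfig(), f, bounds=b)
        assert np.all(s2.vertices >= 0.0) and np.all(s2.vertices <= 1.0)

    def test_best_vertex_never_degrades(self, rng):
        f = lambda x: float(np.sin(3 * x[0]) + (x[1] - 0.3) ** 2)
        verts = rng.uniform(size=(3, 2))
        s = self._simplex(f, verts)
        for _ in range(30):
            prev = s.values.min()
            s, _ = nm_step(s, NMConfig(), f, bounds=unit_box(2))
            assert s.values.min() <= prev + 1e-15

    def test_fifty_steps_solve_a_2d_quadratic(self):
        f = lambda x: float((x[0] - 0.3) ** 2 + (x[1] - 0.7) ** 2)
        verts = initial_simplex(np.array([0.5, 0.5]), 0.1)
        s = Simplex(verts, np.array([f(v) for v in verts]))
        for _ in range(50):
            s, _ = nm_step(s, NMConfig(), f, bounds=unit_box(2))
        best = s.vertices[np.argmin(s.values)]
        assert np.allclose(best, [0.3, 0.7], atol=1e-3)

    def test_non_finite_candidates_are_rejected_not_fatal(self):
        def f(x):
            if x[0] > 0.8:
                return np.nan
            return float((x[0] - 0.5) ** 2)

        s = self._simplex(lambda x: float((x[0] - 0.5) ** 2), [[0.4], [0.7]])
        s2, _ = nm_step(s, NMConfig(), f, bounds=unit_box(1))
        assert np.all(np.isfinite(s2.values))


class TestMinimize:
    def test_constant_function_converges_immediately_at_x0(self):
        res = minimize(lambda x: 1.0, np.full(3, 0.4), unit_box(3),
                       NMConfig(n_restarts=1, max_iter=500))
        assert res.converged
        # flat function: nothing ever beats the initial simplex, which
        # stays within one edge length of x0
        assert np.allclose(res.x_opt, 0.4, atol=0.15)
        assert res.j_opt == 1.0
        assert res.n_iter < 300

    def test_12d_quadratic_matches_reference_optimizer(self):
        # centre strictly inside the default parameter box
        from hrfit.hrf import default_bounds

        b = default_bounds()
        centre = b[:, 0] + 0.37 * (b[:, 1] - b[:, 0])
        scale = 1.0 / (b[:, 1] - b[:, 0]) ** 2

        def f(x):
            return float(np.sum(scale * (x - centre) ** 2))

        x0 = b[:, 0] + 0.6 * (b[:, 1] - b[:, 0])
        res = minimize(f, x0, b, NMConfig(n_restarts=3, max_iter=5000, seed=0))
        ref = scipy_minimize(
            f, x0, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        assert res.j_opt <= ref.fun + 1e-6
        assert np.allclose(res.x_opt, centre, atol=1e-3)

    def test_trace_is_monotone_nonincreasing(self, rng):
        f = lambda x: float(np.sum(np.cos(3 * x) + (x - 0.4) ** 2))
        res = minimize(f, rng.uniform(size=5), unit_box(5),
                       NMConfig(n_restarts=2, max_iter=800, seed=1))
        assert np.all(np.diff(res.trace) <= 0)

    def test_all_iterates_respect_the_box(self):
        seen = []

        def f(x):
            seen.append(x.copy())
            return float(np.sum((x - 0.2) ** 2))

        minimize(f, np.full(3, 0.9), unit_box(3), NMConfig(n_restarts=2, max_iter=300))
        seen = np.array(seen)
        assert np.all(seen >= 0.0) and np.all(seen <= 1.0)

    def test_identical_seeds_give_bit_identical_results(self):
        f = lambda x: float(np.sum(np.sin(5 * x) + x**2))
        cfg = NMConfig(n_restarts=4, max_iter=400, seed=77)
        r1 = minimize(f, np.full(4, 0.5), unit_box(4), cfg)
        r2 = minimize(f, np.full(4, 0.5), unit_box(4), cfg)
        assert np.array_equal(r1.x_opt, r2.x_opt)
        assert r1.j_opt == r2.j_opt
        assert np.array_equal(r1.trace, r2.trace)

    def test_j_opt_equals_cost_at_x_opt(self):
        f = lambda x: float(np.sum((x - 0.3) ** 4))
        res = minimize(f, np.full(3, 0.8), unit_box(3), NMConfig(n_restarts=1))
        assert res.j_opt == pytest.approx(f(res.x_opt), rel=1e-12)

    def test_fixed_parameters_via_zero_width_bounds(self):
        b = np.array([[0.0, 1.0], [0.5, 0.5], [0.0, 1.0]])
        f = lambda x: float(np.sum((x - 0.2) ** 2))
        res = minimize(f, np.array([0.9, 0.5, 0.9]), b, NMConfig(n_restarts=1))
        assert res.x_opt[1] == 0.5
        assert np.allclose(res.x_opt[[0, 2]], 0.2, atol=1e-4)

    def test_everywhere_failing_cost_raises_with_diagnostics(self):
        def f(x):
            raise ValueError("bad model")

        with pytest.raises(OptimizationError, match="non-finite"):
            minimize(f, np.full(2, 0.5), unit_box(2), NMConfig(n_restarts=1))

    def test_invalid_bounds_are_rejected(self):
        with pytest.raises(ValueError, match="lower bound"):
            minimize(lambda x: 0.0, np.zeros(2), np.array([[1.0, 0.0], [0.0, 1.0]]))
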