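"""Kernels, currents, flow integration, energy and registration."""

import numpy as np
import pytest

from ccmorph.curves import Curve, DownsampleScheme
from ccmorph.errors import InvalidKernelError, OptimizationError
from ccmorph.lddmm import (
    KernelSpec,
    MomentumField,
    RegistrationConfig,
    _energy_and_grad,
    _energy_only,
    curve_to_current,
    currents_inner_product,
    energy,
    gaussian_kernel,
    integrate_flow,
    matching_term,
    register,
    register_with_downsampling,
    velocity_field,
)


def small_config(**kw):
    kw.setdefault("kernel", KernelSpec(sigma_V=4.0, sigma_W=3.0))
    return RegistrationConfig(**kw)


class TestGaussianKernel:
    def test_zero_distance(self):
        assert gaussian_kernel((1.0, 2.0), (1.0, 2.0), 5.0) == 1.0

    def test_distance_equal_sigma(self):
        assert gaussian_kernel((0, 0), (3.0, 0), 3.0) == pytest.approx(np.exp(-1))

    def test_monotone_decreasing_in_distance(self):
        vals = [gaussian_kernel((0, 0), (d, 0), 2.0) for d in (0.5, 1, 2, 5, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-10

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidKernelError):
            gaussian_kernel((0, 0), (1, 1), 0.0)


class TestCurrents:
    def test_square_tangents_telescope(self, unit_square_cw):
        centers, tangents = curve_to_current(unit_square_cw)
        assert len(centers) == 4
        np.testing.assert_allclose(tangents.sum(axis=0), [0.0, 0.0], atol=1e-15)

    def test_tangents_telescope_for_any_closed_curve(self, crescent60):
        _, tangents = curve_to_current(crescent60)
        np.testing.assert_allclose(tangents.sum(axis=0), [0.0, 0.0], atol=1e-9)

    def test_self_product_single_segment(self):
        A = (np.array([[5.0, 7.0]]), np.array([[2.0, 0.0]]))
        assert currents_inner_product(A, A, 3.0) == pytest.approx(4.0)

    def test_parallel_segments_sigma_apart(self):
        A = (np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]))
        B = (np.array([[3.0, 0.0]]), np.array([[1.0, 0.0]]))
        assert currents_inner_product(A, B, 3.0) == pytest.approx(np.exp(-1))

    def test_orthogonal_tangents_vanish(self):
        A = (np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]))
        B = (np.array([[9.0, 1.0]]), np.array([[0.0, 1.0]]))
        assert currents_inner_product(A, B, 2.0) == 0.0

    def test_matching_term_zero_on_identical(self, crescent60):
        A = curve_to_current(crescent60)
        assert matching_term(A, A, 6.0) == pytest.approx(0.0, abs=1e-9)

    def test_matching_opposed_tangents(self):
        A = (np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]))
        B = (np.array([[0.0, 0.0]]), np.array([[-1.0, 0.0]]))
        assert matching_term(A, B, 2.0) == pytest.approx(4.0)

    def test_matching_symmetric_and_nonnegative_random(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            nA, nB = rng.integers(1, 5, 2)
            A = (rng.normal(0, 3, (nA, 2)), rng.normal(0, 1, (nA, 2)))
            B = (rng.normal(0, 3, (nB, 2)), rng.normal(0, 1, (nB, 2)))
            e_ab = matching_term(A, B, 2.0)
            e_ba = matching_term(B, A, 2.0)
            assert e_ab >= -1e-9
            assert e_ab == pytest.approx(e_ba, abs=1e-9)


class TestVelocityField:
    def test_zero_momenta_zero_field(self):
        q = np.array([[0.0, 0.0], [1.0, 0.0]])
        v = velocity_field(np.zeros((2, 2)), q, np.array([[0.3, 0.4]]), 2.0)
        np.testing.assert_array_equal(v, [[0.0, 0.0]])

    def test_field_at_control_point(self):
        q = np.array([[2.0, 3.0]])
        a = np.array([[1.0, 0.0]])
        v = velocity_field(a, q, q, 2.0)
        np.testing.assert_allclose(v, [[1.0, 0.0]])

    def test_field_at_sigma_distance(self):
        q = np.array([[0.0, 0.0]])
        a = np.array([[1.0, 0.0]])
        v = velocity_field(a, q, np.array([[2.0, 0.0]]), 2.0)
        np.testing.assert_allclose(v, [[np.exp(-1), 0.0]])


class TestIntegrateFlow:
    def test_zero_momenta_identity_flow(self, crescent60):
        cfg = small_config()
        mom = MomentumField.zeros(cfg.n_timesteps, len(crescent60))
        flow = integrate_flow(crescent60, mom, cfg)
        np.testing.assert_array_equal(flow.trajectories[0], crescent60.points)
        np.testing.assert_array_equal(flow.deformed_template.points, crescent60.points)
        np.testing.assert_array_equal(flow.jacobians, np.ones(len(crescent60)))

    def test_variational_jacobian_matches_finite_difference(self):
        """det(D phi) from the variational equation vs. an FD probe of the map."""
        rng = np.random.default_rng(3)
        tpl = Curve(points=rng.normal(0, 3, (5, 2)))
        cfg = small_config(n_timesteps=10)
        alpha = rng.normal(0, 0.2, (10, 5, 2))
        flow = integrate_flow(tpl, MomentumField(alpha), cfg)

        from ccmorph.lddmm import _kmat

        def probe(x0):
            # advect a passive point through the field of the frozen trajectories
            x = np.atleast_2d(np.asarray(x0, float))
            dt = 1.0 / 10
            for k in range(10):
                K = _kmat(x, flow.trajectories[k], cfg.kernel.sigma_V)
                x = x + dt * (K @ alpha[k])
            return x[0]

        eps = 1e-4
        for i in range(5):
            x0 = tpl.points[i]
            Jfd = np.zeros((2, 2))
            for b in range(2):
                e = np.zeros(2)
                e[b] = eps
                Jfd[:, b] = (probe(x0 + e) - probe(x0 - e)) / (2 * eps)
            assert abs(np.linalg.det(Jfd) - flow.jacobians[i]) < 1e-3

    def test_uniform_scaling_momenta_give_squared_jacobian(self):
        """A radial field expanding by s per unit time gives J ~ s^2."""
        th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        r = 1.0
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        tpl = Curve(points=pts)
        # wide kernel => nearly linear field v(x) ~ c * x near the origin
        sigma = 100.0
        cfg = RegistrationConfig(n_timesteps=50,
                                 kernel=KernelSpec(sigma_V=sigma, sigma_W=3.0))
        K = np.exp(-np.sum((pts[:, None] - pts[None]) ** 2, -1) / sigma**2)
        c = 0.2  # target expansion rate: dx/dt = c x => phi_1 = e^c x
        alpha = np.linalg.solve(K, c * pts)
        mom = MomentumField(np.tile(alpha, (50, 1, 1)))
        flow = integrate_flow(tpl, mom, cfg)
        # alphas are constant (not advected), so the realized map is close to
        # but not exactly e^c; compare against an FD probe instead of e^(2c)
        s = np.linalg.norm(flow.deformed_template.points[0]) / r
        np.testing.assert_allclose(flow.jacobians, s**2, rtol=0.05)


class TestEnergy:
    def test_zero_momenta_identical_curves_zero_energy(self, crescent60):
        cfg = small_config()
        mom = MomentumField.zeros(cfg.n_timesteps, len(crescent60))
        total, reg, match = energy(crescent60, crescent60, mom, cfg)
        assert reg == 0.0
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_zero_momenta_reduces_to_matching(self, circle60, ellipse60):
        cfg = small_config()
        mom = MomentumField.zeros(cfg.n_timesteps, len(circle60))
        total, reg, match = energy(circle60, ellipse60, mom, cfg)
        assert reg == 0.0
        expected = matching_term(curve_to_current(circle60),
                                 curve_to_current(ellipse60), cfg.kernel.sigma_W)
        assert match == pytest.approx(expected)
        assert total == pytest.approx(expected)

    def test_regularization_quadratic_form_single_point_hand_value(self):
        # single control point, T = 1, alpha = (1, 0): reg = gamma * 1 * k(q,q) = gamma
        tpl = np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0]])
        cfg = small_config(n_timesteps=1, gamma=0.7)
        # zero momenta except one unit vector at point 0
        alpha = np.zeros((1, 3, 2))
        alpha[0, 0] = [1.0, 0.0]
        sub = Curve(points=tpl)
        _, reg, _ = energy(sub, sub, MomentumField(alpha), cfg)
        K = np.exp(-np.sum((tpl[:, None] - tpl[None]) ** 2, -1) / cfg.kernel.sigma_V**2)
        expected = 0.7 * float(alpha[0].ravel() @ np.kron(K, np.eye(2)) @ alpha[0].ravel())
        assert reg == pytest.approx(expected)

    def test_analytic_gradient_matches_central_differences(self):
        """Adjoint gradient vs. central FD, 5-point template, T = 3."""
        rng = np.random.default_rng(0)
        tpl = Curve(points=np.array([[0, 0], [4, 1], [6, 4], [3, 6], [0, 4]], float))
        tgt = Curve(points=tpl.points + rng.normal(0, 1, (5, 2)))
        cfg = small_config(n_timesteps=3)
        alpha = rng.normal(0, 0.3, (3, 5, 2))
        tcur = curve_to_current(tgt)
        *_, g = _energy_and_grad(tpl.points, tcur, alpha, cfg, None)
        h = 1e-5
        gfd = np.zeros_like(alpha)
        for idx in np.ndindex(alpha.shape):
            ap, am = alpha.copy(), alpha.copy()
            ap[idx] += h
            am[idx] -= h
            gfd[idx] = (_energy_only(tpl.points, tcur, ap, cfg, None)[0]
                        - _energy_only(tpl.points, tcur, am, cfg, None)[0]) / (2 * h)
        rel = np.abs(g - gfd).max() / np.abs(gfd).max()
        assert rel < 1e-4


class TestRegister:
    def test_identity_registration(self, crescent60):
        res = register(crescent60, crescent60)
        assert res.converged
        assert res.energy_trace[-1][2] <= 1e-8  # matching
        np.testing.assert_allclose(res.flow.jacobians, 1.0, atol=1e-6)

    def test_outward_circle_growth_jacobians_above_one(self):
        th = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        c20 = Curve(points=np.column_stack([64 + 20 * np.cos(th), 64 + 20 * np.sin(th)]))
        c24 = Curve(points=np.column_stack([64 + 24 * np.cos(th), 64 + 24 * np.sin(th)]))
        res = register(c20, c24)
        assert res.energy_trace[-1][2] < 0.02 * res.energy_trace[0][2]
        assert np.all(res.flow.jacobians > 1.0)  # outward deformation

    def test_energy_trace_monotone_nonincreasing(self, circle60, ellipse60):
        res = register(circle60, ellipse60, RegistrationConfig(max_iters=50))
        totals = [t for t, _, _ in res.energy_trace]
        assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_line_search_failure_at_first_iteration_raises(self, circle60, ellipse60):
        cfg = RegistrationConfig(ls_init_step=1e12, ls_max_evals=1)
        with pytest.raises(OptimizationError):
            register(circle60, ellipse60, cfg)

    def test_diffeomorphism_positive_jacobians(self, circle60, ellipse60):
        res = register(circle60, ellipse60, RegistrationConfig(max_iters=150))
        assert np.all(res.flow.jacobians > 0)


class TestDownsampling:
    def test_factor_one_matches_plain_register(self, circle60, ellipse60):
        cfg = RegistrationConfig(max_iters=20)
        a = register(circle60, ellipse60, cfg)
        b = register_with_downsampling(circle60, ellipse60, DownsampleScheme(1), cfg)
        np.testing.assert_array_equal(a.momenta.alpha, b.momenta.alpha)
        np.testing.assert_array_equal(a.flow.jacobians, b.flow.jacobians)

    def test_template_only_counter_arithmetic(self, crescent200):
        """Per energy evaluation, factor-2 template-only down-sampling cuts
        deformation-kernel evaluations exactly 4x and matching-kernel
        evaluations at least 2x."""
        tgt = Curve(points=crescent200.points + [1.5, -0.5])
        cfg = RegistrationConfig(max_iters=5)
        full = register_with_downsampling(crescent200, tgt, DownsampleScheme(1), cfg)
        down = register_with_downsampling(
            crescent200, tgt, DownsampleScheme(2, "template_only"), cfg)

        def per_eval(res):
            c = res.op_counters
            evals = c.n_energy_evals + c.n_grad_evals
            return (c.kernel_evals_deform / evals,
                    (c.kernel_evals_match - len(tgt.points) ** 2) / evals)

        d_full, m_full = per_eval(full)
        d_down, m_down = per_eval(down)
        assert d_full / d_down == pytest.approx(4.0)
        assert m_full / m_down >= 2.0

    def test_total_kernel_evals_below_one_third(self, crescent200):
        """Factor-2 template-only: total kernel evaluations fall below 1/3
        of baseline per evaluation (n_template = n_target = 200, T = 10)."""
        tgt = Curve(points=crescent200.points + [1.5, -0.5])
        cfg = RegistrationConfig(max_iters=5)
        full = register_with_downsampling(crescent200, tgt, DownsampleScheme(1), cfg)
        down = register_with_downsampling(
            crescent200, tgt, DownsampleScheme(2, "template_only"), cfg)

        def totals_per_eval(res):
            c = res.op_counters
            evals = c.n_energy_evals + c.n_grad_evals
            return (c.kernel_evals_deform + c.kernel_evals_match
                    - len(tgt.points) ** 2) / evals

        assert totals_per_eval(down) <= totals_per_eval(full) / 3.0

    def test_markers_at_downsampled_points(self, crescent60):
        tgt = Curve(points=crescent60.points + [1.0, 0.0])
        res = register_with_downsampling(
            crescent60, tgt, DownsampleScheme(2, "template_only"),
            RegistrationConfig(max_iters=10))
        assert len(res.flow.jacobians) == 30

    def test_too_aggressive_factor_raises(self, unit_square_cw):
        from ccmorph.errors import TooFewPointsError

        with pytest.raises(TooFewPointsError):
            register_with_downsampling(unit_square_cw, unit_square_cw,
                                       DownsampleScheme(4), small_config())
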