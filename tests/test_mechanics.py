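import numpy as np
import pytest

from elastopinn.fields import (
    DisplacementField,
    ElasticityField,
    ResidualForceMap,
    StrainField,
    StressField,
)
from elastopinn.grid import GridSpec
from elastopinn.mechanics import (
    DEFAULT_KERNELS,
    compute_strain,
    constitutive_stress,
    constitutive_vjp,
    conv3_adjoint,
    conv3_valid,
    diff_x,
    diff_x_adjoint,
    diff_y,
    diff_y_adjoint,
    movsum3,
    movsum3_adjoint,
    residual_forces,
    residual_forces_adjoint,
    strain_adjoint,
)


class TestStrain:
    def test_linear_displacement_gives_exact_strain(self):
        grid = GridSpec(q=12, h=0.7)
        x, y = grid.coordinates()
        disp = DisplacementField(u_x=0.01 * x, u_y=np.zeros_like(x))
        strain = compute_strain(disp, grid)
        np.testing.assert_allclose(strain.eps_xx, 0.01, atol=1e-14)
        np.testing.assert_allclose(strain.eps_yy, 0.0, atol=1e-14)
        np.testing.assert_allclose(strain.gamma_xy, 0.0, atol=1e-14)

    def test_rigid_translation_is_strain_free(self):
        grid = GridSpec(q=9, h=0.3)
        disp = DisplacementField(
            u_x=np.full((9, 9), 1.7), u_y=np.full((9, 9), -2.3)
        )
        strain = compute_strain(disp, grid)
        for comp in (strain.eps_xx, strain.eps_yy, strain.gamma_xy):
            np.testing.assert_allclose(comp, 0.0, atol=1e-13)

    @pytest.mark.parametrize("h", [0.04, 0.02, 0.01])
    def test_second_order_accuracy_against_analytic_derivative(self, h):
        q = 41
        grid = GridSpec(q=q, h=h)
        x, _ = grid.coordinates()
        disp = DisplacementField(u_x=np.sin(x), u_y=np.zeros_like(x))
        strain = compute_strain(disp, grid)
        err = np.abs(strain.eps_xx - np.cos(x)).max()
        # central interior + one-sided edges are both O(h^2)
        assert err < 1.5 * h**2

    def test_shear_mixes_both_components(self):
        grid = GridSpec(q=10, h=0.5)
        x, y = grid.coordinates()
        disp = DisplacementField(u_x=0.02 * y, u_y=0.03 * x)
        strain = compute_strain(disp, grid)
        np.testing.assert_allclose(strain.gamma_xy, 0.05, atol=1e-13)


class TestConstitutive:
    def test_zero_poisson_is_identity_like(self):
        strain = StrainField(
            eps_xx=np.full((3, 3), 0.01),
            eps_yy=np.zeros((3, 3)),
            gamma_xy=np.zeros((3, 3)),
        )
        field = ElasticityField(E=np.ones((3, 3)), nu=np.full((3, 3), 1e-12))
        stress = constitutive_stress(strain, field)
        np.testing.assert_allclose(stress.sigma_xx, 0.01, rtol=1e-9)
        np.testing.assert_allclose(stress.sigma_yy, 0.0, atol=1e-12)

    def test_pure_shear_hand_value(self):
        # tau = E / (2 (1 + nu)) * gamma = 1 / 2.5 * 0.02 = 0.008 MPa
        strain = StrainField(
            eps_xx=np.zeros((2, 2)),
            eps_yy=np.zeros((2, 2)),
            gamma_xy=np.full((2, 2), 0.02),
        )
        field = ElasticityField(E=np.ones((2, 2)), nu=np.full((2, 2), 0.25))
        stress = constitutive_stress(strain, field)
        np.testing.assert_allclose(stress.tau_xy, 0.008, rtol=1e-12)

    def test_incompressible_hand_value(self):
        # sigma_xx = (1/0.75) * (0.01 + 0.5 * (-0.005)) = 0.01 MPa
        strain = StrainField(
            eps_xx=np.full((2, 2), 0.01),
            eps_yy=np.full((2, 2), -0.005),
            gamma_xy=np.zeros((2, 2)),
        )
        field = ElasticityField(E=np.ones((2, 2)), nu=np.full((2, 2), 0.5))
        stress = constitutive_stress(strain, field)
        np.testing.assert_allclose(stress.sigma_xx, 0.01, rtol=1e-12)

    def test_locality(self, rng):
        # stress at a point depends on E only at that point
        grid = GridSpec(q=6, h=1.0)
        strain = StrainField(*[rng.normal(size=(6, 6)) for _ in range(3)])
        E = np.full((6, 6), 0.5)
        s0 = constitutive_stress(strain, ElasticityField(E=E, nu=np.full((6, 6), 0.3)))
        E2 = E.copy()
        E2[2, 3] = 0.9
        s1 = constitutive_stress(strain, ElasticityField(E=E2, nu=np.full((6, 6), 0.3)))
        changed = s1.sigma_xx != s0.sigma_xx
        assert changed[2, 3]
        assert changed.sum() == 1


class TestKernels:
    def test_all_kernels_sum_to_zero(self):
        k = DEFAULT_KERNELS
        for w in (k.x_w_xx, k.x_w_yy, k.x_w_xy, k.y_w_xx, k.y_w_yy, k.y_w_xy):
            assert w.sum() == 0.0

    def test_balance_sets_are_transposes_with_roles_swapped(self):
        k = DEFAULT_KERNELS
        np.testing.assert_array_equal(k.y_w_yy, k.x_w_xx.T)
        np.testing.assert_array_equal(k.y_w_xy, k.x_w_xy.T)


class TestResidualForces:
    def test_uniform_stress_is_balanced(self):
        grid = GridSpec(q=10, h=0.4, t=2.0)
        stress = StressField(
            sigma_xx=np.full((10, 10), 5.0),
            sigma_yy=np.full((10, 10), 2.0),
            tau_xy=np.full((10, 10), 1.0),
        )
        res = residual_forces(stress, grid)
        np.testing.assert_allclose(res.e_x, 0.0, atol=1e-13)
        np.testing.assert_allclose(res.e_y, 0.0, atol=1e-13)
        assert res.e_x.shape == (8, 8)  # p = q - 2

    def test_linear_sigma_xx_gives_closed_form_residual(self):
        # sigma_xx = k x: each row of the x-balance kernel contributes
        # 2 k h, three rows give 6 k h, times h t -> 6 k h^2 t
        grid = GridSpec(q=9, h=0.31, t=1.7)
        k = 0.83
        x, _ = grid.coordinates()
        stress = StressField(sigma_xx=k * x, sigma_yy=0 * x, tau_xy=0 * x)
        res = residual_forces(stress, grid)
        np.testing.assert_allclose(res.e_x, 6 * k * grid.h**2 * grid.t, rtol=1e-12)
        np.testing.assert_allclose(res.e_y, 0.0, atol=1e-13)

    def test_matches_brute_force_double_loop(self, rng):
        # direct evaluation of the subregion sum, exact equality
        grid = GridSpec(q=8, h=0.5, t=1.3)
        stress = StressField(*[rng.normal(size=(8, 8)) for _ in range(3)])
        res = residual_forces(stress, grid)
        k = DEFAULT_KERNELS
        ht = grid.h * grid.t
        for i in range(6):
            for j in range(6):
                ex = ey = 0.0
                for a in range(3):
                    for b in range(3):
                        ex += (
                            k.x_w_xx[a, b] * stress.sigma_xx[i + a, j + b]
                            + k.x_w_yy[a, b] * stress.sigma_yy[i + a, j + b]
                            + k.x_w_xy[a, b] * stress.tau_xy[i + a, j + b]
                        )
                        ey += (
                            k.y_w_xx[a, b] * stress.sigma_xx[i + a, j + b]
                            + k.y_w_yy[a, b] * stress.sigma_yy[i + a, j + b]
                            + k.y_w_xy[a, b] * stress.tau_xy[i + a, j + b]
                        )
                assert res.e_x[i, j] == pytest.approx(ex * ht, rel=1e-13)
                assert res.e_y[i, j] == pytest.approx(ey * ht, rel=1e-13)

    def test_linearity_in_stress(self, rng):
        grid = GridSpec(q=7, h=0.8)
        s1 = StressField(*[rng.normal(size=(7, 7)) for _ in range(3)])
        s2 = StressField(*[rng.normal(size=(7, 7)) for _ in range(3)])
        both = StressField(
            sigma_xx=2 * s1.sigma_xx + 3 * s2.sigma_xx,
            sigma_yy=2 * s1.sigma_yy + 3 * s2.sigma_yy,
            tau_xy=2 * s1.tau_xy + 3 * s2.tau_xy,
        )
        r1, r2, rb = (residual_forces(s, grid) for s in (s1, s2, both))
        np.testing.assert_allclose(rb.e_x, 2 * r1.e_x + 3 * r2.e_x, rtol=1e-12)
        np.testing.assert_allclose(rb.e_y, 2 * r1.e_y + 3 * r2.e_y, rtol=1e-12)

    def test_analytic_equilibrium_field_residual_vanishes_as_h_squared(self):
        # quartic divergence-free stress: sigma_xx = x^3 y,
        # sigma_yy = x y^3, tau = -1.5 x^2 y^2 satisfies both balances
        # analytically but not to machine precision on the stencil
        errs = []
        for q in (17, 33):
            grid = GridSpec(q=q, h=2.0 / (q - 1))
            x, y = grid.coordinates()
            stress = StressField(
                sigma_xx=x**3 * y,
                sigma_yy=x * y**3,
                tau_xy=-1.5 * x**2 * y**2,
            )
            res = residual_forces(stress, grid)
            # normalize out the h^2 t scale of the residual itself
            errs.append(
                max(np.abs(res.e_x).max(), np.abs(res.e_y).max())
                / (grid.h**2 * grid.t)
            )
        # halving h must shrink the consistency error ~4x (second order)
        assert errs[1] < errs[0] / 3.0


class TestAdjoints:
    """The hand-written vector-Jacobian products against the inner-product
    identity <A x, y> = <x, A^T y> and numerical differentiation."""

    def test_difference_operators(self, rng):
        h = 0.37
        f = rng.normal(size=(9, 9))
        g = rng.normal(size=(9, 9))
        for D, DT in ((diff_x, diff_x_adjoint), (diff_y, diff_y_adjoint)):
            lhs = float((D(f, h) * g).sum())
            rhs = float((f * DT(g, h)).sum())
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_convolution_and_moving_sum(self, rng):
        f = rng.normal(size=(8, 8))
        bar = rng.normal(size=(6, 6))
        for kern in (DEFAULT_KERNELS.x_w_xx, DEFAULT_KERNELS.x_w_xy):
            lhs = float((conv3_valid(f, kern) * bar).sum())
            rhs = float((f * conv3_adjoint(bar, kern, 8)).sum())
            assert lhs == pytest.approx(rhs, rel=1e-12)
        assert float((movsum3(f) * bar).sum()) == pytest.approx(
            float((f * movsum3_adjoint(bar, 8)).sum()), rel=1e-12
        )

    def test_strain_and_residual_adjoints(self, rng):
        grid = GridSpec(q=8, h=0.42, t=1.5)
        disp = DisplacementField(*[rng.normal(size=(8, 8)) for _ in range(2)])
        bar_eps = StrainField(*[rng.normal(size=(8, 8)) for _ in range(3)])
        strain = compute_strain(disp, grid)
        lhs = float(
            (strain.eps_xx * bar_eps.eps_xx).sum()
            + (strain.eps_yy * bar_eps.eps_yy).sum()
            + (strain.gamma_xy * bar_eps.gamma_xy).sum()
        )
        back = strain_adjoint(bar_eps, grid)
        rhs = float((disp.u_x * back.u_x).sum() + (disp.u_y * back.u_y).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)

        stress = StressField(*[rng.normal(size=(8, 8)) for _ in range(3)])
        bar_e = ResidualForceMap(*[rng.normal(size=(6, 6)) for _ in range(2)])
        res = residual_forces(stress, grid)
        lhs = float((res.e_x * bar_e.e_x).sum() + (res.e_y * bar_e.e_y).sum())
        back_s = residual_forces_adjoint(bar_e, grid)
        rhs = float(
            (stress.sigma_xx * back_s.sigma_xx).sum()
            + (stress.sigma_yy * back_s.sigma_yy).sum()
            + (stress.tau_xy * back_s.tau_xy).sum()
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_constitutive_vjp_matches_numerical_derivatives(self, rng):
        strain = StrainField(*[0.01 * rng.normal(size=(4, 4)) for _ in range(3)])
        E = rng.uniform(0.2, 1.0, (4, 4))
        nu = rng.uniform(0.1, 0.45, (4, 4))
        field = ElasticityField(E=E, nu=nu)
        bar = StressField(*[rng.normal(size=(4, 4)) for _ in range(3)])

        def scalar(E_, nu_, eps_):
            s = constitutive_stress(
                StrainField(*eps_), ElasticityField(E=E_, nu=nu_)
            )
            return float(
                (s.sigma_xx * bar.sigma_xx).sum()
                + (s.sigma_yy * bar.sigma_yy).sum()
                + (s.tau_xy * bar.tau_xy).sum()
            )

        d_eps, dE, dnu = constitutive_vjp(strain, field, bar)
        eps0 = [strain.eps_xx, strain.eps_yy, strain.gamma_xy]
        h = 1e-6
        for arr, grad in ((E, dE), (nu, dnu)):
            idx = (1, 2)
            ap = arr.copy()
            ap[idx] += h
            am = arr.copy()
            am[idx] -= h
            if arr is E:
                num = (scalar(ap, nu, eps0) - scalar(am, nu, eps0)) / (2 * h)
            else:
                num = (scalar(E, ap, eps0) - scalar(E, am, eps0)) / (2 * h)
            assert grad[idx] == pytest.approx(num, rel=1e-5)
        for k, grad in enumerate([d_eps.eps_xx, d_eps.eps_yy, d_eps.gamma_xy]):
            idx = (2, 1)
            ep = [a.copy() for a in eps0]
            em = [a.copy() for a in eps0]
            ep[k][idx] += h
            em[k][idx] -= h
            num = (scalar(E, nu, ep) - scalar(E, nu, em)) / (2 * h)
            assert grad[idx] == pytest.approx(num, rel=1e-5)
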