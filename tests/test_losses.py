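import numpy as np
import pytest

from elastopinn.fields import (
    DisplacementField,
    ElasticityField,
    ResidualForceMap,
    StressField,
)
from elastopinn.grid import GridSpec
from elastopinn.losses import (
    BoundaryData,
    ConstraintTargets,
    LossWeights,
    loss_boundary_displacement,
    loss_boundary_traction,
    loss_mean_displacement,
    loss_mean_elasticity,
    loss_residual,
    total_loss,
)
from elastopinn.mechanics import constitutive_stress, residual_forces
from elastopinn.fields import StrainField


class TestResidualLoss:
    def test_zero_residual_gives_zero(self):
        res = ResidualForceMap(e_x=np.zeros((3, 3)), e_y=np.zeros((3, 3)))
        assert loss_residual(res, np.ones((5, 5))) == 0.0

    def test_hand_value_single_subregion_block(self):
        # uniform E = 1 -> moving sum = 9; |e| = 9 everywhere in one
        # balance direction -> contribution exactly 1.0
        E = np.ones((5, 5))
        res = ResidualForceMap(e_x=np.full((3, 3), 9.0), e_y=np.zeros((3, 3)))
        assert loss_residual(res, E) == pytest.approx(1.0)
        both = ResidualForceMap(e_x=np.full((3, 3), 9.0), e_y=np.full((3, 3), -9.0))
        assert loss_residual(both, E) == pytest.approx(2.0)

    def test_invariant_under_joint_scaling(self, rng):
        E = rng.uniform(0.2, 1.0, (6, 6))
        res = ResidualForceMap(
            e_x=rng.normal(size=(4, 4)), e_y=rng.normal(size=(4, 4))
        )
        base = loss_residual(res, E)
        c = 3.7
        scaled = ResidualForceMap(e_x=c * res.e_x, e_y=c * res.e_y)
        assert loss_residual(scaled, c * E) == pytest.approx(base, rel=1e-12)

    def test_nonpositive_modulus_window_rejected(self):
        E = np.ones((5, 5))
        E[2, 2] = -20.0
        res = ResidualForceMap(e_x=np.ones((3, 3)), e_y=np.ones((3, 3)))
        with pytest.raises(ValueError):
            loss_residual(res, E)


class TestBoundaryLosses:
    def test_exact_prediction_is_zero(self):
        pred = DisplacementField(u_x=np.full((4, 4), 0.2), u_y=np.zeros((4, 4)))
        bdata = BoundaryData.from_dirichlet([(0, 0, 0.2), (3, 0, 0.2)])
        assert loss_boundary_displacement(pred, bdata) == 0.0

    def test_mae_of_two_points(self):
        pred = DisplacementField(u_x=np.zeros((4, 4)), u_y=np.zeros((4, 4)))
        bdata = BoundaryData.from_dirichlet([(1, 0, 0.1), (2, 0, -0.3)])
        assert loss_boundary_displacement(pred, bdata) == pytest.approx(0.2)

    def test_random_case_equals_brute_force(self, rng):
        q = 6
        pred = DisplacementField(
            u_x=rng.normal(size=(q, q)), u_y=rng.normal(size=(q, q))
        )
        bc = [
            (int(rng.integers(0, q * q)), int(rng.integers(0, 2)), float(rng.normal()))
            for _ in range(9)
        ]
        bdata = BoundaryData.from_dirichlet(bc)
        flat = [pred.u_x.ravel(), pred.u_y.ravel()]
        brute = np.mean([abs(flat[c][n] - v) for n, c, v in bc])
        assert loss_boundary_displacement(pred, bdata) == pytest.approx(brute)

    def test_traction_free_edge_with_zero_stress(self):
        q = 5
        stress = StressField(*(np.zeros((q, q)) for _ in range(3)))
        bdata = BoundaryData(
            trac_index=np.array([4, 9, 14]),
            trac_normal=np.tile([1.0, 0.0], (3, 1)),
            trac_value=np.zeros((3, 2)),
        )
        assert loss_boundary_traction(stress, bdata) == 0.0

    def test_uniform_stress_matching_prescribed_traction(self):
        q = 4
        stress = StressField(
            sigma_xx=np.full((q, q), 0.5),
            sigma_yy=np.zeros((q, q)),
            tau_xy=np.zeros((q, q)),
        )
        right_edge = np.array([j * q + (q - 1) for j in range(q)])
        bdata = BoundaryData(
            trac_index=right_edge,
            trac_normal=np.tile([1.0, 0.0], (q, 1)),
            trac_value=np.tile([0.5, 0.0], (q, 1)),
        )
        assert loss_boundary_traction(stress, bdata) == pytest.approx(0.0)

    def test_traction_equals_hand_computed_sigma_dot_n(self, rng):
        q = 5
        stress = StressField(*[rng.normal(size=(q, q)) for _ in range(3)])
        idx = np.array([3, 7, 21])
        normals = rng.normal(size=(3, 2))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        values = rng.normal(size=(3, 2))
        bdata = BoundaryData(trac_index=idx, trac_normal=normals, trac_value=values)
        acc = []
        for k, n in enumerate(idx):
            sxx = stress.sigma_xx.ravel()[n]
            syy = stress.sigma_yy.ravel()[n]
            txy = stress.tau_xy.ravel()[n]
            tx = sxx * normals[k, 0] + txy * normals[k, 1]
            ty = txy * normals[k, 0] + syy * normals[k, 1]
            acc += [abs(tx - values[k, 0]), abs(ty - values[k, 1])]
        assert loss_boundary_traction(stress, bdata) == pytest.approx(np.mean(acc))


class TestMeanConstraints:
    def test_mean_elasticity_hand_value(self):
        # 2x2 grid summing to 4.4 against target sum 4.0 -> 0.1
        E = np.array([[1.1, 1.1], [1.1, 1.1]])
        targets = ConstraintTargets(mean_E_target=1.0)
        assert loss_mean_elasticity(E, targets) == pytest.approx(0.1)

    def test_zero_at_target(self):
        E = np.full((3, 3), 0.7)
        assert loss_mean_elasticity(E, ConstraintTargets(mean_E_target=0.7)) == 0.0

    def test_deviation_scales_linearly(self):
        targets = ConstraintTargets(mean_E_target=1e-9)
        a = loss_mean_elasticity(np.full((4, 4), 0.5), targets)
        b = loss_mean_elasticity(np.full((4, 4), 1.0), targets)
        assert b == pytest.approx(2 * a, rel=1e-6)

    def test_mean_displacement(self):
        targets = ConstraintTargets()
        u = np.array([[1.0, -1.0], [2.0, -2.0]])
        assert loss_mean_displacement(u, targets) == 0.0
        assert loss_mean_displacement(u + 0.3, targets) == pytest.approx(0.3)

    def test_nonzero_displacement_target(self):
        targets = ConstraintTargets(mean_disp_target=0.5)
        u = np.full((3, 3), 0.5)
        assert loss_mean_displacement(u, targets) == 0.0


class TestTotalLoss:
    def test_forward_all_zero(self):
        w = LossWeights()
        assert total_loss("forward", {"L_r": 0.0, "L_u": 0.0, "L_f": 0.0}, w) == 0.0

    def test_inverse_hand_arithmetic(self):
        w = LossWeights(w_r=1.0, w_e=10.0)
        assert total_loss("inverse", {"L_r": 0.2, "L_e": 0.05}, w) == pytest.approx(0.7)

    def test_mixed_reduces_to_inverse_when_wd_zero(self):
        comp = {"L_r": 0.3, "L_e": 0.1, "L_d": 0.9}
        w0 = LossWeights(w_r=1.0, w_e=2.0, w_d=0.0)
        assert total_loss("mixed", comp, w0) == total_loss(
            "inverse", comp, w0
        )

    def test_missing_component_rejected(self):
        with pytest.raises(ValueError):
            total_loss("inverse", {"L_r": 0.1}, LossWeights())

    def test_monotone_in_components(self, rng):
        w = LossWeights(w_r=1.0, w_e=3.0, w_d=0.5)
        base = {"L_r": 0.2, "L_e": 0.1, "L_d": 0.05}
        t0 = total_loss("mixed", base, w)
        for term in base:
            bumped = dict(base)
            bumped[term] += 0.01
            assert total_loss("mixed", bumped, w) > t0

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(w_r=0.0)
        with pytest.raises(ValueError):
            LossWeights(w_e=-1.0)


class TestIdentifiability:
    def test_scale_ambiguity_resolved_by_mean_constraint(self, rng):
        # 5x5 toy: L_r is invariant along c * E_true (stress scales with
        # E for a fixed measured strain); adding the mean-elasticity
        # term makes c = 1 the unique minimizer on a grid of scales
        grid = GridSpec(q=5, h=0.5)
        E_true = rng.uniform(0.2, 1.0, (5, 5))
        nu = np.full((5, 5), 0.3)
        strain = StrainField(*[0.01 * rng.normal(size=(5, 5)) for _ in range(3)])
        targets = ConstraintTargets(mean_E_target=float(E_true.mean()))

        def L_r(c):
            f = ElasticityField(E=c * E_true, nu=nu)
            stress = constitutive_stress(strain, f)
            return loss_residual(residual_forces(stress, grid), c * E_true)

        scales = np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0])
        L_r_vals = np.array([L_r(c) for c in scales])
        np.testing.assert_allclose(L_r_vals, L_r_vals[0], rtol=1e-12)

        totals = [
            total_loss(
                "inverse",
                {"L_r": L_r(c), "L_e": loss_mean_elasticity(c * E_true, targets)},
                LossWeights(w_r=1.0, w_e=1.0),
            )
            for c in scales
        ]
        assert int(np.argmin(totals)) == int(np.where(scales == 1.0)[0][0])
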