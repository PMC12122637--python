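"""Steps 1-4 for the homogeneous linear model: auxiliary points, the set 𝒜,
partner families, kernel membership, witness solutions, classification."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from auxident import (InitialCondition, ModelSpec, ParameterPoint, Verdict,
                      SpaceTimeGrid, auxiliary_point, classify,
                      construct_nonidentifiable_solution, in_set_A,
                      indistinguishable_partners, is_in_kernel, step4_filter,
                      solve_linear_analytic, solution_distance)
from auxident.linear import AuxiliaryPoint, kernel_coefficients

PI2 = math.pi**2


class TestAuxiliaryPoint:
    def test_swap_enforces_nonnegative_diffusivity(self):
        A = auxiliary_point(ParameterPoint(0.05, 0, 1),
                            ParameterPoint(0.05 + 1 / PI2, 0, 2))
        assert A.as_tuple() == pytest.approx((1 / PI2, 0.0, 1.0))
        assert A.swapped

    def test_componentwise_difference(self):
        A = auxiliary_point(ParameterPoint(2, 1, 3), ParameterPoint(1, 1, 3))
        assert A.as_tuple() == (1.0, 0.0, 0.0)
        assert not A.swapped

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            auxiliary_point(ParameterPoint(1, 0, 0), ParameterPoint(1, 0, 0))


class TestSetAMembership:
    def test_dirichlet_first_mode(self, dirichlet_spec):
        m = in_set_A(AuxiliaryPoint(1 / PI2, 0.0, 1.0), dirichlet_spec)
        assert m.in_A and m.index == 1

    def test_neumann_constant_plane(self):
        m = in_set_A(AuxiliaryPoint(1.0, 0.0, 0.0), ModelSpec.neumann())
        assert m.in_A and m.tag == "constant"

    def test_negative_c_never_matches_dirichlet(self, dirichlet_spec):
        assert not in_set_A(AuxiliaryPoint(1.0, 0.0, -3.0), dirichlet_spec).in_A


class TestPartnerFamilies:
    def test_fig_pair_partner(self, dirichlet_spec):
        fam = indistinguishable_partners(ParameterPoint(0.05, 0, 1),
                                         dirichlet_spec, 1)
        A2 = fam.partner_from_c(2.0)
        assert A2.d == pytest.approx(0.05 + 1 / PI2, rel=1e-12)
        assert A2.c == 2.0

    def test_drift_family_preserves_ratio(self, dirichlet_spec):
        fam = indistinguishable_partners(ParameterPoint(1, 2, 3),
                                         dirichlet_spec, 1, drift=True)
        A2 = fam.partner_from_d(2.0)
        assert A2.b == pytest.approx(4.0)
        # the pair really is indistinguishable: auxiliary c matches λ1(d, b)
        m = in_set_A(auxiliary_point(ParameterPoint(1, 2, 3), A2), dirichlet_spec)
        assert m.in_A and m.index == 1

    def test_driftless_base_has_no_drifted_partners(self, dirichlet_spec):
        with pytest.raises(ValueError, match="sign of b1 and b2"):
            indistinguishable_partners(ParameterPoint(1, 0, 0),
                                       dirichlet_spec, 1, drift=True)

    def test_neumann_constant_mode_family(self):
        fam = indistinguishable_partners(ParameterPoint(1, 0, 0),
                                         ModelSpec.neumann(), 0)
        for A2 in fam.sample(4, seed=3):
            assert A2.c == 0.0
            m = in_set_A(auxiliary_point(ParameterPoint(1, 0, 0), A2),
                         ModelSpec.neumann())
            assert m.in_A

    def test_mu_invariant_constant_along_family(self, dirichlet_spec):
        """c - dπ² is conserved along the sampled n = 1 Dirichlet family."""
        A1 = ParameterPoint(0.05, 0, 1)
        fam = indistinguishable_partners(A1, dirichlet_spec, 1)
        mu_star = A1.c - A1.d * PI2
        for A2 in fam.sample(5):
            assert A2.c - A2.d * PI2 == pytest.approx(mu_star, abs=1e-12)

    def test_step4_keeps_only_sign_definite_modes(self, dirichlet_spec):
        A1 = ParameterPoint(0.05, 0, 1)
        fams = [indistinguishable_partners(A1, dirichlet_spec, n)
                for n in range(1, 6)]
        kept = step4_filter(fams)
        assert [f.index for f in kept] == [1]
        neu = [indistinguishable_partners(ParameterPoint(1, 0, 0),
                                          ModelSpec.neumann(), n)
               for n in (0, 1, 2)]
        assert [f.index for f in step4_filter(neu)] == [0]
        assert step4_filter([]) == []


class TestKernelMembership:
    def test_dominant_mode_in_kernel(self, dirichlet_spec):
        A = AuxiliaryPoint(1 / PI2, 0.0, 1.0)
        u0 = InitialCondition.from_callable(lambda x: np.sin(math.pi * x))
        assert is_in_kernel(u0, A, dirichlet_spec)

    def test_perturbed_mode_not_in_kernel_against_quadrature_oracle(
            self, dirichlet_spec):
        A = AuxiliaryPoint(1 / PI2, 0.0, 1.0)
        u0 = InitialCondition.from_callable(
            lambda x: np.sin(math.pi * x) + 0.1 * np.sin(2 * math.pi * x))
        assert not is_in_kernel(u0, A, dirichlet_spec)
        # oracle: explicit L² projection by adaptive quadrature
        proj, _ = quad(lambda x: (math.sin(math.pi * x)
                                  + 0.1 * math.sin(2 * math.pi * x))
                       * math.sin(math.pi * x), 0, 1)
        resid_sq = quad(lambda x: ((math.sin(math.pi * x)
                                    + 0.1 * math.sin(2 * math.pi * x))
                                   - 2 * proj * math.sin(math.pi * x))**2,
                        0, 1)[0]
        norm_sq = quad(lambda x: (math.sin(math.pi * x)
                                  + 0.1 * math.sin(2 * math.pi * x))**2, 0, 1)[0]
        assert math.sqrt(resid_sq / norm_sq) > 0.05

    def test_constant_in_neumann_kernel(self):
        A = AuxiliaryPoint(1.0, 0.0, 0.0)
        u0 = InitialCondition.from_callable(lambda x: np.ones_like(x))
        assert is_in_kernel(u0, A, ModelSpec.neumann())

    def test_trivial_u0_rejected(self, dirichlet_spec):
        u0 = InitialCondition.from_callable(lambda x: 0.0 * x)
        with pytest.raises(ValueError, match="identically zero"):
            is_in_kernel(u0, AuxiliaryPoint(1 / PI2, 0, 1.0), dirichlet_spec)


class TestWitnessConstruction:
    def test_fig_pair_solution(self, dirichlet_spec, fig_pair):
        A1, A2 = fig_pair
        w = construct_nonidentifiable_solution(A1, A2, 1, 1.0, dirichlet_spec)
        assert w.exponent == pytest.approx(1 - 0.05 * PI2, rel=1e-12)
        gx, gt = np.linspace(0, 1, 101), np.linspace(0, 2, 21)
        assert w.residual(A1, gx, gt) <= 1e-10
        assert w.residual(A2, gx, gt) <= 1e-10

    def test_periodic_mixed_mode(self):
        spec = ModelSpec.periodic()
        P1 = ParameterPoint(0.05, 0, 1.0)
        P2 = indistinguishable_partners(P1, spec, 1).partner_from_d(0.1)
        w = construct_nonidentifiable_solution(P1, P2, 1, 1.0, spec,
                                               gammas=[1.0, 1.0])
        gx, gt = np.linspace(0, 2 * math.pi, 64), np.linspace(0, 2, 11)
        assert w.residual(P1, gx, gt) <= 1e-10
        assert w.residual(P2, gx, gt) <= 1e-10
        assert w.exponent == pytest.approx(1 - 0.05)

    def test_not_in_A_raises(self, dirichlet_spec):
        with pytest.raises(ValueError, match="not in the set"):
            construct_nonidentifiable_solution(ParameterPoint(1, 0, 1),
                                               ParameterPoint(2, 0, 1),
                                               1, 1.0, dirichlet_spec)

    def test_drift_ratio_violation_raises(self, dirichlet_spec):
        A1 = ParameterPoint(1, 2, 3)
        lam = 9.0 / (4 * 0.5) + 0.5 * PI2  # λ1(0.5, 3) would need ratio 2
        A2 = ParameterPoint(0.5, -1.0, 3 - lam)
        # engineer c difference matching λ1(d, b) while breaking the ratio
        with pytest.raises(ValueError, match="drift (ratio|constraint)"):
            construct_nonidentifiable_solution(A1, A2, 1, 1.0, dirichlet_spec)

    def test_degenerate_robin_family_witness(self):
        spec = ModelSpec.robin(1.0)
        A1 = ParameterPoint(0.3, 2.0, 2.0)
        fam = indistinguishable_partners(A1, spec, degenerate_robin=True)
        A2 = fam.partner_from_b(3.0)
        assert A2.d == A1.d and A2.c == pytest.approx(3.0)
        w = construct_nonidentifiable_solution(A1, A2, None, 1.0, spec)
        gx, gt = np.linspace(0, 1, 101), np.linspace(0, 1, 11)
        assert w.residual(A1, gx, gt) <= 1e-10
        assert w.residual(A2, gx, gt) <= 1e-10


class TestClassification:
    def test_fig_pair_verdicts(self, dirichlet_spec, fig_pair):
        A1, A2 = fig_pair
        u0 = InitialCondition.from_callable(lambda x: np.sin(math.pi * x))
        res = classify(A1, A2, u0, dirichlet_spec)
        assert res.verdict is Verdict.INDISTINGUISHABLE_ANI
        assert res.witness is not None
        u0b = InitialCondition.from_callable(lambda x: np.sin(2 * math.pi * x))
        assert classify(A1, A2, u0b, dirichlet_spec).verdict \
            is Verdict.DISTINGUISHABLE_AI
        res_r = classify(ParameterPoint(1, 0, 1), ParameterPoint(2, 0, 1),
                         u0, dirichlet_spec)
        assert res_r.verdict is Verdict.DISTINGUISHABLE_R

    def test_classify_symmetric(self, dirichlet_spec, fig_pair):
        A1, A2 = fig_pair
        u0 = InitialCondition.from_callable(lambda x: np.sin(math.pi * x))
        assert classify(A1, A2, u0, dirichlet_spec).verdict \
            == classify(A2, A1, u0, dirichlet_spec).verdict

    def test_verdicts_validated_by_forward_solver(self, dirichlet_spec, fig_pair):
        """Indistinguishable pairs have coincident trajectories (≤ 1e-6 sup)
        while distinguishable ones separate by > 1e-3 somewhere."""
        A1, A2 = fig_pair
        grid = SpaceTimeGrid.observation()
        U1 = solve_linear_analytic(A1, [1.0], dirichlet_spec, grid)
        U2 = solve_linear_analytic(A2, [1.0], dirichlet_spec, grid)
        assert solution_distance(U1, U2) <= 1e-6
        V1 = solve_linear_analytic(A1, [1.0, 0.2], dirichlet_spec, grid)
        V2 = solve_linear_analytic(A2, [1.0, 0.2], dirichlet_spec, grid)
        assert solution_distance(V1, V2) > 1e-3

    def test_witness_matches_kernel_projection(self, dirichlet_spec, fig_pair):
        A1, A2 = fig_pair
        u0 = InitialCondition.from_callable(lambda x: 2.5 * np.sin(math.pi * x))
        res = classify(A1, A2, u0, dirichlet_spec)
        x = np.linspace(0, 1, 31)
        assert np.allclose(res.witness(x, 0.0), u0(x), atol=1e-9)
        coef, _ = kernel_coefficients(u0, res.auxiliary, dirichlet_spec)
        assert coef[0] == pytest.approx(2.5, rel=1e-9)
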