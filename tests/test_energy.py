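"""Free-energy model: passive elasticity, cytoskeletal chemical equilibrium,
substrate tractions and the suspension reference state."""

import numpy as np
import pytest
from scipy.optimize import brentq

from homeostat import CellParameters, InvalidMicrostateError, elastic, island
from homeostat.energy import (FreeEnergyModel, solve_unbound_fraction,
                              suspension_energy, with_suspension)
from homeostat.geometry import (Discretization, N_COEFFS, ShapeState,
                                evaluate_kinematics, make_reference_cell)

PARAMS = CellParameters()
DISC = Discretization(PARAMS)


def affine_shape(a11, a12, a21, a22):
    c = np.zeros(N_COEFFS)
    c[:4] = [a11, a12, a21, a22]
    return ShapeState(c)


def random_valid_shapes(model, n, seed=0, amp=0.04):
    rng = np.random.default_rng(seed)
    shapes = []
    while len(shapes) < n:
        c = make_reference_cell(model.params).coefficients.copy()
        c += rng.normal(size=N_COEFFS) * amp
        try:
            model.gibbs(ShapeState(c))
        except InvalidMicrostateError:
            continue
        shapes.append(ShapeState(c))
    return shapes


def ogden_density(lam, mu, m, kappa):
    J = lam * lam
    return (2 * mu / m ** 2) * (2 * lam ** m - 2 - m * np.log(J)) \
        + 0.5 * kappa * (J - 1) ** 2


class TestPassiveEnergy:
    def test_zero_at_identity(self):
        model = FreeEnergyModel(PARAMS, elastic(30.0), DISC)
        fields = evaluate_kinematics(make_reference_cell(PARAMS), DISC)
        assert model.passive_energy(fields) == 0.0

    def test_uniform_dilation_closed_form(self):
        model = FreeEnergyModel(PARAMS, elastic(30.0), DISC)
        lam = 1.2
        fields = evaluate_kinematics(affine_shape(lam, 0, 0, lam), DISC)
        p = PARAMS
        A_c = np.pi * (p.R0 ** 2 - p.RN ** 2)
        A_n = np.pi * p.RN ** 2
        expected = p.t0 * (
            A_c * ogden_density(lam, p.mu_cytoplasm, p.ogden_m, p.kappa)
            + A_n * ogden_density(lam, p.mu_nucleus, p.ogden_m, p.kappa)
        ) / p.energy_norm
        # nucleus boundary does not align with quadrature rings
        assert model.passive_energy(fields) == pytest.approx(expected, rel=2e-2)
        assert model.passive_energy(fields) > 0

    def test_linear_in_modulus_at_zero_bulk_penalty(self):
        lam = 1.3
        base = PARAMS.with_(kappa=1e-12, mu_nucleus=PARAMS.mu_cytoplasm)
        doubled = base.with_(mu_cytoplasm=2 * base.mu_cytoplasm,
                             mu_nucleus=2 * base.mu_nucleus)
        fields = evaluate_kinematics(affine_shape(lam, 0, 0, lam), DISC)
        e1 = FreeEnergyModel(base, elastic(30.0), DISC).passive_energy(fields)
        e2 = FreeEnergyModel(doubled, elastic(30.0), DISC).passive_energy(fields)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)


class TestCytoskeletonEquilibrium:
    def test_no_tension_gives_isotropic_fibres(self):
        params = PARAMS.with_(sigma_max=0.0)
        model = FreeEnergyModel(params, elastic(30.0), DISC)
        fields = evaluate_kinematics(affine_shape(1.1, 0.05, 0, 1.0), DISC)
        cyto = model.cytoskeleton_equilibrium(fields)
        # Psi is constant when sigma = 0, so eta cannot depend on phi
        assert np.allclose(cyto.eta, cyto.eta[:, :1])

    def test_equibiaxial_strain_isotropic_in_phi(self):
        model = FreeEnergyModel(PARAMS, elastic(30.0), DISC)
        fields = evaluate_kinematics(affine_shape(1.25, 0, 0, 1.25), DISC)
        cyto = model.cytoskeleton_equilibrium(fields)
        assert np.allclose(cyto.eta, cyto.eta[:, :1])

    def test_conservation_root_matches_bisection_oracle(self):
        # 2-point, 2-orientation toy discretization with stated Psi values
        E = np.exp(np.array([0.5, -1.0, 2.0, 0.0]))
        n_hat = np.array([1.1, 0.9, 1.3, 1.0])
        w = np.full(4, 0.25)
        eta_max = 0.9

        def g(nu):
            return nu + np.sum(w * eta_max * n_hat * nu * E / (1 + nu * E)) - 1.0

        oracle = brentq(g, 1e-12, 1 - 1e-12, xtol=1e-14)
        nu = solve_unbound_fraction(E, n_hat, w, eta_max)
        assert nu == pytest.approx(oracle, abs=1e-10)

    def test_conservation_residual_below_1e8_on_random_states(self):
        model = FreeEnergyModel(PARAMS, elastic(10.0), DISC)
        for shape in random_valid_shapes(model, 20, seed=5):
            fields = evaluate_kinematics(shape, DISC)
            cyto = model.cytoskeleton_equilibrium(fields)
            assert cyto.residual < 1e-8
            assert 0.0 <= cyto.N_b <= 1.0


class TestCytoskeletonEnergy:
    def test_uniform_state_matches_hand_formula(self):
        # identity on a rigid island: all fields uniform, so the energy
        # reduces to closed-form arithmetic
        model = FreeEnergyModel(PARAMS, island(4000.0), DISC)
        shape = make_reference_cell(PARAMS)
        fields = evaluate_kinematics(shape, DISC)
        cyto = model.cytoskeleton_equilibrium(fields)
        p = PARAMS
        psi = (p.sigma_max * p.omega - p.mu_b0) / p.kT_hat
        nu = cyto.N_u
        eta = p.eta_max * nu * np.exp(psi) / (1 + nu * np.exp(psi))
        bracket = nu * (np.log(nu) - 1) + eta * (np.log(eta / p.eta_max) - 1 - psi)
        expected = (p.c_cyto * bracket + p.f_cyto_offset) / p.energy_norm
        assert model.cytoskeleton_energy(cyto, fields) == pytest.approx(expected, rel=1e-10)

    def test_higher_polymerization_lowers_energy(self):
        # raise sigma_max at a fixed deformed shape: N_b rises, F_cyto falls
        shape = affine_shape(1.2, 0.1, 0, 1.15)
        fields = evaluate_kinematics(shape, DISC)
        lo = FreeEnergyModel(PARAMS.with_(sigma_max=200.0), island(9000.0), DISC)
        hi = FreeEnergyModel(PARAMS.with_(sigma_max=280.0), island(9000.0), DISC)
        c_lo, c_hi = (m.cytoskeleton_equilibrium(fields) for m in (lo, hi))
        assert c_hi.N_b > c_lo.N_b
        assert hi.cytoskeleton_energy(c_hi, fields) < lo.cytoskeleton_energy(c_lo, fields)

    def test_rock_inhibition_raises_f_cyto_on_fixed_shapes(self):
        untreated = FreeEnergyModel(with_suspension(PARAMS), island(2725.0), DISC)
        treated = FreeEnergyModel(
            with_suspension(PARAMS.with_(sigma_max=231.0)), island(2725.0), DISC)
        for shape in random_valid_shapes(untreated, 15, seed=11, amp=0.03):
            bd_u = untreated.gibbs(shape)
            bd_t = treated.gibbs(shape)
            assert bd_t.F_cyto > bd_u.F_cyto
            assert bd_t.N_b < bd_u.N_b


class TestSubstrate:
    def test_rigid_island_stores_no_energy(self):
        model = FreeEnergyModel(PARAMS, island(9000.0), DISC)
        for shape in random_valid_shapes(model, 5, seed=2):
            assert model.gibbs(shape).F_sub == 0.0

    def test_zero_stress_state_has_zero_tractions(self):
        params = PARAMS.with_(sigma_max=0.0)
        model = FreeEnergyModel(params, elastic(30.0), DISC)
        bd = model.gibbs(make_reference_cell(params), store_tractions=True)
        assert np.allclose(bd.tractions, 0.0, atol=1e-10)
        assert bd.F_sub == pytest.approx(0.0, abs=1e-12)
        assert bd.T_hat_total == pytest.approx(0.0, abs=1e-12)

    def test_winkler_energy_closed_form_for_uniform_patch(self):
        model = FreeEnergyModel(PARAMS, elastic(30.0), DISC)
        # uniform |T| over the inner half-radius patch
        T0 = 2.5  # kPa
        patch = DISC.r_flat <= 0.5 * PARAMS.R0
        Tmag = np.where(patch, T0, 0.0)
        a_patch = DISC.w[patch].sum()
        expected = T0 ** 2 * a_patch / (2 * model.k_winkler) / PARAMS.energy_norm
        assert model.winkler_energy(Tmag) == pytest.approx(expected, rel=1e-12)

    def test_net_force_and_torque_vanish(self):
        model = FreeEnergyModel(PARAMS, elastic(30.0), DISC)
        for shape in random_valid_shapes(model, 5, seed=9):
            bd = model.gibbs(shape, store_tractions=True)
            x = DISC.positions(shape.coefficients)
            f = np.einsum("p,pi->i", DISC.w, bd.tractions)
            tq = np.sum(DISC.w * (x[:, 0] * bd.tractions[:, 1]
                                  - x[:, 1] * bd.tractions[:, 0]))
            scale = np.sum(DISC.w * np.hypot(*bd.tractions.T)) + 1e-300
            assert abs(f[0]) / scale < 1e-6 and abs(f[1]) / scale < 1e-6
            assert abs(tq) / (scale * PARAMS.R0) < 1e-6


class TestGibbs:
    def test_breakdown_additivity(self):
        model = FreeEnergyModel(PARAMS, elastic(10.0), DISC)
        for shape in random_valid_shapes(model, 100, seed=1):
            bd = model.gibbs(shape)
            assert bd.G == bd.F_passive + bd.F_cyto + bd.F_sub
            assert bd.F_sub >= 0.0 and bd.F_passive >= 0.0

    def test_stiffer_substrate_lowers_gibbs_for_fixed_shape(self):
        soft = FreeEnergyModel(PARAMS, elastic(3.0), DISC)
        stiff = FreeEnergyModel(PARAMS, elastic(70.0), DISC)
        for shape in random_valid_shapes(soft, 10, seed=4):
            g_soft = soft.gibbs(shape)
            g_stiff = stiff.gibbs(shape)
            if g_soft.T_total > 0:
                assert g_stiff.G <= g_soft.G

    def test_island_violation_is_invalid(self):
        model = FreeEnergyModel(PARAMS, island(900.0), DISC)
        with pytest.raises(InvalidMicrostateError):
            model.gibbs(make_reference_cell(PARAMS))  # diameter 40 > side 30


class TestSuspension:
    def test_no_contraction_without_fibre_tension(self):
        state = suspension_energy(PARAMS.with_(sigma_max=0.0))
        assert state.lam == 1.0
        assert state.F_passive == 0.0
        assert state.G_S == pytest.approx(state.F_cyto)

    def test_fibre_tension_contracts_the_cell(self):
        state = suspension_energy(PARAMS)
        assert state.lam < 1.0

    def test_energy_norm_scaling(self):
        g1 = suspension_energy(PARAMS).G_S
        g2 = suspension_energy(PARAMS.with_(energy_norm=2 * PARAMS.energy_norm)).G_S
        assert g1 == pytest.approx(2 * g2, rel=1e-12)

    def test_suspended_f_cyto_matches_full_model_at_identity(self):
        # with sigma_max = 0 the suspended state is the undeformed circle and
        # its cytoskeletal energy must agree with the full-field evaluation
        params = PARAMS.with_(sigma_max=0.0, suspension_tension_factor=1.0)
        model = FreeEnergyModel(params, island(9000.0), DISC)
        bd = model.gibbs(make_reference_cell(params))
        assert suspension_energy(params).F_cyto == pytest.approx(bd.F_cyto, rel=1e-10)
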