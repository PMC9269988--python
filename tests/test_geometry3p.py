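"""Three-phase geometry: areas, curvatures, state function, 0-D dynamics."""

import numpy as np
import pytest
import sympy as sp

from tcatsim import GeometryState, ValidationError
from tcatsim.config import SolverParams, ThreePhaseInitial
from tcatsim.closure import ClosureCoefficients
from tcatsim.fixtures import (
    GeometryParams,
    build_threephase_equilibrium_fixture,
    build_threephase_fixture,
)
from tcatsim.geometry3p import (
    ThreePhaseModel0D,
    curvature_rate_0d,
    fit_state_function,
    galilean_residual,
    gauss_bonnet_residual,
    interface_normal_velocity,
    interfacial_area_rate,
    simulate_threephase_0d,
    sphere_pack_state,
)


class TestSpherePack:
    def test_sphere_formulas(self):
        st_ = sphere_pack_state(1000.0, 1e-4)
        assert st_.area_wn == pytest.approx(1.2566e-4, rel=1e-4)
        assert st_.gauss_curv_wn == pytest.approx(1e8)
        assert st_.mean_curv_wn == pytest.approx(2e4)
        assert st_.euler_density == pytest.approx(1000.0)

    def test_empty_pack(self):
        st_ = sphere_pack_state(0.0, 1e-4)
        assert st_.eps_n == 0.0 and st_.area_wn == 0.0

    def test_extensivity_in_number_density(self):
        a = sphere_pack_state(500.0, 1e-4)
        b = sphere_pack_state(1000.0, 1e-4)
        assert b.eps_n == pytest.approx(2 * a.eps_n)
        assert b.area_wn == pytest.approx(2 * a.area_wn)
        assert b.gauss_curv_wn == pytest.approx(a.gauss_curv_wn)

    def test_dense_packing_rejected(self):
        with pytest.raises(ValidationError):
            sphere_pack_state(1e12, 1e-4)


class TestGaussBonnet:
    def test_sphere_pack_is_exact(self):
        st_ = sphere_pack_state(1234.0, 7e-5)
        scale = 4.0 * np.pi * st_.euler_density
        assert abs(gauss_bonnet_residual(st_)) < 1e-12 * scale

    def test_zero_geometry(self):
        st_ = sphere_pack_state(0.0, 1e-4)
        assert gauss_bonnet_residual(st_) == 0.0

    def test_linear_in_curvature_perturbation(self):
        st_ = sphere_pack_state(1000.0, 1e-4)
        delta = 1e3
        perturbed = GeometryState(
            eps_w=st_.eps_w, eps_n=st_.eps_n, eps_s=st_.eps_s,
            area_wn=st_.area_wn, area_ws=0.0, area_ns=0.0,
            mean_curv_wn=st_.mean_curv_wn,
            gauss_curv_wn=st_.gauss_curv_wn + delta,
            euler_density=st_.euler_density,
        )
        assert gauss_bonnet_residual(perturbed) == pytest.approx(
            -st_.area_wn * delta, rel=1e-9
        )


class TestAreaAndCurvatureRates:
    def _state(self, area=0.1, j=2e4, chi=0.6, phi=0.5):
        return GeometryState(
            eps_w=0.45, eps_n=0.25, eps_s=0.30, area_wn=area,
            area_ws=8e3, area_ns=5e3, mean_curv_wn=j,
            gauss_curv_wn=1e8, wetted_fraction=chi, contact_angle=phi,
        )

    def test_equilibrium_rate_vanishes(self):
        st_ = self._state()
        assert interfacial_area_rate(st_, 0.0, 0.0, 0.0, 2.0, st_.area_wn) == 0.0

    def test_term_isolation_geometric_part(self):
        st_ = self._state()
        q = 3.7e-6
        rate = interfacial_area_rate(st_, q, 0.0, 0.0, 0.0, st_.area_wn)
        assert rate == pytest.approx(st_.mean_curv_wn * q)

    def test_wetting_rate_term(self):
        st_ = self._state()
        rate = interfacial_area_rate(st_, 0.0, 0.0, 1e-5, 0.0, st_.area_wn)
        assert rate == pytest.approx(np.cos(0.5) * (8e3 + 5e3) * 1e-5)

    def test_curvature_rate_conserves_product(self):
        st_ = self._state()
        rate = curvature_rate_0d(st_, 1e-3)
        # d(area*K)/dt = K*da + area*dK = 0
        assert st_.gauss_curv_wn * 1e-3 + st_.area_wn * rate == pytest.approx(
            0.0, abs=1e-6
        )

    def test_vanishing_area_is_error(self):
        st_ = GeometryState(
            eps_w=0.5, eps_n=0.2, eps_s=0.3, area_wn=0.0, area_ws=0.0,
            area_ns=0.0, mean_curv_wn=0.0,
        )
        with pytest.raises(ValidationError):
            curvature_rate_0d(st_, 1.0)


class TestInterfaceNormalVelocity:
    def test_stationary_volume_fraction(self):
        assert interface_normal_velocity(0.0, 5.0, 1e4) == 0.0

    def test_direct_formula(self):
        w = interface_normal_velocity(2e-6, 3.0, 1e2, mean_normal=1.0)
        assert w == pytest.approx(-2e-6 * 4.0 / 1e4)

    def test_sign_flip(self):
        a = interface_normal_velocity(1e-6, 3.0, 1e2)
        b = interface_normal_velocity(-1e-6, 3.0, 1e2)
        assert a == pytest.approx(-b)

    def test_zero_area_with_rate_is_error(self):
        with pytest.raises(ValidationError):
            interface_normal_velocity(1e-6, 3.0, 0.0)


class TestGalileanResidual:
    def test_homogeneous_state_residual_vanishes(self):
        x = np.linspace(0.0, 1.0, 50)
        r = galilean_residual(x, np.full(50, 0.2), np.full(50, 1e4),
                              np.full(50, 2e4), np.full(50, 1e8))
        scale = 2 * 1e8 * 0.2  # magnitude of the curvature term
        assert np.max(np.abs(r)) < 1e-12 * scale

    def test_zero_curvature_linear_field(self):
        x = np.linspace(0.0, 1.0, 50)
        r = galilean_residual(x, 0.1 + 0.01 * x, np.full(50, 1e4),
                              np.full(50, 0.0), np.full(50, 0.0))
        assert np.max(np.abs(r)) < 1e-10

    def test_converges_to_symbolic_residual(self):
        xs = sp.symbols("x")
        eps_e = sp.Rational(1, 10) + sp.sin(2 * sp.pi * xs) / 50
        area_e = 1 + sp.cos(2 * sp.pi * xs) / 5
        j_e = 2 + sp.sin(4 * sp.pi * xs) / 3
        k_e = 1 + sp.cos(2 * sp.pi * xs) / 4
        g = sp.Rational(1, 3)
        exact_e = (-(1 - 2 * g) * sp.diff(area_e * j_e, xs)
                   + 2 * k_e * sp.diff(eps_e, xs)
                   - (1 - g) * sp.diff(eps_e, xs, 3))
        fns = [sp.lambdify(xs, e) for e in (eps_e, area_e, j_e, k_e, exact_e)]
        errs = []
        for n in (100, 200):
            x = np.linspace(0.0, 1.0, n)
            r = galilean_residual(x, fns[0](x), fns[1](x), fns[2](x), fns[3](x))
            sl = slice(4, n - 4)
            errs.append(np.max(np.abs(r[sl] - fns[4](x)[sl])))
        assert errs[1] < errs[0] / 3.0  # ~second-order convergence


class TestStateFunction:
    @staticmethod
    def _sphere_dataset():
        rows = []
        for n_dens in np.linspace(500.0, 2000.0, 6):
            for radius in np.linspace(5e-5, 2e-4, 6):
                st_ = sphere_pack_state(n_dens, radius)
                rows.append([
                    st_.area_wn + st_.area_ns,
                    st_.area_wn * st_.mean_curv_wn,
                    st_.euler_density,
                    st_.eps_n,
                ])
        return np.asarray(rows)

    def test_sphere_pack_family_recovered_exactly(self):
        data = self._sphere_dataset()
        f = fit_state_function(data)
        pred = f.predict(data[:, :3])
        assert np.max(np.abs(pred - data[:, 3]) / data[:, 3]) < 1e-6

    def test_permutation_invariance(self, rng):
        data = self._sphere_dataset()
        f1 = fit_state_function(data)
        f2 = fit_state_function(data[rng.permutation(len(data))])
        probe = data[::5, :3]
        assert np.allclose(f1.predict(probe), f2.predict(probe), rtol=1e-10)

    def test_constant_dataset_gives_constant_predictor(self):
        data = np.tile([1.0, 2.0, 3.0, 0.25], (30, 1))
        f = fit_state_function(data)
        assert np.allclose(f.predict(np.array([[9.0, 9.0, 9.0]])), 0.25)

    def test_degenerate_span_rejected(self):
        data = np.tile([1.0, 2.0, 3.0, 0.25], (30, 1))
        data[:, 3] = np.linspace(0.1, 0.5, 30)
        with pytest.raises(ValidationError):
            fit_state_function(data)

    def test_too_few_states_rejected(self):
        with pytest.raises(ValidationError):
            fit_state_function(np.ones((10, 4)))


class TestThreePhase0D:
    def test_equilibrium_is_stationary(self):
        cfg = build_threephase_equilibrium_fixture()
        res = simulate_threephase_0d(cfg)
        assert abs(res.eps["w"][-1] - res.eps["w"][0]) < 1e-10
        assert abs(res.area_wn[-1] - res.area_wn[0]) < 1e-10 * res.area_wn[0]
        for pid in ("w", "n", "s"):
            for sp, traj in res.omega[pid].items():
                assert abs(traj[-1] - traj[0]) < 1e-10

    def test_transfer_only_two_box(self):
        cfg = build_threephase_fixture(transfers_only_species="o")
        res = simulate_threephase_0d(cfg)
        rho = cfg.densities
        tot = sum(res.eps[p] * rho[p] * res.omega[p]["o"] for p in ("w", "n", "s"))
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-10
        # converges toward matched augmented potentials: both fractions meet
        final_gap = abs(res.omega["w"]["o"][-1] - res.omega["n"]["o"][-1])
        initial_gap = abs(res.omega["w"]["o"][0] - res.omega["n"]["o"][0])
        assert final_gap < 0.05 * initial_gap
        assert res.ledger_min >= -1e-12

    def test_reaction_only_mass_conserved_and_entropy_positive(self):
        cfg = build_threephase_fixture(reactions_only=True)
        res = simulate_threephase_0d(cfg)
        rho = cfg.densities
        tot = sum(
            res.eps[p] * rho[p] * sum(res.omega[p][sp] for sp in res.omega[p])
            for p in ("w", "n", "s")
        )
        assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-10
        assert res.ledger_min >= -1e-12
        assert all(l.groups["reaction"] >= 0.0 for l in res.ledgers)

    def test_area_curvature_product_conserved(self):
        cfg = build_threephase_fixture()
        res = simulate_threephase_0d(cfg)
        prod = res.area_wn * res.gauss_curv_wn
        assert np.max(np.abs(prod - prod[0])) / prod[0] < 1e-9

    def test_volume_fraction_escape_is_error(self):
        cfg = build_threephase_fixture()
        model = ThreePhaseModel0D(cfg)
        y = model.pack(cfg.initial)
        y[0] = 1.4
        with pytest.raises(ValidationError):
            model.rhs(0.0, y)
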