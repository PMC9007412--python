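"""Maxwell-Stefan flux solver: closure, oracles, limits and conversions."""

import numpy as np
import pytest

from msmix.msdiffusion import (
    DegenerateFaceError,
    DiffusionParams,
    FaceState,
    driving_forces,
    fick_ms_convert,
    flux_matrices,
    ms_flux_solve,
)
from msmix.species import SpeciesSet
from msmix.thermo import ThermoParams, ln_activity_coefficients


@pytest.fixture
def dp():
    return DiffusionParams(D01=0.4e-9, D02=1.0e-9, D12=1.25e-9, mode="nonideal")


def random_face(rng, s, scale=1.0):
    x = rng.dirichlet([1, 1, 1])
    g = rng.normal(size=3) * scale
    g -= g.mean()
    return FaceState(x, g, 1.0 / (x @ s.molar_volumes))


def brute_force_flux(f, d, dp, s):
    """All three MS relations plus the volume closure, solved by least squares."""
    x, V = f.x, s.V
    phi = x * V / (x @ V)
    D = dp.pair_matrix()
    A = np.zeros((4, 3))
    b = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if j == i:
                continue
            A[i, j] += x[i] * x[j] / D[i, j]
            A[i, i] -= x[i] * x[j] / D[i, j]
        b[i] = d[i]
    A[3] = phi
    u, *_ = np.linalg.lstsq(A, b, rcond=None)
    return f.total_concentration * x * u


class TestParams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            DiffusionParams(D01=-1e-9)
        with pytest.raises(ValueError):
            DiffusionParams(mode="bogus")

    def test_pair_matrix_symmetric(self, dp):
        D = dp.pair_matrix()
        assert np.allclose(D, D.T)


class TestDrivingForces:
    def test_zero_gradients(self, params, species, dp, rng):
        f = FaceState(
            rng.dirichlet([1, 1, 1]), np.zeros(3), 1e4
        )
        assert np.allclose(driving_forces(f, params, species, "nonideal"), 0.0)

    def test_ideal_mode_is_gradient(self, params, species, rng):
        f = random_face(rng, species)
        assert np.allclose(driving_forces(f, params, species, "ideal"), f.grad_x)

    def test_zero_sum_and_finite_at_zero_solute(self, params, species, rng):
        x = np.array([0.0, 0.35, 0.65])
        g = np.array([1.0, 200.0, -201.0])
        f = FaceState(x, g, 1.0 / (x @ species.molar_volumes))
        d = driving_forces(f, params, species, "nonideal")
        assert np.all(np.isfinite(d))
        assert d.sum() == pytest.approx(0.0, abs=1e-12)

    def test_matches_chemical_potential_chain_rule(self, params, species):
        """d_i = x_i * d(beta mu_i)/dz from finite differences along the
        spatial direction, at a face with all species present."""
        xL = np.array([0.05, 0.60, 0.35])
        xR = np.array([0.04, 0.55, 0.41])
        dz = 1e-5
        f = FaceState.from_compositions(xL, xR, dz, species)
        d = driving_forces(f, params, species, "nonideal")
        eps = 1e-7  # spatial half-step for the directional derivative

        def mu(x):
            return np.log(x) + ln_activity_coefficients(x, params, species)

        dmu_dz = (mu(f.x + eps * f.grad_x) - mu(f.x - eps * f.grad_x)) / (2 * eps)
        oracle = f.x * dmu_dz
        assert np.allclose(d, oracle, rtol=1e-5, atol=1e-10)


class TestFluxSolve:
    def test_uniform_composition_gives_zero_flux(self, params, species, dp, rng):
        x = rng.dirichlet([1, 1, 1])
        f = FaceState(x, np.zeros(3), 1.0 / (x @ species.molar_volumes))
        J = ms_flux_solve(f, np.zeros(3), dp, species)
        assert np.allclose(J.J, 0.0)

    def test_ideal_limit_is_fickian(self, ideal_params, ideal_species, rng):
        """Equal diffusivities, equal volumes: J_i = -c_t D grad(x_i)."""
        dpe = DiffusionParams(1e-9, 1e-9, 1e-9, mode="ideal")
        for _ in range(5):
            f = random_face(rng, ideal_species)
            d = driving_forces(f, ideal_params, ideal_species, "ideal")
            J = ms_flux_solve(f, d, dpe, ideal_species)
            expected = -f.total_concentration * 1e-9 * f.grad_x
            assert np.allclose(J.J, expected, rtol=1e-12, atol=1e-20)

    def test_volume_flux_closure(self, params, species, dp, rng):
        for _ in range(20):
            f = random_face(rng, species)
            d = driving_forces(f, params, species, "nonideal")
            J = ms_flux_solve(f, d, dp, species)
            assert J.volume_flux_residual(species) < 1e-12

    def test_agrees_with_brute_force_least_squares(self, params, species, dp, rng):
        for _ in range(50):
            f = random_face(rng, species)
            d = driving_forces(f, params, species, "nonideal")
            J = ms_flux_solve(f, d, dp, species).J
            Jb = brute_force_flux(f, d, dp, species)
            assert np.allclose(J, Jb, rtol=1e-10, atol=1e-10 * np.abs(Jb).max())

    def test_absent_species_gets_zero_flux(self, params, species, dp):
        x = np.array([0.0, 0.4, 0.6])
        g = np.array([0.0, 100.0, -100.0])
        f = FaceState(x, g, 1.0 / (x @ species.molar_volumes))
        d = driving_forces(f, params, species, "nonideal")
        J = ms_flux_solve(f, d, dp, species)
        assert J.J[0] == 0.0
        assert J.volume_flux_residual(species) < 1e-12

    def test_degenerate_face_raises(self, params, species, dp):
        x = np.array([1.0, 0.0, 0.0])
        f = FaceState(x, np.zeros(3), 1.0 / (x @ species.molar_volumes))
        with pytest.raises(DegenerateFaceError):
            ms_flux_solve(f, np.zeros(3), dp, species)

    def test_frame_scale_invariance(self, params, dp, rng):
        """Scaling all physical volumes by a common factor leaves the volume
        fluxes V_i J_i (hence the phi dynamics) unchanged."""
        s1 = SpeciesSet()
        s2 = SpeciesSet(solvent_molar_volume=s1.solvent_molar_volume * 3.7)
        for _ in range(5):
            x = rng.dirichlet([1, 1, 1])
            g = rng.normal(size=3)
            g -= g.mean()
            out = []
            for s in (s1, s2):
                f = FaceState(x, g, 1.0 / (x @ s.molar_volumes))
                d = driving_forces(f, params, s, "nonideal")
                J = ms_flux_solve(f, d, dp, s)
                out.append(J.J * s.molar_volumes)
            assert np.allclose(out[0], out[1], rtol=1e-12)

    def test_species_permutation_symmetry(self, rng):
        """Permuting labels with correspondingly permuted chi, v and D
        permutes the fluxes."""
        s = SpeciesSet()
        p = ThermoParams.glycine_water_ethanol()
        perm = [0, 2, 1]
        chi_p = p.chi[np.ix_(perm, perm)] * s.v[2]
        s_p = SpeciesSet(
            names=("glycine", "ethanol", "water"),
            molar_masses=tuple(s.M[perm]),
            thermo_volume_ratios=tuple(s.v[perm] / s.v[2]),
            physical_volume_ratios=tuple(s.V[perm] / s.V[2]),
            solvent_molar_volume=s.molar_volumes[2],
        )
        p_p = ThermoParams(chi=chi_p, solubility_constant=p.solubility_constant)
        dp = DiffusionParams(D01=0.4e-9, D02=1.0e-9, D12=1.25e-9)
        dp_p = DiffusionParams(D01=1.0e-9, D02=0.4e-9, D12=1.25e-9)  # pairs permuted
        for _ in range(5):
            x = rng.dirichlet([1, 1, 1])
            g = rng.normal(size=3)
            g -= g.mean()
            f = FaceState(x, g, 1.0 / (x @ s.molar_volumes))
            d = driving_forces(f, p, s, "nonideal")
            J = ms_flux_solve(f, d, dp, s).J
            f2 = FaceState(x[perm], g[perm], 1.0 / (x[perm] @ s_p.molar_volumes))
            d2 = driving_forces(f2, p_p, s_p, "nonideal")
            J2 = ms_flux_solve(f2, d2, dp_p, s_p).J
            assert np.allclose(J[perm], J2, rtol=1e-9)


class TestFickMsConversion:
    def test_ideal_parameters_identity(self, ideal_params, ideal_species):
        for x in (0.1, 0.5, 0.9):
            out = fick_ms_convert(x, 1e-9, (1, 2), ideal_params, ideal_species)
            assert out == pytest.approx(1e-9, rel=1e-12)

    def test_round_trip(self, params, species):
        d0 = 0.4e-9
        ms = fick_ms_convert(0.5, d0, (2, 1), params, species, "fick_to_ms")
        back = fick_ms_convert(0.5, ms, (2, 1), params, species, "ms_to_fick")
        assert back == pytest.approx(d0, rel=1e-12)

    def test_water_ethanol_edge_against_fd_oracle(self, params, species):
        """Gamma_b from central differences of ln gamma along the binary edge."""
        x = 0.5
        h = 1e-6

        def lng_eth(xe):
            comp = np.array([0.0, 1 - xe, xe])
            return ln_activity_coefficients(comp, params, species)[2]

        gamma_b = 1 + x * (lng_eth(x + h) - lng_eth(x - h)) / (2 * h)
        got = fick_ms_convert(x, 0.4e-9, (2, 1), params, species, "fick_to_ms")
        assert got == pytest.approx(0.4e-9 / gamma_b, rel=1e-6)

    def test_inside_miscibility_gap_rejected(self, params, species):
        """Conversion undefined where the binary thermodynamic factor <= 0,
        located by the bracketing oracle on the solute/antisolvent edge."""
        ts = np.linspace(1e-3, 1 - 1e-3, 400)
        edge = np.stack([ts, np.zeros_like(ts), 1 - ts], axis=-1)
        lng0 = ln_activity_coefficients(edge, params, species)[:, 0]
        gb = 1 + ts * np.gradient(lng0, ts)
        x_bad = float(ts[np.argmin(gb)])
        with pytest.raises(ValueError, match="miscibility gap"):
            fick_ms_convert(x_bad, 1e-9, (0, 2), params, species)

    def test_invalid_pair_and_range(self, params, species):
        with pytest.raises(ValueError):
            fick_ms_convert(0.5, 1e-9, (1, 1), params, species)
        with pytest.raises(ValueError):
            fick_ms_convert(1.0, 1e-9, (1, 2), params, species)


class TestFluxMatrices:
    def test_consistent_with_pointwise_solver(self, params, species, dp, rng):
        """The batched per-face diffusion matrices reproduce the pointwise
        Maxwell-Stefan solve for infinitesimal gradients."""
        V = species.V
        for _ in range(5):
            x = rng.dirichlet([1, 1, 1])
            dphi = rng.normal(size=2)
            B = flux_matrices(x[None, :], params, species, dp)[0]
            F_B = -B @ dphi
            phi = x * V / (x @ V)
            dphi3 = np.array([dphi[0], dphi[1], -dphi.sum()])
            h = 1e-7
            phiL, phiR = phi - 0.5 * h * dphi3, phi + 0.5 * h * dphi3
            xL = (phiL / V) / np.sum(phiL / V)
            xR = (phiR / V) / np.sum(phiR / V)
            f = FaceState.from_compositions(xL, xR, h, species)
            d = driving_forces(f, params, species, "nonideal")
            J = ms_flux_solve(f, d, dp, species)
            F_direct = J.J[:2] * species.molar_volumes[:2]
            assert np.allclose(F_B, F_direct, rtol=1e-5)
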