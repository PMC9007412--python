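"""Activity model: limits, thermodynamic consistency, and derivative oracles.

The analytic activity coefficients and thermodynamic factors are checked
against independent numerical differentiation of the Gibbs energy.
"""

import numpy as np
import pytest

from msmix.species import Composition, SpeciesSet
from msmix.thermo import (
    ThermoParams,
    _gibbs,
    activity_coefficients,
    chemical_potentials,
    ln_activity_coefficients,
    molar_gibbs_energy,
    stability_test,
    supersaturation_nonideal,
    thermodynamic_factor,
)

# frozen from a 50-digit evaluation of the mixing free energy at the
# saturated-times-0.85 aqueous composition (independent oracle)
GIBBS_REGRESSION = -0.20384661169863216
X_AQ = np.array([0.0655, 0.9345, 0.0])


def _fd_lngamma_from_gibbs(x, p, s, h=1e-7):
    """Partial-molar derivative of n*G(n) as an independent gamma oracle."""
    out = np.zeros(3)
    for i in range(3):
        up, dn = x.copy(), x.copy()
        up[i] += h
        dn[i] -= h
        gu = up.sum() * _gibbs(up / up.sum(), p, s)
        gd = dn.sum() * _gibbs(dn / dn.sum(), p, s)
        with np.errstate(divide="ignore"):
            out[i] = (gu - gd) / (2 * h) - np.log(x[i])
    return out


class TestGibbsEnergy:
    def test_pure_corners_are_zero(self, params, species):
        for i in range(3):
            x = np.zeros(3)
            x[i] = 1.0
            assert molar_gibbs_energy(Composition(x), params, species) == 0.0

    def test_ideal_entropy_of_mixing(self, ideal_params, ideal_species):
        c = Composition(np.full(3, 1.0 / 3.0))
        expected = np.log(1.0 / 3.0)  # 3 * (1/3) ln(1/3)
        assert molar_gibbs_energy(c, ideal_params, ideal_species) == pytest.approx(
            expected, abs=1e-14
        )

    def test_regression_value_at_aqueous_composition(self, params, species):
        g = molar_gibbs_energy(Composition(X_AQ), params, species)
        assert g == pytest.approx(GIBBS_REGRESSION, abs=1e-14)


class TestActivityCoefficients:
    def test_ideal_gammas_are_unity(self, ideal_params, ideal_species, rng):
        for _ in range(5):
            c = Composition(rng.dirichlet([1, 1, 1]))
            assert activity_coefficients(c, ideal_params, ideal_species) == pytest.approx(
                [1.0, 1.0, 1.0], abs=1e-14
            )

    def test_pure_component_normalization(self, params, species):
        g = activity_coefficients(Composition([1.0, 0.0, 0.0]), params, species)
        assert g[0] == pytest.approx(1.0, abs=1e-14)

    def test_solute_gamma_in_aqueous_solution(self, params, species):
        """gamma_0 ~ 1.50 at the 0.85-supersaturated aqueous composition,
        cross-checked against differentiation of the Gibbs energy."""
        g0 = activity_coefficients(Composition(X_AQ), params, species)[0]
        assert g0 == pytest.approx(1.50, abs=0.005)
        oracle = np.exp(_fd_lngamma_from_gibbs(X_AQ.copy(), params, species))
        assert g0 == pytest.approx(oracle[0], rel=1e-6)

    def test_antisolvent_infinite_dilution_limit(self, params, species):
        """Analytic x2 -> 0 limit in pure water: ln g2 = ln v2 + 1 - v2 + v2*chi12."""
        v2, chi12 = species.v[2], params.chi[1, 2]
        expected = np.exp(np.log(v2) + 1.0 - v2 + v2 * chi12)
        got = activity_coefficients(Composition([0.0, 1.0, 0.0]), params, species)[2]
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(4.5288367032098528, rel=1e-12)

    def test_matches_gibbs_derivative_at_random_points(self, params, species, rng):
        for _ in range(20):
            x = rng.dirichlet([1, 1, 1])
            got = ln_activity_coefficients(x, params, species)
            oracle = _fd_lngamma_from_gibbs(x, params, species)
            assert np.allclose(got, oracle, atol=1e-6)

    def test_gibbs_duhem(self, params, species, rng):
        """sum_i x_i d(ln gamma_i)/ds = 0 along random simplex directions."""
        h = 1e-6
        for _ in range(100):
            x = rng.dirichlet([1, 1, 1])
            d = rng.normal(size=3)
            d -= d.mean()
            diff = (
                ln_activity_coefficients(x + h * d, params, species)
                - ln_activity_coefficients(x - h * d, params, species)
            ) / (2 * h)
            assert abs(x @ diff) < 1e-8

    def test_species_relabel_symmetry(self, rng):
        """Swapping solvent and antisolvent labels with transposed parameters
        permutes the outputs."""
        s = SpeciesSet()
        p = ThermoParams.glycine_water_ethanol()
        perm = [0, 2, 1]
        # with the reference volume pinned to the (new) solvent, the residual
        # prefactor v/v_ref changes by the old antisolvent ratio; chi absorbs it
        chi_p = p.chi[np.ix_(perm, perm)] * s.v[2]
        v_new = s.v[perm] / s.v[2]
        s_p = SpeciesSet(
            names=("glycine", "ethanol", "water"),
            molar_masses=tuple(s.M[perm]),
            thermo_volume_ratios=tuple(v_new),
            physical_volume_ratios=(1.0, 1.0, 1.0),
        )
        p_p = ThermoParams(chi=chi_p, solubility_constant=p.solubility_constant)
        for _ in range(5):
            x = rng.dirichlet([1, 1, 1])
            a = ln_activity_coefficients(x, p, s)
            b = ln_activity_coefficients(x[perm], p_p, s_p)
            # activity coefficients are invariant under the reference-volume
            # rescaling, so the permuted system must reproduce them
            assert np.allclose(a[perm], b, atol=1e-12)


class TestChemicalPotentials:
    def test_pure_reference_state(self, params, species):
        assert chemical_potentials(
            Composition([1.0, 0.0, 0.0]), params, species, species=0
        ) == pytest.approx(0.0, abs=1e-14)

    def test_ideal_solution_log_form(self, ideal_params, ideal_species):
        c = Composition([0.25, 0.5, 0.25])
        mu = chemical_potentials(c, ideal_params, ideal_species)
        assert np.allclose(mu, np.log(c.x), atol=1e-14)

    def test_composes_activity_and_mole_fraction(self, params, species):
        c = Composition(X_AQ)
        g0 = activity_coefficients(c, params, species)[0]
        assert chemical_potentials(c, params, species, species=0) == pytest.approx(
            np.log(0.0655 * g0)
        )

    def test_absent_species_rejected(self, params, species):
        with pytest.raises(ValueError):
            chemical_potentials(Composition(X_AQ), params, species, species=2)
        with pytest.raises(ValueError):
            chemical_potentials(Composition(X_AQ), params, species)


class TestSupersaturation:
    def test_zero_solute(self, params, species):
        assert supersaturation_nonideal(Composition([0, 0.5, 0.5]), params, species) == 0.0

    def test_value_at_initial_aqueous_solution(self, params, species):
        assert supersaturation_nonideal(
            Composition(X_AQ), params, species
        ) == pytest.approx(0.89, abs=0.005)


class TestThermodynamicFactor:
    def test_ideal_reduces_to_identity(self, ideal_params, ideal_species, rng):
        for _ in range(5):
            tf = thermodynamic_factor(
                Composition(rng.dirichlet([1, 1, 1])), ideal_params, ideal_species
            )
            assert np.allclose(tf.gamma_matrix, np.eye(2), atol=1e-14)

    def test_matches_finite_difference_oracle(self, params, species):
        x = np.array([0.02, 0.93, 0.05])
        tf = thermodynamic_factor(Composition(x), params, species)
        h = 1e-6
        oracle = np.zeros((2, 2))
        for j in range(2):
            up, dn = x.copy(), x.copy()
            up[j] += h
            up[2] -= h
            dn[j] -= h
            dn[2] += h
            diff = (
                ln_activity_coefficients(up, params, species)
                - ln_activity_coefficients(dn, params, species)
            ) / (2 * h)
            oracle[:, j] = diff[:2]
        oracle = np.eye(2) + x[:2, None] * oracle
        assert np.allclose(tf.gamma_matrix, oracle, atol=1e-6)

    def test_finite_on_zero_solute_edge(self, params, species):
        tf = thermodynamic_factor(Composition([0.0, 0.4, 0.6]), params, species)
        assert np.all(np.isfinite(tf.gamma_matrix))

    def test_dilute_aqueous_corner_is_stable(self, params, species):
        """Positive-definite Gamma near pure water, confirmed by the Hessian
        of the Gibbs energy (finite differences)."""
        x = np.array([0.001, 0.998, 0.001])
        tf = thermodynamic_factor(Composition(x), params, species)
        assert tf.min_eigenvalue > 0
        h = 1e-5
        H = np.zeros((2, 2))

        def g_of(y0, y1):
            return _gibbs(np.array([y0, y1, 1 - y0 - y1]), params, species)

        for a in range(2):
            for b in range(2):
                pp = [x[0], x[1]]
                pm = [x[0], x[1]]
                mp_ = [x[0], x[1]]
                mm = [x[0], x[1]]
                pp[a] += h
                pp[b] += h
                pm[a] += h
                pm[b] -= h
                mp_[a] -= h
                mp_[b] += h
                mm[a] -= h
                mm[b] -= h
                H[a, b] = (g_of(*pp) - g_of(*pm) - g_of(*mp_) + g_of(*mm)) / (4 * h * h)
        assert np.all(np.linalg.eigvalsh(H) > 0)


class TestStability:
    def test_ideal_never_demixes(self, ideal_params, ideal_species, rng):
        for _ in range(10):
            stable, m = stability_test(
                Composition(rng.dirichlet([1, 1, 1])), ideal_params, ideal_species
            )
            assert stable and m > 0

    def test_classification_invariant_under_dependent_choice(self, params, species, rng):
        for _ in range(20):
            c = Composition(rng.dirichlet([1, 1, 1]))
            votes = {stability_test(c, params, species, dependent=d)[0] for d in range(3)}
            assert len(votes) == 1

    def test_glycine_ethanol_tie_line_midpoint_unstable(self, params, species):
        """Bracketing oracle: the binary thermodynamic factor goes negative
        between the coexisting compositions, so the midpoint is unstable."""
        ts = np.linspace(1e-3, 1 - 1e-3, 400)
        edge = np.stack([ts, np.zeros_like(ts), 1 - ts], axis=-1)
        lng0 = ln_activity_coefficients(edge, params, species)[:, 0]
        gb = 1 + ts * np.gradient(lng0, ts)
        assert gb.min() < 0  # a miscibility gap exists on the edge
        mid = 0.5 * (ts[np.argmax(gb < 0)] + ts[len(ts) - 1 - np.argmax(gb[::-1] < 0)])
        stable, _ = stability_test(Composition([mid, 0.0, 1 - mid]), params, species)
        assert not stable
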