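r"""Extended Scatchard–Hildebrand solution thermodynamics for a ternary mixture.

Model
-----
The dimensionless molar Gibbs energy of mixing combines a Flory–Huggins
entropy (size-asymmetric) with a regular-solution residual,

.. math::

    \beta \Delta G = \sum_i x_i \ln\varphi_i
        + \frac{v}{v_\mathrm{ref}} \sum_{i<j} \chi_{ij}\,\varphi_i \varphi_j ,

where :math:`v = \sum_i x_i v_i`, :math:`\varphi_i = x_i v_i / v` and the
reference volume is the solvent effective volume.  The exact partial-molar
derivative gives the activity coefficients

.. math::

    \ln\gamma_i = \ln\frac{\varphi_i}{x_i} + 1 - \frac{v_i}{v}
        + \frac{v_i}{v_\mathrm{ref}} \Bigl[ \sum_{j\ne i}\chi_{ij}\varphi_j
        - \sum_{j<k}\chi_{jk}\varphi_j\varphi_k \Bigr].

Supersaturation with respect to the crystalline solute is the activity ratio
:math:`S = x_0\gamma_0\, e^{-\beta(\mu_0^s-\mu_0^\circ)}`; the solubility
constant :math:`\beta(\mu_0^s-\mu_0^\circ)` is composition independent, so a
single activity evaluation suffices.

The thermodynamic factor matrix
:math:`\Gamma_{ij} = \delta_{ij} + x_i\,\partial\ln\gamma_i/\partial x_j`
(antisolvent taken as the dependent species) converts mole-fraction gradients
into activity-based driving forces; its eigenvalues classify local phase
stability, with :math:`\min\operatorname{eig}\Gamma \le 0` marking the
spinodal.  All derivatives here are analytic; finite differences appear only
in the test suite as an independent oracle.

All functions accept arrays of compositions with shape ``(..., 3)`` and
broadcast; the dataclass-level API wraps single :class:`~msmix.species.Composition`
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import Composition, SpeciesSet

__all__ = [
    "ThermoParams",
    "ThermoFactor",
    "molar_gibbs_energy",
    "activity_coefficients",
    "ln_activity_coefficients",
    "chemical_potentials",
    "supersaturation_nonideal",
    "thermodynamic_factor",
    "stability_test",
]


def _chi_matrix(chi01: float, chi02: float, chi12: float) -> np.ndarray:
    chi = np.zeros((3, 3))
    chi[0, 1] = chi[1, 0] = chi01
    chi[0, 2] = chi[2, 0] = chi02
    chi[1, 2] = chi[2, 1] = chi12
    return chi


@dataclass(frozen=True)
class ThermoParams:
    """Interaction parameters and solubility constant of the activity model.

    ``chi`` is the symmetric, zero-diagonal binary interaction matrix; larger
    values mean a stronger tendency of the pair to demix.  ``solubility_constant``
    is the dimensionless :math:`\\beta(\\mu_0^s - \\mu_0^\\circ)` fixing the
    solute solubility curve.  The temperature is a fixed label: all parameters
    are dimensionless at 298 K.
    """

    chi: np.ndarray = field(default_factory=lambda: _chi_matrix(0.59, 2.075, 1.07))
    solubility_constant: float = -2.2
    temperature: float = 298.0

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        if chi.shape != (3, 3):
            raise ValueError("chi must be a 3x3 matrix")
        if not np.allclose(chi, chi.T, atol=0.0):
            raise ValueError("chi must be symmetric")
        if np.any(np.diag(chi) != 0.0):
            raise ValueError("chi must have a zero diagonal")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "chi", chi)

    @classmethod
    def glycine_water_ethanol(cls) -> "ThermoParams":
        """Fitted parameters of the glycine/water/ethanol system at 298 K."""
        return cls()

    @classmethod
    def ideal(cls) -> "ThermoParams":
        """All interactions zero; with equal effective volumes gives gamma = 1."""
        return cls(chi=np.zeros((3, 3)), solubility_constant=-2.2)

    def is_ideal(self) -> bool:
        return bool(np.all(self.chi == 0.0))


@dataclass(frozen=True)
class ThermoFactor:
    """2x2 thermodynamic factor over the independent species (solute, solvent)."""

    gamma_matrix: np.ndarray
    eigenvalues: np.ndarray

    @property
    def min_eigenvalue(self) -> float:
        return float(np.min(self.eigenvalues))

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.gamma_matrix))


# ---------------------------------------------------------------------------
# vectorized core (compositions with shape (..., 3))
# ---------------------------------------------------------------------------

def _phi_and_v(x: np.ndarray, s: SpeciesSet) -> tuple[np.ndarray, np.ndarray]:
    v = s.v
    vbar = x @ v
    phi = x * v / vbar[..., None]
    return phi, vbar


def ln_activity_coefficients(x: np.ndarray, p: ThermoParams, s: SpeciesSet) -> np.ndarray:
    """ln gamma_i for compositions ``x`` of shape ``(..., 3)``.

    The ``x_i -> 0`` limit is taken analytically: ``phi_i/x_i -> v_i/v``.
    """
    x = np.asarray(x, dtype=float)
    v = s.v
    phi, vbar = _phi_and_v(x, s)
    chi_phi = phi @ p.chi  # (..., 3): (chi . phi)_i
    q = 0.5 * np.einsum("...i,...i->...", phi, chi_phi)  # sum_{j<k} chi phi phi
    # ln(phi_i / x_i) = ln(v_i / vbar), exact for all x_i including 0
    ln_ratio = np.log(v) - np.log(vbar)[..., None]
    return ln_ratio + 1.0 - v / vbar[..., None] + v * (chi_phi - q[..., None])


def _gibbs(x: np.ndarray, p: ThermoParams, s: SpeciesSet) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    phi, vbar = _phi_and_v(x, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(x > 0.0, x * np.log(np.where(phi > 0.0, phi, 1.0)), 0.0).sum(axis=-1)
    chi_phi = phi @ p.chi
    res = vbar * 0.5 * np.einsum("...i,...i->...", phi, chi_phi)
    return ent + res


def _gamma_matrix(x: np.ndarray, p: ThermoParams, s: SpeciesSet, dependent: int = 2) -> np.ndarray:
    """Analytic thermodynamic factor, shape ``(..., 2, 2)``.

    Independent species are the two others in ascending order; ``x_dependent``
    absorbs the simplex constraint.  The result is regular on the boundary
    faces where an independent species vanishes, because
    ``x_i / phi_i = v / v_i`` there.
    """
    x = np.asarray(x, dtype=float)
    v = s.v
    idx = [i for i in range(3) if i != dependent]
    phi, vbar = _phi_and_v(x, s)
    chi_phi = phi @ p.chi

    # dv/dx_j and dphi_i/dx_j for independent j (dependent species eliminated)
    dv = v[idx] - v[dependent]  # (2,)
    # dphi[..., i, j] = (v_i/v)(delta_ij - delta_i,dep) - phi_i dv_j / v
    delta = np.zeros((3, 2))
    for col, j in enumerate(idx):
        delta[j, col] = 1.0
    delta[dependent, :] = -1.0
    dphi = (v[:, None] * delta) / vbar[..., None, None] - (
        phi[..., :, None] * dv[None, :]
    ) / vbar[..., None, None]

    # dQ/dx_j = sum_m (chi.phi)_m dphi_m/dx_j
    dQ = np.einsum("...m,...mj->...j", chi_phi, dphi)
    # d(chi.phi)_i/dx_j = sum_k chi_ik dphi_k/dx_j
    dchi_phi = np.einsum("ik,...kj->...ij", p.chi, dphi)

    # Gamma_ij = (v/v_i) dphi_i/dx_j + x_i [ (v_i/v^2) dv_j + v_i (dchi_phi_ij - dQ_j) ]
    xi = x[..., idx]
    vi = v[idx]
    term1 = (vbar[..., None, None] / vi[:, None]) * dphi[..., idx, :]
    bracket = (vi[:, None] / vbar[..., None, None] ** 2) * dv[None, :] + vi[:, None] * (
        dchi_phi[..., idx, :] - dQ[..., None, :]
    )
    return term1 + xi[..., :, None] * bracket


def _min_eig_2x2(g: np.ndarray) -> np.ndarray:
    """Smaller eigenvalue (real part) of a batch of 2x2 matrices."""
    tr = g[..., 0, 0] + g[..., 1, 1]
    disc = 0.25 * (g[..., 0, 0] - g[..., 1, 1]) ** 2 + g[..., 0, 1] * g[..., 1, 0]
    return 0.5 * tr - np.sqrt(np.clip(disc, 0.0, None))


# ---------------------------------------------------------------------------
# Composition-level API
# ---------------------------------------------------------------------------

def molar_gibbs_energy(c: Composition, p: ThermoParams, s: SpeciesSet) -> float:
    """Dimensionless molar Gibbs energy of mixing; zero at every pure corner."""
    return float(_gibbs(c.x, p, s))


def activity_coefficients(c: Composition, p: ThermoParams, s: SpeciesSet) -> np.ndarray:
    return np.exp(ln_activity_coefficients(c.x, p, s))


def chemical_potentials(
    c: Composition, p: ThermoParams, s: SpeciesSet, species: int | None = None
) -> np.ndarray | float:
    """beta * (mu_i - mu_i^pure) = ln(x_i gamma_i).

    Diverges at ``x_i = 0``, so requesting a vanished species raises.
    """
    lng = ln_activity_coefficients(c.x, p, s)
    if species is not None:
        if c.x[species] <= 0.0:
            raise ValueError(f"chemical potential undefined at x[{species}] = 0")
        return float(np.log(c.x[species]) + lng[species])
    if np.any(c.x <= 0.0):
        missing = [s.names[i] for i in range(3) if c.x[i] <= 0.0]
        raise ValueError(f"chemical potential undefined for absent species: {missing}")
    return np.log(c.x) + lng


def supersaturation_nonideal(c: Composition, p: ThermoParams, s: SpeciesSet) -> float:
    """Activity-based supersaturation S = x_0 gamma_0 exp(-solubility_constant)."""
    x0 = c.x[0]
    if x0 == 0.0:
        return 0.0
    lng0 = ln_activity_coefficients(c.x, p, s)[0]
    return float(x0 * np.exp(lng0 - p.solubility_constant))


def thermodynamic_factor(
    c: Composition, p: ThermoParams, s: SpeciesSet, dependent: int = 2
) -> ThermoFactor:
    g = _gamma_matrix(c.x, p, s, dependent=dependent)
    eig = np.linalg.eigvals(g)
    if np.max(np.abs(eig.imag)) > 1e-9 * max(1.0, np.max(np.abs(eig.real))):
        raise ArithmeticError(f"complex thermodynamic-factor eigenvalues: {eig}")
    return ThermoFactor(gamma_matrix=g, eigenvalues=np.sort(eig.real))


def stability_test(
    c: Composition, p: ThermoParams, s: SpeciesSet, dependent: int = 2
) -> tuple[bool, float]:
    """Local phase stability: ``(stable, min eigenvalue of Gamma)``.

    Unstable (inside the spinodal) iff the smaller eigenvalue is <= 0; the
    classification does not depend on which species is taken as dependent.
    """
    tf = thermodynamic_factor(c, p, s, dependent=dependent)
    m = tf.min_eigenvalue
    return (m > 0.0, m)
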