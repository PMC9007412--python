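r"""Maxwell–Stefan fluxes in the volume reference frame for a ternary liquid.

Chemical-potential gradients drive the relative motion of species through the
Maxwell–Stefan relations

.. math::

    d_i \;=\; \sum_{j\ne i} \frac{x_i x_j}{\text{\DJ}_{ij}} (u_j - u_i),
    \qquad
    d_i \;=\; \sum_j \Gamma_{ij} \,\partial_z x_j ,

with symmetric pairwise diffusivities.  In a closed incompressible channel
the natural frame is the volume frame, where the volume-average velocity
vanishes; the closure :math:`\sum_i \phi_i u_i = 0` (equivalently
:math:`\sum_i V_i J_i = 0`, with :math:`\phi_i` the physical volume
fractions) completes the linear system for the species velocities, which is
solved directly rather than through a transcribed matrix inverse.  The ideal
mode replaces :math:`\Gamma` by the identity, recovering independent Fickian
diffusion when all diffusivities and physical volumes are equal.

Species with mole fraction below a floor of 1e-12 are treated as absent:
their velocity is pinned to the frame velocity, giving exactly zero flux, and
the redundant Maxwell–Stefan row is dropped (only :math:`n-1` of them are
independent by Gibbs–Duhem).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import SpeciesSet
from .thermo import ThermoParams, _gamma_matrix

__all__ = [
    "DiffusionParams",
    "FaceState",
    "FluxVector",
    "DegenerateFaceError",
    "driving_forces",
    "ms_flux_solve",
    "fick_ms_convert",
    "flux_matrices",
]

X_FLOOR = 1e-12


class DegenerateFaceError(ValueError):
    """Raised when fewer than two species are present at a face."""


@dataclass(frozen=True)
class DiffusionParams:
    """Symmetric Maxwell–Stefan diffusivities (m^2/s) and transport mode.

    ``mode == "ideal"`` uses identity thermodynamic factors (concentration
    gradients as driving forces); ``"nonideal"`` uses the activity model.
    The diffusivities are composition independent by default;
    ``composition_dependent`` may hold a callable ``x -> (D01, D02, D12)``
    hook, though none ships with the package.
    """

    D01: float = 1e-9
    D02: float = 1e-9
    D12: float = 1e-9
    mode: str = "nonideal"
    composition_dependent: object = None

    def __post_init__(self) -> None:
        if min(self.D01, self.D02, self.D12) <= 0:
            raise ValueError("Maxwell-Stefan diffusivities must be positive")
        if self.mode not in ("ideal", "nonideal"):
            raise ValueError("mode must be 'ideal' or 'nonideal'")

    def pair_matrix(self, x: np.ndarray | None = None) -> np.ndarray:
        """Symmetric 3x3 matrix of pair diffusivities (diagonal unused)."""
        if self.composition_dependent is not None and x is not None:
            d01, d02, d12 = self.composition_dependent(x)
        else:
            d01, d02, d12 = self.D01, self.D02, self.D12
        D = np.full((3, 3), np.inf)
        D[0, 1] = D[1, 0] = d01
        D[0, 2] = D[2, 0] = d02
        D[1, 2] = D[2, 1] = d12
        return D


@dataclass(frozen=True)
class FaceState:
    """Composition, mole-fraction gradients (1/m) and total molar concentration
    (mol/m^3) at a cell face."""

    x: np.ndarray
    grad_x: np.ndarray
    total_concentration: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        g = np.asarray(self.grad_x, float)
        if abs(x.sum() - 1.0) > 1e-10 or np.any(x < 0):
            raise ValueError("face composition must be a valid mole-fraction triple")
        if abs(g.sum()) > 1e-6 * max(1.0, np.max(np.abs(g))):
            raise ValueError("mole-fraction gradients must sum to zero")
        g = g - g.sum() / 3.0  # project out rounding in the zero-sum constraint
        if self.total_concentration <= 0:
            raise ValueError("total concentration must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "grad_x", g)

    @classmethod
    def from_compositions(
        cls, x_left: np.ndarray, x_right: np.ndarray, dz: float, s: SpeciesSet
    ) -> "FaceState":
        x = 0.5 * (np.asarray(x_left, float) + np.asarray(x_right, float))
        grad = (np.asarray(x_right, float) - np.asarray(x_left, float)) / dz
        ct = 1.0 / float(x @ s.molar_volumes)
        return cls(x, grad, ct)


@dataclass(frozen=True)
class FluxVector:
    """Molar diffusive fluxes in the volume frame, mol/(m^2 s)."""

    J: np.ndarray

    def volume_flux_residual(self, s: SpeciesSet) -> float:
        """|sum_i V_i J_i| relative to the flux scale (exact closure is 0)."""
        vj = self.J * s.molar_volumes
        scale = np.max(np.abs(vj))
        return float(abs(vj.sum()) / scale) if scale > 0 else 0.0


def driving_forces(
    f: FaceState, p: ThermoParams, s: SpeciesSet, mode: str = "nonideal"
) -> np.ndarray:
    """Activity-based driving forces d_i = sum_j Gamma_ij dx_j/dz, 1/m.

    The antisolvent is the dependent species; its driving force follows from
    the zero-sum constraint.  Ideal mode uses Gamma = I so d_i is simply the
    mole-fraction gradient.
    """
    if mode == "ideal":
        return f.grad_x.copy()
    g = _gamma_matrix(f.x, p, s, dependent=2)
    d = np.empty(3)
    d[:2] = g @ f.grad_x[:2]
    d[2] = -d[0] - d[1]
    return d


def _velocity_system(
    x: np.ndarray, phi: np.ndarray, d: np.ndarray, D: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Square linear system A u = b for the species velocities."""
    present = x > X_FLOOR
    if present.sum() < 2:
        raise DegenerateFaceError("flux undefined with fewer than two species present")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    rows = []
    pres_idx = np.flatnonzero(present)
    for i in pres_idx[:-1]:  # n_present - 1 independent MS relations
        row = np.zeros(3)
        for j in range(3):
            if j == i:
                continue
            row[j] = x[i] * x[j] / D[i, j]
            row[i] -= x[i] * x[j] / D[i, j]
        rows.append((row, d[i]))
    rows.append((phi.copy(), 0.0))  # volume-frame closure sum phi_i u_i = 0
    for k in np.flatnonzero(~present):
        e = np.zeros(3)
        e[k] = 1.0
        rows.append((e, 0.0))  # absent species move with the frame
    for r, (row, rhs) in enumerate(rows):
        A[r] = row
        b[r] = rhs
    return A, b


def ms_flux_solve(
    f: FaceState, d: np.ndarray, dp: DiffusionParams, s: SpeciesSet
) -> FluxVector:
    """Invert the Maxwell–Stefan relations for the fluxes in the volume frame.

    Solves for the species velocities u_i under the volume-frame closure and
    returns J_i = c_t x_i u_i.  Exactly satisfies sum_i V_i J_i = 0.
    """
    x = f.x
    V = s.V
    phi = x * V / (x @ V)
    D = dp.pair_matrix(x)
    A, b = _velocity_system(x, phi, np.asarray(d, float), D)
    u = np.linalg.solve(A, b)
    return FluxVector(J=f.total_concentration * x * u)


def fick_ms_convert(
    x_binary: float,
    coefficient: float,
    pair: tuple[int, int],
    p: ThermoParams,
    s: SpeciesSet,
    direction: str = "fick_to_ms",
) -> float:
    """Convert between the binary Fick and Maxwell–Stefan diffusivities.

    On a binary edge the two are related by ``D_fick = D_ms * Gamma_b`` with
    ``Gamma_b = 1 + x d ln(gamma)/dx`` the scalar thermodynamic factor.
    ``x_binary`` is the mole fraction of ``pair[0]``; the third species is
    absent.  Inside a binary miscibility gap ``Gamma_b <= 0`` and the
    conversion is undefined.
    """
    i, j = pair
    if i == j or not {i, j} <= {0, 1, 2}:
        raise ValueError("pair must name two distinct species indices")
    if not 0.0 < x_binary < 1.0:
        raise ValueError("binary mole fraction must lie strictly inside (0, 1)")
    x = np.zeros(3)
    x[i] = x_binary
    x[j] = 1.0 - x_binary
    g = _gamma_matrix(x, p, s, dependent=j)
    idx = [k for k in range(3) if k != j]
    gamma_b = float(g[idx.index(i), idx.index(i)])
    if gamma_b <= 0.0:
        raise ValueError(
            f"thermodynamic factor {gamma_b:.4f} <= 0 inside the binary miscibility gap; "
            "Fick/Maxwell-Stefan conversion undefined"
        )
    if direction == "fick_to_ms":
        return float(coefficient / gamma_b)
    if direction == "ms_to_fick":
        return float(coefficient * gamma_b)
    raise ValueError("direction must be 'fick_to_ms' or 'ms_to_fick'")


# ---------------------------------------------------------------------------
# batched face transport matrices for the finite-volume solver
# ---------------------------------------------------------------------------

def _dx_dphi(x: np.ndarray, s: SpeciesSet, evolved: tuple[int, int]) -> np.ndarray:
    """d x_i / d phi_j for all i and evolved j, dependent = the third species.

    Shape ``(..., 3, 2)``; columns follow the order of ``evolved``.
    """
    V = s.V
    dep = ({0, 1, 2} - set(evolved)).pop()
    m = x[..., :] * V  # proportional to phi
    phi = m / m.sum(axis=-1, keepdims=True)
    r = phi / V
    ssum = r.sum(axis=-1)
    out = np.empty(x.shape[:-1] + (3, 2))
    for col, j in enumerate(evolved):
        for i in range(3):
            delta = (1.0 if i == j else 0.0) - (1.0 if i == dep else 0.0)
            out[..., i, col] = delta / (V[i] * ssum) - (r[..., i] / ssum) * (
                1.0 / V[j] - 1.0 / V[dep]
            ) / ssum
    return out


def velocity_responses(
    x_face: np.ndarray,
    p: ThermoParams,
    s: SpeciesSet,
    dp: DiffusionParams,
    evolved: tuple[int, int] = (0, 1),
) -> tuple[np.ndarray, np.ndarray]:
    """Species-velocity responses to unit volume-fraction gradients per face.

    For each face composition returns ``(U, phi)`` where ``U[f, i, j]`` is the
    velocity of evolved species ``evolved[i]`` under a unit gradient of
    ``phi_{evolved[j]}`` (the third species' fraction absorbing the simplex
    constraint), and ``phi`` are the physical volume fractions.  The actual
    volume flux is ``F_i = w_i * (U @ grad_phi)_i`` for a mobility weight
    ``w_i`` (the face volume fraction, or a donor-limited variant).  Faces with
    fewer than two species present get ``U = 0``.
    """
    x = np.asarray(x_face, float)
    n = x.shape[0]
    V = s.V
    phi = x * V / (x @ V)[:, None]
    if dp.mode == "ideal":
        gam = np.broadcast_to(np.eye(2), (n, 2, 2))
    else:
        gam = _gamma_matrix(x, p, s, dependent=2)
    T = _dx_dphi(x, s, evolved)

    D = dp.pair_matrix()
    present = x > X_FLOOR
    ok = present.sum(axis=1) >= 2

    # Maxwell-Stefan row for every species; n_present - 1 of them enter the
    # square system together with the closure and pins for absent species.
    ms_rows = np.zeros((n, 3, 3))
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            coef = x[:, i] * x[:, j] / D[i, j]
            ms_rows[:, i, j] += coef
            ms_rows[:, i, i] -= coef

    dvec = np.empty((n, 3, 2))  # driving forces per unit phi-gradient
    dvec[:, :2, :] = gam @ T[:, :2, :]
    dvec[:, 2, :] = -dvec[:, 0, :] - dvec[:, 1, :]

    U = np.zeros((n, 2, 2))
    idx_ok = np.flatnonzero(ok)
    if idx_ok.size == 0:
        return U, phi
    patt = present[:, 0] * 4 + present[:, 1] * 2 + present[:, 2] * 1
    for code in np.unique(patt[idx_ok]):
        sel = idx_ok[patt[idx_ok] == code]
        pres = [bool(code & 4), bool(code & 2), bool(code & 1)]
        pres_idx = [i for i in range(3) if pres[i]]
        Ag = np.zeros((sel.size, 3, 3))
        bg = np.zeros((sel.size, 3, 2))
        r = 0
        for i in pres_idx[:-1]:
            Ag[:, r, :] = ms_rows[sel, i, :]
            bg[:, r, :] = dvec[sel, i, :]
            r += 1
        Ag[:, r, :] = phi[sel]  # volume-frame closure
        r += 1
        for k in range(3):
            if not pres[k]:
                Ag[:, r, k] = 1.0  # absent species move with the frame
                r += 1
        u = np.linalg.solve(Ag, bg)  # (m, 3, 2)
        U[sel] = u[:, list(evolved), :]
    return U, phi


def flux_matrices(
    x_face: np.ndarray,
    p: ThermoParams,
    s: SpeciesSet,
    dp: DiffusionParams,
    evolved: tuple[int, int] = (0, 1),
) -> np.ndarray:
    """Effective 2x2 volume-flux diffusion matrices B per face.

    For each face composition, returns ``B`` such that the volume fluxes of
    the evolved species obey ``F_i = -sum_j B_ij d(phi_j)/dz`` with the third
    flux from the frame closure.  Uses the face volume fraction itself as the
    mobility weight (no donor limiting).  Shape: ``(n_faces, 2, 2)``.
    """
    U, phi = velocity_responses(x_face, p, s, dp, evolved)
    return -phi[:, list(evolved), None] * U
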