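"""Ternary phase diagram: solubility curve, spinodal region and binodal tie lines.

The solid–liquid boundary is the solute solubility curve, found by solving the
saturation condition ``ln(x_0 gamma_0) = solubility_constant`` along rays of
fixed solvent/antisolvent ratio.  Liquid–liquid demixing is bounded by the
spinodal (where the smaller eigenvalue of the thermodynamic factor crosses
zero) and by the binodal, constructed by equating the chemical potential of
every species in two coexisting phases and marching the resulting tie lines
from the solute/antisolvent binary edge toward the plait point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, fsolve
from shapely.geometry import Point, Polygon

from .species import Composition, SpeciesSet
from .thermo import (
    ThermoParams,
    _gamma_matrix,
    _min_eig_2x2,
    ln_activity_coefficients,
    stability_test,
    supersaturation_nonideal,
)

__all__ = [
    "SolubilityPoint",
    "TieLine",
    "PhaseRegions",
    "solubility_mole_fraction",
    "solubility_curve",
    "SolubilityTable",
    "supersaturation_ideal",
    "spinodal_boundary",
    "binodal_tielines",
    "classify_point",
    "phase_regions",
    "regions_to_frame",
]


@dataclass(frozen=True)
class SolubilityPoint:
    """Saturated composition at a fixed solute-free solvent ratio."""

    solvent_ethanol_mass_fraction: float
    x_sat: float
    mass_fraction_glycine: float
    composition: Composition


@dataclass(frozen=True)
class TieLine:
    """Pair of coexisting liquid phases with equal chemical potentials."""

    phase_a: Composition  # solute-lean phase
    phase_b: Composition  # solute-rich phase
    residual: float

    def midpoint(self) -> Composition:
        return Composition(0.5 * (self.phase_a.x + self.phase_b.x))


@dataclass
class PhaseRegions:
    """Sampled phase boundaries plus point-in-region tests."""

    solubility: list[SolubilityPoint]
    spinodal: np.ndarray  # (n, 3) mole fractions, possibly empty
    tielines: list[TieLine]
    plait_point_reached: bool = False
    _binodal_hull: Polygon | None = field(default=None, repr=False)

    def binodal_hull(self) -> Polygon | None:
        """Polygon (in x0, x1 coordinates) spanned by the tie lines."""
        if self._binodal_hull is None and self.tielines:
            a = np.array([t.phase_a.x[:2] for t in self.tielines])
            b = np.array([t.phase_b.x[:2] for t in self.tielines])
            ring = np.vstack([a, b[::-1]])
            self._binodal_hull = Polygon(ring).buffer(0)
        return self._binodal_hull

    def inside_binodal(self, c: Composition, tol: float = 0.0) -> bool:
        """Whether the point lies in the tie-line envelope.

        ``tol`` extends the envelope outward, absorbing the discretization of
        the continuation near the plait point where binodal and spinodal touch.
        """
        hull = self.binodal_hull()
        if hull is None:
            return False
        pt = Point(c.x[0], c.x[1])
        if hull.contains(pt):
            return True
        return tol > 0.0 and hull.exterior.distance(pt) < tol


# ---------------------------------------------------------------------------
# solubility
# ---------------------------------------------------------------------------

def _solvent_ray(ethanol_mass_fraction: float, s: SpeciesSet) -> tuple[float, float]:
    """Solute-free solvent mole fractions (water, ethanol) at given mass ratio."""
    w = float(ethanol_mass_fraction)
    if not 0.0 <= w <= 1.0:
        raise ValueError("ethanol mass fraction in solvent must lie in [0, 1]")
    ne = w / s.M[2]
    nw = (1.0 - w) / s.M[1]
    tot = ne + nw
    return nw / tot, ne / tot


def solubility_mole_fraction(
    ethanol_mass_fraction_in_solvent: float,
    p: ThermoParams,
    s: SpeciesSet,
    bracket: tuple[float, float] = (1e-10, 0.9),
) -> SolubilityPoint:
    """Saturated solute mole fraction along a fixed water:ethanol ray.

    Solves ``ln(x_0 gamma_0) = solubility_constant`` by bracketed root finding;
    the residual at the root is below 1e-10.
    """
    fw, fe = _solvent_ray(ethanol_mass_fraction_in_solvent, s)

    def residual(t: float) -> float:
        x = np.array([t, (1.0 - t) * fw, (1.0 - t) * fe])
        return float(np.log(t) + ln_activity_coefficients(x, p, s)[0] - p.solubility_constant)

    lo, hi = bracket
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        raise ValueError(
            "no saturation root in bracket; thermodynamic parameters look pathological"
        )
    t = brentq(residual, lo, hi, xtol=1e-15, rtol=8.9e-16)
    x = np.array([t, (1.0 - t) * fw, (1.0 - t) * fe])
    c = Composition(x)
    return SolubilityPoint(
        solvent_ethanol_mass_fraction=float(ethanol_mass_fraction_in_solvent),
        x_sat=float(t),
        mass_fraction_glycine=float(c.mass_fractions(s)[0]),
        composition=c,
    )


def solubility_curve(
    p: ThermoParams, s: SpeciesSet, n_points: int = 41
) -> list[SolubilityPoint]:
    grid = np.linspace(0.0, 1.0, n_points)
    return [solubility_mole_fraction(w, p, s) for w in grid]


class SolubilityTable:
    """Monotone interpolant of ``x_sat`` versus solvent ethanol mass fraction.

    The simulator evaluates the concentration-ratio supersaturation in every
    cell at every output time; interpolating a densely pre-solved curve keeps
    that evaluation vectorized.  With 201 nodes the interpolation error is
    far below the transport discretization error.
    """

    def __init__(self, p: ThermoParams, s: SpeciesSet, n_points: int = 201) -> None:
        self.grid = np.linspace(0.0, 1.0, n_points)
        self.values = np.array(
            [solubility_mole_fraction(w, p, s).x_sat for w in self.grid]
        )
        self._interp = PchipInterpolator(self.grid, self.values, extrapolate=False)

    def __call__(self, ethanol_mass_fraction: np.ndarray) -> np.ndarray:
        w = np.clip(np.asarray(ethanol_mass_fraction, float), 0.0, 1.0)
        return self._interp(w)


def supersaturation_ideal(
    c: Composition,
    p: ThermoParams,
    s: SpeciesSet,
    table: SolubilityTable | None = None,
) -> float:
    """Concentration-ratio supersaturation ``x_0 / x_sat`` at the local solvent ratio.

    The reference solubility is the activity model's own saturation value at
    the cell's water:ethanol mass ratio, so both supersaturation definitions
    agree (value 1) on the solubility curve, while away from it this one
    ignores the activity coefficient.
    """
    if c.x[0] == 0.0:
        return 0.0
    w = c.solvent_ethanol_mass_fraction(s)
    xsat = float(table(w)) if table is not None else solubility_mole_fraction(w, p, s).x_sat
    return float(c.x[0] / xsat)


# ---------------------------------------------------------------------------
# spinodal
# ---------------------------------------------------------------------------

def _min_eig_at(pts: np.ndarray, p: ThermoParams, s: SpeciesSet) -> np.ndarray:
    return _min_eig_2x2(_gamma_matrix(pts, p, s))


def spinodal_boundary(
    p: ThermoParams,
    s: SpeciesSet,
    resolution: int = 120,
    refine_tol: float = 1e-6,
) -> np.ndarray:
    """Zero contour of the smaller Gamma eigenvalue on the composition simplex.

    Scans a barycentric grid, then bisects every grid edge whose endpoints
    disagree in sign until ``|min eig| < refine_tol``.  Returns an ``(n, 3)``
    array of mole fractions; empty for models without a miscibility gap.
    """
    if resolution < 50:
        raise ValueError("resolution must be at least 50")
    eps = 1e-9
    ts = np.linspace(eps, 1.0 - eps, resolution)
    pts = []
    pairs = []
    # grid nodes (x0, x2) with x1 = 1 - x0 - x2
    nodes = {}
    for i, x0 in enumerate(ts):
        for j, x2 in enumerate(ts):
            if x0 + x2 >= 1.0 - eps:
                continue
            nodes[(i, j)] = len(pts)
            pts.append([x0, 1.0 - x0 - x2, x2])
    pts = np.array(pts)
    if len(pts) == 0:
        return np.empty((0, 3))
    vals = _min_eig_at(pts, p, s)
    for (i, j), a in nodes.items():
        for di, dj in ((1, 0), (0, 1)):
            b = nodes.get((i + di, j + dj))
            if b is not None and vals[a] * vals[b] < 0:
                pairs.append((a, b))
    if not pairs:
        return np.empty((0, 3))

    lo = pts[[a for a, _ in pairs]]
    hi = pts[[b for _, b in pairs]]
    flo = vals[[a for a, _ in pairs]]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = _min_eig_at(mid, p, s)
        if np.max(np.abs(fm)) < refine_tol:
            lo = hi = mid
            break
        take_lo = flo * fm < 0
        hi = np.where(take_lo[:, None], mid, hi)
        lo = np.where(take_lo[:, None], lo, mid)
        flo = np.where(take_lo, flo, fm)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# binodal
# ---------------------------------------------------------------------------

def _binary_demix(p: ThermoParams, s: SpeciesSet) -> tuple[float, float] | None:
    """Coexisting solute mole fractions on the solute/antisolvent edge, or None."""
    ts = np.linspace(1e-6, 1 - 1e-6, 400)
    edge = np.stack([ts, np.zeros_like(ts), 1.0 - ts], axis=-1)
    gb = 1.0 + ts * np.gradient(ln_activity_coefficients(edge, p, s)[:, 0], ts)
    if not np.any(gb < 0):
        return None

    def mu(t: float) -> np.ndarray:
        x = np.array([t, 0.0, 1.0 - t])
        lng = ln_activity_coefficients(x, p, s)
        return np.array([np.log(t) + lng[0], np.log(1.0 - t) + lng[2]])

    lo = ts[np.argmax(gb < 0)]  # first unstable point
    hi = ts[len(ts) - 1 - np.argmax(gb[::-1] < 0)]

    def expit(z):
        return 1.0 / (1.0 + np.exp(-z))

    def eqs(z):
        # logit variables keep both phases strictly inside (0, 1)
        ta, tb = expit(z[0]), expit(z[1])
        return mu(ta) - mu(tb)

    z0 = [np.log(0.5 * lo / (1 - 0.5 * lo)), np.log(0.5 * (1 + hi) / (1 - 0.5 * (1 + hi)))]
    sol, info, ok, _ = fsolve(eqs, x0=z0, full_output=True, xtol=1e-14)
    ta, tb = sorted(expit(sol))
    if ok != 1 or tb - ta < 1e-6:
        return None
    return float(ta), float(tb)


def binodal_tielines(
    p: ThermoParams,
    s: SpeciesSet,
    n_lines: int = 40,
    step: float = 0.01,
) -> tuple[list[TieLine], str]:
    """Tie lines of the liquid–liquid region, marched from the binary edge.

    Continuation in the solvent content of the solute-lean phase with step
    halving on failure.  Returns the lines found plus a status string:
    ``"ok"``, ``"no demixing"`` or ``"plait point"`` when continuation stalls
    because the two phases merge.
    """
    binary = _binary_demix(p, s)
    if binary is None:
        return [], "no demixing"
    ta, tb = binary
    lines: list[TieLine] = []

    def mu_all(x: np.ndarray) -> np.ndarray:
        return np.log(np.maximum(x, 1e-300)) + ln_activity_coefficients(x, p, s)

    # first tie line: binary edge (water chemical potential -inf on both sides;
    # equality holds in the x1 -> 0 limit and is recorded with the edge values)
    a = Composition(np.array([ta, 0.0, 1.0 - ta]))
    b = Composition(np.array([tb, 0.0, 1.0 - tb]))
    res = float(np.max(np.abs((mu_all(a.x) - mu_all(b.x))[[0, 2]])))
    lines.append(TieLine(a, b, res))

    x1a = 0.0
    guess = np.array([ta, tb, 1e-4])  # x0a, x0b, x1b
    status = "ok"
    h = step
    while len(lines) < n_lines:
        advanced = False
        while h > 1e-6:
            x1a_new = x1a + h

            def eqs(z):
                x0a, x0b, x1b = z
                xa = np.array([x0a, x1a_new, 1.0 - x0a - x1a_new])
                xb = np.array([x0b, x1b, 1.0 - x0b - x1b])
                if np.any(xa <= 0) or np.any(xb <= 0):
                    return np.full(3, 1e3)
                return mu_all(xa) - mu_all(xb)

            sol, info, ok, _ = fsolve(eqs, x0=guess, full_output=True, xtol=1e-13)
            sep = abs(sol[0] - sol[1]) + abs(x1a_new - sol[2])
            if ok == 1 and sep > 5e-3:
                x1a = x1a_new
                guess = sol
                xa = np.array([sol[0], x1a, 1.0 - sol[0] - x1a])
                xb = np.array([sol[1], sol[2], 1.0 - sol[1] - sol[2]])
                res = float(np.max(np.abs(mu_all(xa) - mu_all(xb))))
                lines.append(TieLine(Composition(xa), Composition(xb), res))
                advanced = True
                break
            h *= 0.5
        if not advanced:
            status = "plait point"
            break
        if h < step:
            h = min(step, h * 2)
    return lines, status


def phase_regions(
    p: ThermoParams,
    s: SpeciesSet,
    resolution: int = 120,
    n_lines: int = 150,
    n_solubility: int = 41,
) -> PhaseRegions:
    lines, status = binodal_tielines(p, s, n_lines=n_lines)
    return PhaseRegions(
        solubility=solubility_curve(p, s, n_solubility),
        spinodal=spinodal_boundary(p, s, resolution=resolution),
        tielines=lines,
        plait_point_reached=(status == "plait point"),
    )


def classify_point(
    c: Composition,
    regions: PhaseRegions,
    p: ThermoParams,
    s: SpeciesSet,
) -> tuple[str, str]:
    """Liquid-phase and solid-phase status of a composition.

    Returns ``(liquid, solid)`` with liquid in {stable, metastable, unstable}
    (metastable = locally stable but inside the binodal envelope) and solid in
    {undersaturated, supersaturated} from the activity-based supersaturation.
    """
    stable, _ = stability_test(c, p, s)
    if not stable:
        liquid = "unstable"
    elif regions.inside_binodal(c):
        liquid = "metastable"
    else:
        liquid = "stable"
    solid = "supersaturated" if supersaturation_nonideal(c, p, s) > 1.0 else "undersaturated"
    return liquid, solid


def regions_to_frame(regions: PhaseRegions, s: SpeciesSet) -> pd.DataFrame:
    """Flatten sampled boundaries to a table in mass-fraction coordinates."""
    rows = []
    for pt in regions.solubility:
        w = pt.composition.mass_fractions(s)
        rows.append(("solubility", *pt.composition.x, *w))
    for x in regions.spinodal:
        w = Composition(x).mass_fractions(s)
        rows.append(("spinodal", *x, *w))
    for t in regions.tielines:
        for label, ph in (("binodal_a", t.phase_a), ("binodal_b", t.phase_b)):
            rows.append((label, *ph.x, *ph.mass_fractions(s)))
    cols = ["region"] + [f"x_{n}" for n in s.names] + [f"w_{n}" for n in s.names]
    return pd.DataFrame(rows, columns=cols)
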