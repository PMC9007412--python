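"""Least-squares calibration of the activity model from solubility and binary
activity-coefficient tables, with a seeded synthetic-data generator.

The solute/antisolvent interaction and the solubility constant are fitted to
solute solubility across solvent compositions; pair interactions and effective
volume ratios are fitted to binary activity-coefficient curves (as derived
from VLE or vapor-pressure experiments).  The generator produces noisy tables
from known parameters so that recovery can be tested without external data:
noiseless tables must be fitted back to the generating parameters to
numerical precision.

Losses are taken on the logarithm of solubility — the antisolvent-rich branch
spans orders of magnitude and is exactly where measurements are hardest — and
on ln(gamma) for activity tables.  Optimization is bounded with a small
multi-start to avoid local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .phase_diagram import solubility_mole_fraction
from .species import SpeciesSet
from .thermo import ThermoParams, ln_activity_coefficients

__all__ = [
    "SolubilityTable",
    "ActivityTable",
    "FitResult",
    "synth_solubility_table",
    "synth_activity_table",
    "fit_solubility_params",
    "fit_binary_activity",
]

_PAIR_TO_CHI = {(0, 1): "chi01", (0, 2): "chi02", (1, 2): "chi12"}

BOUNDS = {
    "chi01": (0.0, 10.0),
    "chi02": (0.0, 10.0),
    "chi12": (0.0, 10.0),
    "solubility_constant": (-10.0, 0.0),
    "v0": (0.1, 10.0),
    "v2": (0.1, 10.0),
}


@dataclass(frozen=True)
class SolubilityTable:
    """Rows of (solvent ethanol mass fraction, solute mass fraction of solution)."""

    solvent_ethanol_mass_fraction: np.ndarray
    solubility_mass_fraction: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        w = np.asarray(self.solvent_ethanol_mass_fraction, float)
        y = np.asarray(self.solubility_mass_fraction, float)
        if w.shape != y.shape or w.ndim != 1:
            raise ValueError("table columns must be 1-D and equal length")
        if np.any((w < 0) | (w > 1)) or np.any((y <= 0) | (y >= 1)):
            raise ValueError("fractions out of range")
        object.__setattr__(self, "solvent_ethanol_mass_fraction", w)
        object.__setattr__(self, "solubility_mass_fraction", y)

    def __len__(self) -> int:
        return self.solvent_ethanol_mass_fraction.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "solvent_ethanol_mass_fraction": self.solvent_ethanol_mass_fraction,
                "solubility_mass_fraction": self.solubility_mass_fraction,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "csv") -> "SolubilityTable":
        return cls(
            df["solvent_ethanol_mass_fraction"].to_numpy(),
            df["solubility_mass_fraction"].to_numpy(),
            provenance,
        )


@dataclass(frozen=True)
class ActivityTable:
    """Rows of (mole fraction of pair[0], activity coefficient of ``species``)
    on a binary edge; the remaining species is absent."""

    pair: tuple[int, int]
    species: int
    mole_fraction: np.ndarray
    activity_coefficient: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        x = np.asarray(self.mole_fraction, float)
        g = np.asarray(self.activity_coefficient, float)
        if self.species not in self.pair:
            raise ValueError("table species must belong to the named pair")
        if x.shape != g.shape or x.ndim != 1:
            raise ValueError("table columns must be 1-D and equal length")
        if np.any((x <= 0) | (x >= 1)) or np.any(g <= 0):
            raise ValueError("mole fractions must be in (0,1) and gamma > 0")
        object.__setattr__(self, "mole_fraction", x)
        object.__setattr__(self, "activity_coefficient", g)

    def __len__(self) -> int:
        return self.mole_fraction.size

    def compositions(self) -> np.ndarray:
        i, j = self.pair
        x = np.zeros((len(self), 3))
        x[:, i] = self.mole_fraction
        x[:, j] = 1.0 - self.mole_fraction
        return x


@dataclass(frozen=True)
class FitResult:
    names: tuple[str, ...]
    values: np.ndarray
    residual_norm: float
    converged: bool
    params: ThermoParams
    species: SpeciesSet


def _apply(names, values, p: ThermoParams, s: SpeciesSet) -> tuple[ThermoParams, SpeciesSet]:
    chi = p.chi.copy()
    const = p.solubility_constant
    v = list(s.thermo_volume_ratios)
    for name, val in zip(names, values):
        if name.startswith("chi"):
            i, j = int(name[3]), int(name[4])
            chi[i, j] = chi[j, i] = val
        elif name == "solubility_constant":
            const = val
        elif name == "v0":
            v[0] = val
        elif name == "v2":
            v[2] = val
        else:
            raise ValueError(f"unknown fit parameter {name!r}")
    return (
        ThermoParams(chi=chi, solubility_constant=const, temperature=p.temperature),
        replace(s, thermo_volume_ratios=tuple(v)),
    )


def synth_solubility_table(
    true_params: ThermoParams,
    s: SpeciesSet,
    n_points: int = 25,
    noise_rel: float = 0.0,
    seed: int = 0,
    w_range: tuple[float, float] = (0.0, 0.9),
) -> SolubilityTable:
    """Noisy solubility table generated from the model itself.

    Evaluates the saturation curve on an even grid of solvent ratios and
    applies multiplicative lognormal noise of relative scale ``noise_rel``.
    Deterministic for a fixed seed.
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    if noise_rel < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    ws = np.linspace(*w_range, n_points)
    y = np.array(
        [solubility_mole_fraction(w, true_params, s).mass_fraction_glycine for w in ws]
    )
    if noise_rel > 0:
        y = y * rng.lognormal(mean=0.0, sigma=noise_rel, size=n_points)
    return SolubilityTable(ws, y, provenance=f"synthetic(seed={seed}, noise={noise_rel})")


def synth_activity_table(
    true_params: ThermoParams,
    s: SpeciesSet,
    pair: tuple[int, int] = (2, 1),
    species: int = 2,
    n_points: int = 25,
    noise_rel: float = 0.0,
    seed: int = 0,
    x_range: tuple[float, float] = (0.02, 0.98),
) -> ActivityTable:
    """Noisy binary activity-coefficient table from the model itself."""
    if n_points < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    xs = np.linspace(*x_range, n_points)
    i, j = pair
    comp = np.zeros((n_points, 3))
    comp[:, i] = xs
    comp[:, j] = 1.0 - xs
    g = np.exp(ln_activity_coefficients(comp, true_params, s)[:, species])
    if noise_rel > 0:
        g = g * rng.lognormal(mean=0.0, sigma=noise_rel, size=n_points)
    return ActivityTable(
        pair, species, xs, g, provenance=f"synthetic(seed={seed}, noise={noise_rel})"
    )


def _multistart_lsq(residual, names, seed: int = 0, n_starts: int = 3):
    lo = np.array([BOUNDS[n][0] for n in names])
    hi = np.array([BOUNDS[n][1] for n in names])
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        if k == 0:
            x0 = 0.5 * (lo + hi)
        else:
            x0 = lo + rng.random(len(names)) * (hi - lo)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")
    return best


def fit_solubility_params(
    table: SolubilityTable,
    free: tuple[str, ...] = ("chi02", "solubility_constant"),
    fixed: ThermoParams | None = None,
    s: SpeciesSet | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit interaction/solubility parameters to a solubility table.

    Minimizes squared residuals of log solubility (solution mass fraction).
    The table must span a solvent-ratio range of at least 0.3 for the default
    parameter pair to be identifiable.
    """
    if len(table) < 4:
        raise ValueError("at least 4 rows required for fitting")
    w = table.solvent_ethanol_mass_fraction
    if w.max() - w.min() < 0.3:
        raise ValueError("table spans too narrow a solvent-ratio range (< 0.3)")
    p0 = fixed if fixed is not None else ThermoParams.glycine_water_ethanol()
    s0 = s if s is not None else SpeciesSet()
    logy = np.log(table.solubility_mass_fraction)

    def residual(theta):
        p, sp = _apply(free, theta, p0, s0)
        try:
            pred = np.array(
                [solubility_mole_fraction(wi, p, sp).mass_fraction_glycine for wi in w]
            )
        except ValueError:
            return np.full(len(table), 1e3)
        return np.log(pred) - logy

    sol = _multistart_lsq(residual, free, seed=seed)
    p_fit, s_fit = _apply(free, sol.x, p0, s0)
    return FitResult(
        names=tuple(free),
        values=sol.x,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        params=p_fit,
        species=s_fit,
    )


def fit_binary_activity(
    table: ActivityTable,
    free: tuple[str, ...] | None = None,
    fixed: ThermoParams | None = None,
    s: SpeciesSet | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit a pair interaction and an effective volume ratio to ln(gamma) data.

    Defaults to the interaction parameter of the table's pair plus the
    non-solvent species' effective volume (``v2`` for the solvent/antisolvent
    edge, ``v0`` for the solute/solvent edge).
    """
    if len(table) < 4:
        raise ValueError("at least 4 rows required for fitting")
    pair = tuple(sorted(table.pair))
    if pair not in _PAIR_TO_CHI:
        raise ValueError(f"unsupported binary edge {table.pair}")
    if free is None:
        chi_name = _PAIR_TO_CHI[pair]
        vol = "v0" if 0 in pair else "v2"
        free = (chi_name, vol)
    else:
        chi_names = [n for n in free if n.startswith("chi")]
        for n in chi_names:
            if tuple(sorted((int(n[3]), int(n[4])))) != pair:
                raise ValueError(
                    f"free parameter {n} does not act on the table's edge {table.pair}"
                )
    p0 = fixed if fixed is not None else ThermoParams.glycine_water_ethanol()
    s0 = s if s is not None else SpeciesSet()
    comp = table.compositions()
    lng_obs = np.log(table.activity_coefficient)

    def residual(theta):
        p, sp = _apply(free, theta, p0, s0)
        return ln_activity_coefficients(comp, p, sp)[:, table.species] - lng_obs

    sol = _multistart_lsq(residual, free, seed=seed)
    p_fit, s_fit = _apply(free, sol.x, p0, s0)
    return FitResult(
        names=tuple(free),
        values=sol.x,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        params=p_fit,
        species=s_fit,
    )
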