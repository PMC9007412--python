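"""Species metadata and composition handling for ternary solute/solvent/antisolvent systems.

The package fixes the species ordering convention (0 = solute, 1 = solvent,
2 = antisolvent) and carries two distinct sets of per-species volumes:

* ``thermo_volume_ratios`` — the *effective* molar volumes ``v_i/v_ref`` of the
  activity model.  These are fitting parameters of the free-energy model, with
  the solvent as reference (``v_1/v_ref = 1``).
* ``physical_volume_ratios`` — the pure-component molar volumes ``V_i/V_1``
  that define the volume reference frame of the transport model (the space a
  molecule actually occupies).

The two coincide only by accident; for glycine/water/ethanol the effective
ethanol volume fitted to activity data (1.50) differs markedly from its
physical molar-volume ratio (3.23).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpeciesSet", "Composition", "GLYCINE_WATER_ETHANOL"]

#: pure-water molar volume at 25 C, m^3/mol (18.015 g/mol / 0.99705 g/cm^3)
WATER_MOLAR_VOLUME = 18.015e-6 / 0.99705

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered ternary species set: (solute, solvent, antisolvent)."""

    names: tuple[str, str, str] = ("glycine", "water", "ethanol")
    molar_masses: tuple[float, float, float] = (75.07, 18.015, 46.07)
    thermo_volume_ratios: tuple[float, float, float] = (3.58, 1.0, 1.50)
    physical_volume_ratios: tuple[float, float, float] = (3.58, 1.0, 3.23)
    solvent_molar_volume: float = WATER_MOLAR_VOLUME

    def __post_init__(self) -> None:
        for attr in ("molar_masses", "thermo_volume_ratios", "physical_volume_ratios"):
            vals = getattr(self, attr)
            if len(vals) != 3 or any(v <= 0 for v in vals):
                raise ValueError(f"{attr} must be three strictly positive values")
        if abs(self.thermo_volume_ratios[1] - 1.0) > 1e-12:
            raise ValueError("solvent thermo volume ratio v_1/v_ref must equal 1")
        if abs(self.physical_volume_ratios[1] - 1.0) > 1e-12:
            raise ValueError("solvent physical volume ratio V_1/V_1 must equal 1")

    @property
    def M(self) -> np.ndarray:
        """Molar masses as an array, g/mol."""
        return np.asarray(self.molar_masses, dtype=float)

    @property
    def v(self) -> np.ndarray:
        """Effective (thermodynamic) volume ratios v_i/v_ref."""
        return np.asarray(self.thermo_volume_ratios, dtype=float)

    @property
    def V(self) -> np.ndarray:
        """Physical volume ratios V_i/V_1."""
        return np.asarray(self.physical_volume_ratios, dtype=float)

    @property
    def molar_volumes(self) -> np.ndarray:
        """Absolute pure-component molar volumes, m^3/mol."""
        return self.V * self.solvent_molar_volume

    def ideal(self) -> "SpeciesSet":
        """Variant with all effective volumes equal (entropically ideal model)."""
        return SpeciesSet(
            names=self.names,
            molar_masses=self.molar_masses,
            thermo_volume_ratios=(1.0, 1.0, 1.0),
            physical_volume_ratios=self.physical_volume_ratios,
            solvent_molar_volume=self.solvent_molar_volume,
        )


GLYCINE_WATER_ETHANOL = SpeciesSet()


def _normalize_or_check(x: np.ndarray, normalize: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise ValueError("composition requires exactly three fractions")
    if np.any(x < -_SUM_TOL):
        raise ValueError(f"negative fraction in composition: {x}")
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if normalize:
        if total <= 0:
            raise ValueError("composition fractions sum to zero")
        return x / total
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"fractions must sum to 1 within {_SUM_TOL}; got {total!r}")
    return x / total


@dataclass(frozen=True)
class Composition:
    """A point in the ternary composition simplex, stored as mole fractions."""

    mole_fractions: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mole_fractions", _normalize_or_check(self.mole_fractions, normalize=False)
        )

    @property
    def x(self) -> np.ndarray:
        return self.mole_fractions

    # -- constructors on alternative bases ---------------------------------
    @classmethod
    def from_mole_fractions(cls, x, normalize: bool = False) -> "Composition":
        return cls(_normalize_or_check(np.asarray(x, float), normalize))

    @classmethod
    def from_mass_fractions(cls, w, s: SpeciesSet, normalize: bool = False) -> "Composition":
        w = _normalize_or_check(np.asarray(w, float), normalize)
        return cls(_normalize_or_check(w / s.M, normalize=True))

    @classmethod
    def from_physical_volume_fractions(
        cls, phi, s: SpeciesSet, normalize: bool = False
    ) -> "Composition":
        phi = _normalize_or_check(np.asarray(phi, float), normalize)
        return cls(_normalize_or_check(phi / s.V, normalize=True))

    # -- conversions -------------------------------------------------------
    def mass_fractions(self, s: SpeciesSet) -> np.ndarray:
        m = self.x * s.M
        return m / m.sum()

    def thermo_volume_fractions(self, s: SpeciesSet) -> np.ndarray:
        """phi_i = x_i v_i / sum_j x_j v_j with the *effective* volumes."""
        q = self.x * s.v
        return q / q.sum()

    def physical_volume_fractions(self, s: SpeciesSet) -> np.ndarray:
        """phi_i = x_i V_i / sum_j x_j V_j with the *physical* volumes."""
        q = self.x * s.V
        return q / q.sum()

    def solvent_ethanol_mass_fraction(self, s: SpeciesSet) -> float:
        """Antisolvent mass over solute-free (solvent + antisolvent) mass."""
        m = self.x * s.M
        denom = m[1] + m[2]
        if denom <= 0:
            raise ValueError("no solvent/antisolvent present; solvent ratio undefined")
        return float(m[2] / denom)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        x = self.x
        return f"Composition(x=[{x[0]:.6g}, {x[1]:.6g}, {x[2]:.6g}])"
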