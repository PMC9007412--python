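"""Solubility and the two supersaturation measures.

Builds the fitted glycine/water/ethanol activity model, solves the saturation
condition in pure water, and evaluates both the concentration-ratio (ideal)
and activity-ratio (nonideal) supersaturation of a typical starting solution.
"""

import numpy as np

from msmix import (
    Composition,
    SpeciesSet,
    ThermoParams,
    activity_coefficients,
    solubility_mole_fraction,
    supersaturation_ideal,
    supersaturation_nonideal,
)

species = SpeciesSet()
params = ThermoParams.glycine_water_ethanol()

sat = solubility_mole_fraction(0.0, params, species)
print(f"glycine solubility in pure water: x_sat = {sat.x_sat:.4f} "
      f"({sat.mass_fraction_glycine:.3f} mass fraction)")

# an aqueous solution at 85% of saturation (concentration ratio)
x0 = 0.85 * sat.x_sat
solution = Composition(np.array([x0, 1.0 - x0, 0.0]))
gamma = activity_coefficients(solution, params, species)
print(f"solution x_glycine = {x0:.4f}, gamma_glycine = {gamma[0]:.3f}")
print(f"ideal    supersaturation S = {supersaturation_ideal(solution, params, species):.3f}")
print(f"nonideal supersaturation S = {supersaturation_nonideal(solution, params, species):.3f}")
print("The activity-based value is higher because glycine's activity "
      "coefficient exceeds 1 even in water; S = 1 would mean saturation.")

# solubility collapses as the solvent turns into ethanol
for w in (0.0, 0.5, 0.8, 1.0):
    pt = solubility_mole_fraction(w, params, species)
    print(f"  ethanol mass fraction in solvent {w:.1f} -> x_sat = {pt.x_sat:.5f}")
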