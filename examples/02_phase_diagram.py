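"""Ternary phase diagram: solubility curve, spinodal region and tie lines.

Samples all three boundaries and classifies a few representative points.
The spinodal (spontaneous demixing) sits strictly inside the binodal
(liquid-liquid coexistence); the whole two-phase region is supersaturated
with respect to crystalline glycine.
"""

from msmix import Composition, SpeciesSet, ThermoParams, classify_point, phase_regions
from msmix.phase_diagram import regions_to_frame

species = SpeciesSet()
params = ThermoParams.glycine_water_ethanol()

regions = phase_regions(params, species, resolution=100, n_lines=150)
print(f"solubility curve: {len(regions.solubility)} samples")
print(f"spinodal contour: {len(regions.spinodal)} samples")
print(f"tie lines: {len(regions.tielines)} "
      f"(plait point reached: {regions.plait_point_reached})")
last = regions.tielines[-1]
print(f"near-plait tie line: a = {last.phase_a.x.round(4)}  b = {last.phase_b.x.round(4)}")

for label, x in [
    ("pure water", [0.0, 1.0, 0.0]),
    ("aqueous solution", [0.0655, 0.9345, 0.0]),
    ("glycine/ethanol-rich", [0.3, 0.05, 0.65]),
]:
    liquid, solid = classify_point(Composition(x), regions, params, species)
    print(f"  {label:22s}: {liquid}, {solid}")

df = regions_to_frame(regions, species)
df.to_csv("phase_diagram.csv", index=False)
print(f"wrote phase_diagram.csv with {len(df)} rows "
      "(mole- and mass-fraction coordinates per region)")
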