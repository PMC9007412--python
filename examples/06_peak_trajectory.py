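"""Where in composition space does the supersaturation peak travel?

Traces the per-second composition of the supersaturation maximum for both
transport modes.  The Fickian peak rides deep into ethanol-rich territory;
the Maxwell-Stefan peak stays water-rich because glycine refuses to enter
the antisolvent until the solvents have intermixed.
"""

from msmix import (
    ChannelConfig,
    DiffusionParams,
    InitialCondition,
    SpeciesSet,
    ThermoParams,
    antisolvent_from_wt_percent,
    peak_trajectory,
    run,
    solution_from_ideal_supersaturation,
)

species = SpeciesSet()
params = ThermoParams.glycine_water_ethanol()
ic = InitialCondition(
    solution_side=solution_from_ideal_supersaturation(0.85, params, species),
    antisolvent_side=antisolvent_from_wt_percent(80.0, species),
    fill_ratio=1.0,
)
cc = ChannelConfig(n_cells=128, dt=0.1, dt_output=1.0, t_end=120.0)

for mode in ("ideal", "nonideal"):
    res = run(ic, cc, params, DiffusionParams(mode=mode), species)
    traj = peak_trajectory(res, species, which=mode)
    w = traj.mass_fractions
    print(f"{mode} peak (mass fractions glycine/water/ethanol, S):")
    for t in (1, 10, 60, 120):
        i = int(t)
        print(f"  t = {t:4d} s: {w[i].round(3)}  S = {traj.S_values[i]:.2f}")
    traj.to_frame(species).to_csv(f"trajectory_{mode}.csv", index=False)
print("CSV trajectories written; columns are barycentric mass fractions for "
      "plotting on a ternary diagram.")
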