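"""Ideal (Fickian) versus thermodynamically consistent diffusive mixing.

A 1 mm channel holds an aqueous glycine solution on the left and an
80 wt% ethanol antisolvent on the right (equal volumes).  Both transport
modes are run at reduced resolution; the ideal model overshoots the fully
mixed supersaturation severalfold, the Maxwell-Stefan model barely at all.
"""

from msmix import (
    ChannelConfig,
    DiffusionParams,
    InitialCondition,
    SpeciesSet,
    ThermoParams,
    antisolvent_from_wt_percent,
    overshoot_metric,
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
cc = ChannelConfig(n_cells=128, dt=0.1, dt_output=1.0, t_end=3000.0, stop_when_relaxed=True)

for mode in ("ideal", "nonideal"):
    res = run(ic, cc, params, DiffusionParams(mode=mode), species)
    which = mode
    s_mixed = res.fully_mixed.S_ideal if mode == "ideal" else res.fully_mixed.S_nonideal
    print(f"{mode:8s}: S_mixed = {s_mixed:.3f}, "
          f"overshoot metric = {overshoot_metric(res, which):.3f}, "
          f"relaxation time = {res.relaxation_time:.1f} s")
print("overshoot metric = (max S anywhere, any time) / (S of the fully mixed state);")
print("values well above 1 are the Fickian artifact; the consistent model stays near 1,")
print("and its composition profiles take several times longer to flatten.")
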