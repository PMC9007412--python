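"""Shared fixtures.

The expensive channel simulations (ideal/nonideal contrast, diffusivity-cube
sweep, spinodal-halt scenario) are session-scoped and reused by the unit,
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from msmix.analysis import sweep_diffusivity_cube
from msmix.msdiffusion import DiffusionParams
from msmix.phase_diagram import phase_regions
from msmix.simulate import (
    ChannelConfig,
    InitialCondition,
    _FieldEvaluator,
    antisolvent_from_wt_percent,
    run,
    solution_from_ideal_supersaturation,
)
from msmix.species import SpeciesSet
from msmix.thermo import ThermoParams


@pytest.fixture(scope="session")
def species() -> SpeciesSet:
    return SpeciesSet()


@pytest.fixture(scope="session")
def params() -> ThermoParams:
    return ThermoParams.glycine_water_ethanol()


@pytest.fixture(scope="session")
def ideal_species() -> SpeciesSet:
    """All volumes equal: the entropically and energetically ideal reference."""
    return SpeciesSet(
        thermo_volume_ratios=(1.0, 1.0, 1.0), physical_volume_ratios=(1.0, 1.0, 1.0)
    )


@pytest.fixture(scope="session")
def ideal_params() -> ThermoParams:
    return ThermoParams.ideal()


@pytest.fixture(scope="session")
def evaluator(params, species) -> _FieldEvaluator:
    return _FieldEvaluator(params, species)


@pytest.fixture(scope="session")
def regions(params, species):
    return phase_regions(params, species, resolution=80, n_lines=150)


@pytest.fixture(scope="session")
def baseline_ic(params, species) -> InitialCondition:
    """Aqueous solution at concentration-ratio supersaturation 0.85 against an
    80 wt% ethanol antisolvent, equal volumes of each (interface mid-channel)."""
    return InitialCondition(
        solution_side=solution_from_ideal_supersaturation(0.85, params, species),
        antisolvent_side=antisolvent_from_wt_percent(80.0, species),
        fill_ratio=1.0,
    )


@pytest.fixture(scope="session")
def contrast_runs(baseline_ic, params, species, evaluator):
    """Ideal- and nonideal-mode baseline runs at 256 cells, to relaxation."""
    cc = ChannelConfig(
        n_cells=256, dt=0.1, dt_output=1.0, t_end=4000.0, stop_when_relaxed=True
    )
    out = {}
    for mode in ("ideal", "nonideal"):
        dp = DiffusionParams(mode=mode)
        out[mode] = run(baseline_ic, cc, params, dp, species, evaluator=evaluator)
    return out


@pytest.fixture(scope="session")
def llps_run(params, species, evaluator):
    """7:3 antisolvent:solution scenario that meets the spinodal and halts."""
    ic = InitialCondition(
        solution_side=solution_from_ideal_supersaturation(0.85, params, species),
        antisolvent_side=antisolvent_from_wt_percent(80.0, species),
        fill_ratio=7.0 / 3.0,
    )
    cc = ChannelConfig(
        n_cells=256, dt=0.1, dt_output=0.1, t_end=2000.0, halt_on_spinodal=True
    )
    return run(ic, cc, params, DiffusionParams(mode="nonideal"), species, evaluator=evaluator)


@pytest.fixture(scope="session")
def ideal_sweep(baseline_ic, params, species, evaluator):
    cc = ChannelConfig(n_cells=256, dt=0.1, dt_output=1.0, t_end=500.0)
    return sweep_diffusivity_cube(
        baseline_ic, cc, params, species, mode="ideal", evaluator=evaluator
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
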