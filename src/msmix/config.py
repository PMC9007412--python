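"""Declarative run configuration: YAML parsing, validation and output writing.

A run is described by a flat YAML document with optional blocks ``species``,
``thermo``, ``diffusion``, ``channel``, ``initial`` and ``output``; omitted
keys fall back to the glycine/water/ethanol defaults (fitted interaction
parameters, nominal diffusivities of 1e-9 m^2/s, 1 mm channel with 1024 cells
and a 0.1 s step).  Every applied default is logged.  ``serialize`` and
``parse_config`` round-trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .msdiffusion import DiffusionParams
from .simulate import (
    ChannelConfig,
    InitialCondition,
    SimulationResult,
    antisolvent_from_vol_percent,
    antisolvent_from_wt_percent,
    solution_from_ideal_supersaturation,
)
from .species import Composition, SpeciesSet
from .thermo import ThermoParams

logger = logging.getLogger("msmix")

__all__ = ["RunConfig", "parse_config", "serialize", "write_outputs", "ConfigError"]


class ConfigError(ValueError):
    """Configuration document violates the schema; message names the key."""


_KNOWN_BLOCKS = {"species", "thermo", "diffusion", "channel", "initial", "output"}


@dataclass(frozen=True)
class RunConfig:
    species: SpeciesSet
    thermo: ThermoParams
    diffusion: DiffusionParams
    channel: ChannelConfig
    initial: InitialCondition
    output_dir: str = "msmix_out"
    verbosity: str = "info"


def _expect_mapping(doc, key):
    block = doc.get(key, {})
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"block '{key}' must be a mapping")
    return dict(block)


def _pop(block: dict, block_name: str, key: str, default):
    if key in block:
        return block.pop(key)
    logger.debug("config: %s.%s defaulted to %r", block_name, key, default)
    return default


def _reject_unknown(block: dict, name: str) -> None:
    if block:
        raise ConfigError(f"unknown key(s) in block '{name}': {sorted(block)}")


def _composition_from_spec(spec, s: SpeciesSet, context: str) -> Composition:
    if not isinstance(spec, dict) or "basis" not in spec:
        raise ConfigError(f"'{context}' must be a mapping with a 'basis' tag")
    spec = dict(spec)
    basis = spec.pop("basis")
    fracs = spec.pop("fractions", None)
    _reject_unknown(spec, context)
    if fracs is None or len(fracs) != 3:
        raise ConfigError(f"'{context}.fractions' must list three values")
    fracs = np.asarray(fracs, float)
    if basis == "mole":
        return Composition.from_mole_fractions(fracs, normalize=True)
    if basis == "mass":
        return Composition.from_mass_fractions(fracs, s, normalize=True)
    if basis == "volume":
        return Composition.from_physical_volume_fractions(fracs, s, normalize=True)
    raise ConfigError(f"'{context}.basis' must be one of mass/mole/volume, got {basis!r}")


def parse_config(text: str) -> RunConfig:
    """Parse and validate a YAML run document, applying defaults."""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("document root must be a mapping")
    unknown = set(doc) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown top-level block(s): {sorted(unknown)}")

    sp = _expect_mapping(doc, "species")
    species = SpeciesSet(
        names=tuple(_pop(sp, "species", "names", list(SpeciesSet().names))),
        molar_masses=tuple(_pop(sp, "species", "molar_masses", list(SpeciesSet().molar_masses))),
        thermo_volume_ratios=tuple(
            _pop(sp, "species", "thermo_volume_ratios", list(SpeciesSet().thermo_volume_ratios))
        ),
        physical_volume_ratios=tuple(
            _pop(
                sp,
                "species",
                "physical_volume_ratios",
                list(SpeciesSet().physical_volume_ratios),
            )
        ),
    )
    _reject_unknown(sp, "species")

    th = _expect_mapping(doc, "thermo")
    default = ThermoParams.glycine_water_ethanol()
    if "chi" in th:
        chi = np.asarray(th.pop("chi"), float)
        if chi.shape != (3, 3):
            raise ConfigError("'thermo.chi' must be a 3x3 matrix")
        if not np.allclose(chi, chi.T):
            raise ConfigError("'thermo.chi' must be symmetric")
    else:
        chi = default.chi
        logger.debug("config: thermo.chi defaulted")
    try:
        thermo = ThermoParams(
            chi=chi,
            solubility_constant=float(
                _pop(th, "thermo", "solubility_constant", default.solubility_constant)
            ),
            temperature=float(_pop(th, "thermo", "temperature", default.temperature)),
        )
    except ValueError as e:
        raise ConfigError(f"thermo block invalid: {e}") from e
    _reject_unknown(th, "thermo")

    df = _expect_mapping(doc, "diffusion")
    try:
        diffusion = DiffusionParams(
            D01=float(_pop(df, "diffusion", "D01", 1e-9)),
            D02=float(_pop(df, "diffusion", "D02", 1e-9)),
            D12=float(_pop(df, "diffusion", "D12", 1e-9)),
            mode=_pop(df, "diffusion", "mode", "nonideal"),
        )
    except ValueError as e:
        raise ConfigError(f"diffusion block invalid: {e}") from e
    _reject_unknown(df, "diffusion")

    ch = _expect_mapping(doc, "channel")
    try:
        channel = ChannelConfig(
            length=float(_pop(ch, "channel", "length", 1e-3)),
            n_cells=int(_pop(ch, "channel", "n_cells", 1024)),
            dt=float(_pop(ch, "channel", "dt", 0.1)),
            dt_output=float(_pop(ch, "channel", "dt_output", 0.1)),
            t_end=float(_pop(ch, "channel", "t_end", 500.0)),
            snapshot_times=tuple(_pop(ch, "channel", "snapshot_times", [])),
            interface_position=_pop(ch, "channel", "interface_position", None),
            halt_on_spinodal=bool(_pop(ch, "channel", "halt_on_spinodal", False)),
            stop_when_relaxed=bool(_pop(ch, "channel", "stop_when_relaxed", False)),
        )
    except ValueError as e:
        raise ConfigError(f"channel block invalid: {e}") from e
    _reject_unknown(ch, "channel")

    init = _expect_mapping(doc, "initial")
    if "solution" in init:
        sol_spec = init.pop("solution")
        if isinstance(sol_spec, dict) and "ideal_supersaturation" in sol_spec:
            target = sol_spec.pop("ideal_supersaturation")
            _reject_unknown(sol_spec, "initial.solution")
            solution = solution_from_ideal_supersaturation(float(target), thermo, species)
        else:
            solution = _composition_from_spec(sol_spec, species, "initial.solution")
    else:
        solution = solution_from_ideal_supersaturation(0.85, thermo, species)
        logger.debug("config: initial.solution defaulted to ideal supersaturation 0.85")
    if "antisolvent" in init:
        anti_spec = init.pop("antisolvent")
        if isinstance(anti_spec, dict) and "ethanol_wt_percent" in anti_spec:
            pct = anti_spec.pop("ethanol_wt_percent")
            _reject_unknown(anti_spec, "initial.antisolvent")
            antisolvent = antisolvent_from_wt_percent(float(pct), species)
        elif isinstance(anti_spec, dict) and "ethanol_vol_percent" in anti_spec:
            pct = anti_spec.pop("ethanol_vol_percent")
            _reject_unknown(anti_spec, "initial.antisolvent")
            antisolvent = antisolvent_from_vol_percent(float(pct), species)
        else:
            antisolvent = _composition_from_spec(anti_spec, species, "initial.antisolvent")
    else:
        antisolvent = antisolvent_from_wt_percent(80.0, species)
        logger.debug("config: initial.antisolvent defaulted to 80 wt%% ethanol")
    try:
        initial = InitialCondition(
            solution_side=solution,
            antisolvent_side=antisolvent,
            fill_ratio=float(_pop(init, "initial", "fill_ratio", 1.0)),
        )
    except ValueError as e:
        raise ConfigError(f"initial block invalid: {e}") from e
    _reject_unknown(init, "initial")

    out = _expect_mapping(doc, "output")
    output_dir = str(_pop(out, "output", "dir", "msmix_out"))
    verbosity = str(_pop(out, "output", "verbosity", "info"))
    _reject_unknown(out, "output")

    return RunConfig(
        species=species,
        thermo=thermo,
        diffusion=diffusion,
        channel=channel,
        initial=initial,
        output_dir=output_dir,
        verbosity=verbosity,
    )


def serialize(cfg: RunConfig) -> str:
    """YAML text that re-parses to an identical RunConfig."""
    doc = {
        "species": {
            "names": list(cfg.species.names),
            "molar_masses": list(cfg.species.molar_masses),
            "thermo_volume_ratios": list(cfg.species.thermo_volume_ratios),
            "physical_volume_ratios": list(cfg.species.physical_volume_ratios),
        },
        "thermo": {
            "chi": cfg.thermo.chi.tolist(),
            "solubility_constant": cfg.thermo.solubility_constant,
            "temperature": cfg.thermo.temperature,
        },
        "diffusion": {
            "D01": cfg.diffusion.D01,
            "D02": cfg.diffusion.D02,
            "D12": cfg.diffusion.D12,
            "mode": cfg.diffusion.mode,
        },
        "channel": {
            "length": cfg.channel.length,
            "n_cells": cfg.channel.n_cells,
            "dt": cfg.channel.dt,
            "dt_output": cfg.channel.dt_output,
            "t_end": cfg.channel.t_end,
            "snapshot_times": list(cfg.channel.snapshot_times),
            "interface_position": cfg.channel.interface_position,
            "halt_on_spinodal": cfg.channel.halt_on_spinodal,
            "stop_when_relaxed": cfg.channel.stop_when_relaxed,
        },
        "initial": {
            "solution": {
                "basis": "mole",
                "fractions": cfg.initial.solution_side.x.tolist(),
            },
            "antisolvent": {
                "basis": "mole",
                "fractions": cfg.initial.antisolvent_side.x.tolist(),
            },
            "fill_ratio": cfg.initial.fill_ratio,
        },
        "output": {"dir": cfg.output_dir, "verbosity": cfg.verbosity},
    }
    return yaml.safe_dump(doc, sort_keys=False)


def write_outputs(result: SimulationResult, cfg: RunConfig, outdir: str | Path) -> list[Path]:
    """Write snapshot CSVs plus a JSON run summary; returns the paths written.

    Each snapshot CSV holds cell-center position, the three volume fractions,
    mass and mole fractions, and both supersaturation fields at 17 significant
    digits so rereading reproduces the values bit for bit.  The effective
    config is echoed alongside for provenance.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {outdir}: {e}") from e
    s = cfg.species
    paths = []
    z = (np.arange(result.config.n_cells) + 0.5) * result.config.dz
    for snap in result.snapshots:
        x = np.vstack([snap.phi[i] for i in range(3)]).T
        m = (snap.phi / s.V[:, None]).T
        xmole = m / m.sum(axis=1, keepdims=True)
        wmass = xmole * s.M
        wmass = wmass / wmass.sum(axis=1, keepdims=True)
        df = pd.DataFrame({"z_m": z})
        for i, name in enumerate(s.names):
            df[f"phi_{name}"] = snap.phi[i]
        for i, name in enumerate(s.names):
            df[f"w_{name}"] = wmass[:, i]
        for i, name in enumerate(s.names):
            df[f"x_{name}"] = xmole[:, i]
        df["S_ideal"] = snap.S_ideal
        df["S_nonideal"] = snap.S_nonideal
        path = outdir / f"snapshot_t{snap.time:.3f}s.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        paths.append(path)

    summary = {
        "mode": result.mode,
        "t_final": float(result.times[-1]) if result.times.size else None,
        "fully_mixed": {
            "mole_fractions": result.fully_mixed.composition.x.tolist(),
            "S_nonideal": result.fully_mixed.S_nonideal,
            "S_ideal": result.fully_mixed.S_ideal,
        },
        "max_S_nonideal": result.max_S_nonideal,
        "max_S_ideal": result.max_S_ideal,
        "relaxation_time_s": result.relaxation_time,
        "conservation_error": result.conservation_error,
        "sum_phi_error": result.sum_phi_error,
        "llps_event": None,
    }
    if result.llps_event is not None:
        e = result.llps_event
        from .phase_diagram import phase_regions, classify_point

        regions = phase_regions(cfg.thermo, s, resolution=60, n_lines=120)
        liquid, solid = classify_point(result.fully_mixed.composition, regions, cfg.thermo, s)
        summary["llps_event"] = {
            "time_s": e.time,
            "cell": e.cell,
            "mole_fractions": e.composition.x.tolist(),
            "min_eigenvalue": e.min_eigenvalue,
        }
        summary["fully_mixed"]["liquid_class"] = liquid
        summary["fully_mixed"]["solid_class"] = solid
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    paths.append(spath)
    cpath = outdir / "effective_config.yaml"
    cpath.write_text(serialize(cfg))
    paths.append(cpath)
    return paths
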