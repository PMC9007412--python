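"""Supersaturation-peak trajectories, overshoot metrics, diffusivity sweeps and
liquid–liquid phase separation reporting.

Nucleation is most likely where the local supersaturation peaks, so the
composition of the per-time supersaturation maximum, traced on the ternary
diagram, summarizes where in composition space a mixing protocol would drive
crystal formation.  The overshoot metric compares the largest supersaturation
seen anywhere in the channel with the fully mixed value: ideal (Fickian)
transport predicts large overshoots, thermodynamically consistent transport
does not.  The diffusivity cube sweep repeats a scenario at the 2^3 low/high
combinations of the three pairwise diffusivities; the solvent/antisolvent
coefficient controls the grouping of outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msdiffusion import DiffusionParams
from .phase_diagram import PhaseRegions, classify_point
from .simulate import ChannelConfig, InitialCondition, SimulationResult, run, _FieldEvaluator
from .species import SpeciesSet
from .thermo import ThermoParams

__all__ = [
    "PeakTrajectory",
    "SweepCorner",
    "SweepResult",
    "peak_trajectory",
    "overshoot_metric",
    "relaxation_time",
    "sweep_diffusivity_cube",
    "llps_report",
]


@dataclass(frozen=True)
class PeakTrajectory:
    """Composition path of the supersaturation peak, sampled at 1 s."""

    times: np.ndarray
    mole_fractions: np.ndarray  # (n, 3)
    mass_fractions: np.ndarray  # (n, 3), barycentric plotting coordinates
    S_values: np.ndarray

    def to_frame(self, s: SpeciesSet) -> pd.DataFrame:
        cols = {f"w_{n}": self.mass_fractions[:, i] for i, n in enumerate(s.names)}
        return pd.DataFrame({"time_s": self.times, **cols, "S": self.S_values})


def _interp_rows(t_out: np.ndarray, t_in: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.interp(t_out, t_in, rows[:, j]) for j in range(rows.shape[1])]
    )


def peak_trajectory(
    result: SimulationResult, s: SpeciesSet, which: str = "nonideal", spacing: float = 1.0
) -> PeakTrajectory:
    """Per-second composition and value of the supersaturation peak.

    Uses the run's recorded peak locations (argmax over cells at each output
    time, leftmost on ties); if the output grid is not at the requested
    spacing the path is interpolated linearly in time.
    """
    if result.times.size == 0:
        raise ValueError("simulation result holds no recorded output times")
    if which == "nonideal":
        x, S = result.peak_x_nonideal, result.peak_S_nonideal
    elif which == "ideal":
        x, S = result.peak_x_ideal, result.peak_S_ideal
    else:
        raise ValueError("which must be 'ideal' or 'nonideal'")
    t_end = result.times[-1]
    t_out = np.arange(0.0, t_end + 1e-9, spacing)
    xs = _interp_rows(t_out, result.times, x)
    xs /= xs.sum(axis=1, keepdims=True)
    Ss = np.interp(t_out, result.times, S)
    M = s.M
    w = xs * M
    w /= w.sum(axis=1, keepdims=True)
    return PeakTrajectory(times=t_out, mole_fractions=xs, mass_fractions=w, S_values=Ss)


def overshoot_metric(result: SimulationResult, which: str = "nonideal") -> float:
    """Largest supersaturation anywhere in the run over its fully mixed value."""
    if which == "nonideal":
        smax, smix = result.max_S_nonideal, result.fully_mixed.S_nonideal
    elif which == "ideal":
        smax, smix = result.max_S_ideal, result.fully_mixed.S_ideal
    else:
        raise ValueError("which must be 'ideal' or 'nonideal'")
    if smix <= 0:
        raise ValueError("fully mixed supersaturation must be positive")
    return float(smax / smix)


def relaxation_time(result: SimulationResult) -> float | None:
    """First output time at which max|phi - phi_mixed| < 0.01, or None."""
    return result.relaxation_time


@dataclass(frozen=True)
class SweepCorner:
    label: str  # e.g. "LHL" for (D01 low, D02 high, D12 low)
    D01: float
    D02: float
    D12: float
    overshoot: float
    relaxation_time: float | None
    llps: bool
    result: SimulationResult


@dataclass(frozen=True)
class SweepResult:
    corners: list[SweepCorner]
    which: str

    def group_by_D12(self) -> tuple[list[SweepCorner], list[SweepCorner]]:
        """(low-D12, high-D12) corners — the two-cluster split of outcomes."""
        d12s = sorted({c.D12 for c in self.corners})
        low = [c for c in self.corners if c.D12 == d12s[0]]
        high = [c for c in self.corners if c.D12 == d12s[-1]]
        return low, high

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "corner": c.label,
                    "D01": c.D01,
                    "D02": c.D02,
                    "D12": c.D12,
                    "overshoot": c.overshoot,
                    "relaxation_time_s": c.relaxation_time,
                    "llps": c.llps,
                }
                for c in self.corners
            ]
        )


def sweep_diffusivity_cube(
    ic: InitialCondition,
    cc: ChannelConfig,
    p: ThermoParams,
    s: SpeciesSet,
    mode: str = "ideal",
    low: float = 0.40e-9,
    high: float = 1.25e-9,
    evaluator: _FieldEvaluator | None = None,
) -> SweepResult:
    """Run the 8 low/high combinations of (D01, D02, D12) on one scenario."""
    if not low < high:
        raise ValueError("low diffusivity must be below high")
    ev = evaluator if evaluator is not None else _FieldEvaluator(p, s)
    corners = []
    for bits in range(8):
        vals = [(low, high)[(bits >> k) & 1] for k in (2, 1, 0)]
        label = "".join("H" if v == high else "L" for v in vals)
        dp = DiffusionParams(D01=vals[0], D02=vals[1], D12=vals[2], mode=mode)
        res = run(ic, cc, p, dp, s, evaluator=ev)
        corners.append(
            SweepCorner(
                label=label,
                D01=vals[0],
                D02=vals[1],
                D12=vals[2],
                overshoot=overshoot_metric(res, which=mode),
                relaxation_time=res.relaxation_time,
                llps=res.llps_event is not None,
                result=res,
            )
        )
    return SweepResult(corners=corners, which=mode)


def llps_report(
    result: SimulationResult,
    regions: PhaseRegions,
    p: ThermoParams,
    s: SpeciesSet,
) -> dict:
    """Summary of any local liquid–liquid instability met during mixing.

    Reports when and where the smaller eigenvalue of the thermodynamic factor
    first crossed zero, the composition there, and how the fully mixed
    composition classifies — localized demixing can occur even when the final
    mixture is well outside the two-phase region.
    """
    mixed_liquid, mixed_solid = classify_point(result.fully_mixed.composition, regions, p, s)
    out = {
        "llps_occurred": result.llps_event is not None,
        "fully_mixed_liquid_class": mixed_liquid,
        "fully_mixed_solid_class": mixed_solid,
        "fully_mixed_mole_fractions": result.fully_mixed.composition.x.tolist(),
    }
    if result.llps_event is not None:
        e = result.llps_event
        event_liquid, _ = classify_point(e.composition, regions, p, s)
        out.update(
            {
                "time_s": e.time,
                "cell": e.cell,
                "composition_mole_fractions": e.composition.x.tolist(),
                "min_eigenvalue": e.min_eigenvalue,
                "event_liquid_class": event_liquid,
            }
        )
    return out
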