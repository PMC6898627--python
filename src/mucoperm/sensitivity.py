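"""One-at-a-time parameter sweeps with checkpoint tables.

Each sweep varies a single physical parameter of a base scenario — the mucus
film volume, the perfusate flow rate, the experimental membrane thickness
h_exp (which enters only through the permeability rescaling P_exp h_exp /
h_m), or the modelled membrane thickness h_m — while holding everything else
fixed, and records the cumulative % of dose collected at a set of checkpoint
times. Changing the mucus volume also changes the film thickness h_t = V_d/S
and hence, in the unstirred variant, the depletion-zone resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .params import ApparatusParams, DrugParams, RunSpec
from .simulate import DissolutionPermeationModel, SimulationResult

__all__ = [
    "SweepParameter",
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "single_scenario_report",
]


class SweepParameter(str, Enum):
    """Parameters the sensitivity analysis can vary."""

    MUCUS_VOLUME = "mucus_volume"      # cm^3
    PERFUSATE_FLOW = "perfusate_flow"  # cm^3 min^-1
    HEXP = "hexp"                      # cm
    HM = "hm"                          # cm


DEFAULT_CHECKPOINTS = (15.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class SweepSpec:
    """A one-at-a-time sweep: which parameter, which values, over which base."""

    parameter: SweepParameter
    values: tuple[float, ...]
    base_drug: DrugParams
    base_app: ApparatusParams
    base_run: RunSpec
    checkpoints: tuple[float, ...] = DEFAULT_CHECKPOINTS

    def __post_init__(self):
        object.__setattr__(self, "parameter", SweepParameter(self.parameter))
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "checkpoints",
                           tuple(float(c) for c in self.checkpoints))
        if not values:
            raise InvalidParameterError("sweep values must be non-empty")
        if any(v <= 0 for v in values):
            raise InvalidParameterError(
                f"sweep values must be positive, got {values}")
        if any(b <= a for a, b in zip(values, values[1:])):
            raise InvalidParameterError(
                f"sweep values must be strictly increasing, got {values}")
        if any(c < 0 or c > self.base_run.t_end for c in self.checkpoints):
            raise InvalidParameterError(
                f"checkpoints must lie in [0, t_end={self.base_run.t_end}]")


@dataclass
class SweepResult:
    """Simulations and checkpoint table of one sweep.

    ``checkpoint_table`` has one row per (parameter value, checkpoint) with
    the % of dose collected; ``ordering_verdict`` gives, per checkpoint, the
    direction of the response across the swept values ("increasing",
    "decreasing", "constant" or "mixed" by strict comparison).
    """

    spec: SweepSpec
    results: list[SimulationResult]
    checkpoint_table: pd.DataFrame
    ordering_verdict: dict[float, str]

    def pct_at(self, checkpoint: float) -> np.ndarray:
        """% collected at one checkpoint, ordered as ``spec.values``."""
        tab = self.checkpoint_table
        rows = tab[tab["checkpoint_min"] == checkpoint]
        if rows.empty:
            raise InvalidParameterError(
                f"no checkpoint {checkpoint!r} in this sweep")
        return rows.sort_values("parameter_value")["pct_collected"].to_numpy()

    def max_spread(self, checkpoint: float) -> float:
        """Largest pairwise difference in % collected at one checkpoint."""
        pct = self.pct_at(checkpoint)
        return float(pct.max() - pct.min())

    def is_flat(self, tol: float = 5.0) -> bool:
        """True if the response varies by < ``tol`` % of dose at every checkpoint."""
        return all(self.max_spread(c) < tol for c in self.spec.checkpoints)

    def to_csv(self, path) -> Path:
        """Write the checkpoint table (parameter_value, checkpoint_min, pct_collected)."""
        path = Path(path)
        self.checkpoint_table.to_csv(path, index=False)
        return path


def _apply_value(spec: SweepSpec, value: float
                 ) -> tuple[DrugParams, ApparatusParams]:
    drug, app = spec.base_drug, spec.base_app
    p = spec.parameter
    if p is SweepParameter.MUCUS_VOLUME:
        app = app.replace(mucus_volume_Vd=value)  # h_t = Vd/S follows
    elif p is SweepParameter.PERFUSATE_FLOW:
        app = app.replace(perfusate_flow_Q=value)
    elif p is SweepParameter.HEXP:
        drug = drug.replace(membrane_thickness_exp_hexp=value)
    elif p is SweepParameter.HM:
        app = app.replace(membrane_thickness_hm=value)
    return drug, app


def _direction(pcts: np.ndarray) -> str:
    diffs = np.diff(pcts)
    if np.all(diffs == 0):
        return "constant"
    if np.all(diffs > 0):
        return "increasing"
    if np.all(diffs < 0):
        return "decreasing"
    return "mixed"


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run one one-at-a-time sweep and tabulate checkpoint responses.

    Every swept value is substituted into a copy of the base scenario; all
    runs share the base integrator settings.
    """
    results = []
    rows = []
    for value in spec.values:
        drug, app = _apply_value(spec, value)
        result = DissolutionPermeationModel(drug, app, spec.base_run).simulate()
        results.append(result)
        for checkpoint, pct in zip(
                spec.checkpoints,
                single_scenario_report(result, spec.checkpoints)):
            rows.append({"parameter_value": value, "checkpoint_min": checkpoint,
                         "pct_collected": pct})
    table = pd.DataFrame(rows)
    verdict = {
        c: _direction(np.array(
            [r["pct_collected"] for r in rows if r["checkpoint_min"] == c]))
        for c in spec.checkpoints
    }
    return SweepResult(spec=spec, results=results, checkpoint_table=table,
                       ordering_verdict=verdict)


def single_scenario_report(result: SimulationResult,
                           checkpoints: Sequence[float]) -> np.ndarray:
    """% of dose collected at each checkpoint (linear interpolation)."""
    checkpoints = np.asarray(list(checkpoints), dtype=float)
    t_max = result.times[-1]
    if np.any(checkpoints < 0) or np.any(checkpoints > t_max):
        raise InvalidParameterError(
            f"checkpoints must lie within [0, {t_max:g}] min")
    return np.interp(checkpoints, result.times, result.pct_collected)
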