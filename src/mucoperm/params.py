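"""Parameter containers for the dissolution–permeation model.

Three frozen dataclasses describe a scenario:

* :class:`DrugParams` — per-drug physicochemical and transport constants
  (solubility, intrinsic dissolution rate, particle size and density, and the
  experimentally measured permeability coefficient with the membrane thickness
  it was measured on).
* :class:`ApparatusParams` — geometry and flow of the perfusion cell
  (membrane area and thickness, donor mucus film volume, receiver volume,
  perfusate flow rate).
* :class:`RunSpec` — what to simulate: dose, whether the dose is deposited as
  solid particles or pre-dissolved solution, whether the donor film is treated
  as well-stirred or as developing a depletion zone, and the numerics.

All values are in the internal cm–g–min unit system (see :mod:`mucoperm.units`
for boundary conversions). Validation raises
:class:`~mucoperm.exceptions.InvalidParameterError` naming the offending
field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

from .exceptions import InvalidParameterError

__all__ = [
    "DoseForm",
    "Stirring",
    "Integrator",
    "DrugParams",
    "ApparatusParams",
    "RunSpec",
]


class DoseForm(str, Enum):
    """How the dose enters the mucus film."""

    PARTICLES = "particles"
    SOLUTION = "solution"


class Stirring(str, Enum):
    """Idealization of the donor film hydrodynamics."""

    WELL_STIRRED = "well_stirred"
    UNSTIRRED = "unstirred"


class Integrator(str, Enum):
    """Fixed-step integration scheme."""

    RK4 = "rk4"
    EULER = "euler"


def _require_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            raise InvalidParameterError(f"{name} must be a finite number, got {value!r}")
        if value <= 0:
            raise InvalidParameterError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            raise InvalidParameterError(f"{name} must be a finite number, got {value!r}")
        if value < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class DrugParams:
    """Physicochemical and transport constants of one drug.

    Parameters
    ----------
    name
        Drug label.
    solubility_Cs
        Saturation solubility C_s in the donor medium, g cm^-3.
    intrinsic_dissolution_rate_IDR
        Intrinsic dissolution rate, g cm^-2 min^-1. Together with C_s it
        fixes the dissolution rate constant k = IDR / C_s.
    initial_diameter_d0
        Initial particle diameter d_0, cm (monodisperse spheres).
    density_rho
        Particle density, g cm^-3.
    permeability_exp_Pexp
        Experimentally measured membrane permeability coefficient P_exp,
        cm min^-1.
    membrane_thickness_exp_hexp
        Hydrated thickness of the membrane on which P_exp was measured, cm.
    """

    name: str
    solubility_Cs: float
    intrinsic_dissolution_rate_IDR: float
    initial_diameter_d0: float
    density_rho: float
    permeability_exp_Pexp: float
    membrane_thickness_exp_hexp: float

    def __post_init__(self):
        _require_positive(
            self,
            "solubility_Cs",
            "intrinsic_dissolution_rate_IDR",
            "initial_diameter_d0",
            "density_rho",
            "permeability_exp_Pexp",
            "membrane_thickness_exp_hexp",
        )

    def replace(self, **changes) -> "DrugParams":
        """Return a copy with the given fields replaced (re-validated)."""
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return DrugParams(**kwargs)


@dataclass(frozen=True)
class ApparatusParams:
    """Geometry and flow of the perfusion cell.

    The donor film thickness is not an independent parameter: a mucus volume
    V_d spread over the membrane area S gives h_t = V_d / S, recomputed
    whenever the volume is changed (e.g. in sensitivity sweeps).
    """

    membrane_area_S: float        # cm^2
    membrane_thickness_hm: float  # cm
    mucus_volume_Vd: float        # cm^3
    receiver_volume_Vr: float     # cm^3
    perfusate_flow_Q: float       # cm^3 min^-1

    def __post_init__(self):
        _require_positive(
            self,
            "membrane_area_S",
            "membrane_thickness_hm",
            "mucus_volume_Vd",
            "receiver_volume_Vr",
        )
        _require_nonnegative(self, "perfusate_flow_Q")

    @property
    def mucus_thickness_ht(self) -> float:
        """Donor film thickness h_t = V_d / S, cm."""
        return self.mucus_volume_Vd / self.membrane_area_S

    def replace(self, **changes) -> "ApparatusParams":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return ApparatusParams(**kwargs)


@dataclass(frozen=True)
class RunSpec:
    """Dose, dose form, stirring mode, and numerics for one simulation.

    ``dt`` is the fixed integration step (min); ``output_stride`` is the
    interval (min) at which states are stored — the integrator always runs at
    ``dt`` and samples the trajectory at the stride.
    """

    dose_M0: float                       # g
    dose_form: DoseForm = DoseForm.PARTICLES
    stirring: Stirring = Stirring.WELL_STIRRED
    t_end: float = 120.0                 # min
    dt: float = 0.01                     # min
    integrator: Integrator = Integrator.RK4
    output_stride: float = 1.0           # min

    def __post_init__(self):
        _require_positive(self, "dose_M0", "t_end", "dt", "output_stride")
        object.__setattr__(self, "dose_form", DoseForm(self.dose_form))
        object.__setattr__(self, "stirring", Stirring(self.stirring))
        object.__setattr__(self, "integrator", Integrator(self.integrator))
        if self.dt > self.t_end:
            raise InvalidParameterError(
                f"dt must satisfy 0 < dt <= t_end, got dt={self.dt}, t_end={self.t_end}"
            )

    def replace(self, **changes) -> "RunSpec":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return RunSpec(**kwargs)
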