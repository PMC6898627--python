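"""Pointwise kinetic laws of the dissolution–permeation model.

The model tracks drug mass through four stocks: solid particles suspended in
the mucus film, drug dissolved in the film, drug that has permeated into the
receiver, and drug swept into the collection tube by the perfusate. The laws
here are evaluated pointwise from a :class:`SystemState` and the scenario
parameters; the integrator in :mod:`mucoperm.simulate` wires them together.

Dissolution follows the Noyes–Whitney law for a monodisperse population of
shrinking spheres: the mass rate is k·S_t·(C_s − C) where k = IDR / C_s is
the dissolution rate constant, S_t the total particle surface area, C_s the
solubility and C the bulk film concentration. Permeation across the membrane
is P·S·(C_mucus − C_perfusate). In the well-stirred idealization the
permeability P = P_exp·h_exp/h_m is constant; in the unstirred idealization a
drug-depleted layer of thickness h_d = f_d·h_t grows next to the membrane as
the fraction f_d of the dose leaves the film, adding series resistance:
P_t = P_exp·h_exp/(h_m + f_d·h_t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidParameterError, InvalidStateError
from .params import Stirring

__all__ = [
    "SystemState",
    "KineticSnapshot",
    "dissolution_rate_constant",
    "particle_diameter_at",
    "total_surface_area",
    "donor_concentration",
    "dissolution_mass_rate",
    "depletion_fraction",
    "permeability",
    "permeation_rate",
    "collection_rate",
    "saturation_capacity",
]


@dataclass(frozen=True)
class SystemState:
    """Masses in the four stocks at one time point (g, min)."""

    t: float
    mass_solid: float
    mass_dissolved: float
    mass_receiver: float
    mass_collected: float

    def __post_init__(self):
        for name in ("mass_solid", "mass_dissolved", "mass_receiver", "mass_collected"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidStateError(f"{name} is not finite: {value!r}")
            if value < 0:
                raise InvalidStateError(f"{name} must be >= 0, got {value!r}")

    @property
    def total_mass(self) -> float:
        return (self.mass_solid + self.mass_dissolved
                + self.mass_receiver + self.mass_collected)


@dataclass(frozen=True)
class KineticSnapshot:
    """Derived kinetic quantities at one time point.

    ``depletion_thickness_hd`` is zero under well-stirred conditions;
    ``particle_diameter_dt`` and ``surface_area_St`` are zero for
    pre-dissolved (solution) doses.
    """

    t: float
    donor_conc_C: float        # g cm^-3
    receiver_conc_Cp: float    # g cm^-3
    particle_diameter_dt: float  # cm
    surface_area_St: float     # cm^2
    permeability_P: float      # cm min^-1
    depletion_thickness_hd: float  # cm


def dissolution_rate_constant(IDR: float, Cs: float) -> float:
    """Dissolution rate constant k = IDR / C_s (cm min^-1).

    The intrinsic dissolution rate IDR (g cm^-2 min^-1) is the flux per unit
    area of a compacted disc dissolving into pure medium; dividing by the
    solubility yields the ratio D/h of the particle's diffusion coefficient to
    its unstirred-diffusion-layer thickness, which the shrinking-sphere law
    uses as a first-order rate constant.
    """
    if Cs <= 0:
        raise InvalidParameterError(f"solubility Cs must be > 0, got {Cs!r}")
    if IDR < 0:
        raise InvalidParameterError(f"IDR must be >= 0, got {IDR!r}")
    return IDR / Cs


def particle_diameter_at(M_t: float, M0: float, d0: float) -> float:
    """Diameter of a (shrunken) particle when the powder mass is M_t.

    Monodisperse spheres shrinking uniformly at fixed particle number give
    d_t = (M_t d_0^3 / M_0)^(1/3).
    """
    if M0 <= 0:
        raise InvalidParameterError(f"M0 must be > 0, got {M0!r}")
    if d0 <= 0:
        raise InvalidParameterError(f"d0 must be > 0, got {d0!r}")
    if M_t < 0 or M_t > M0:
        raise InvalidStateError(f"M_t must lie in [0, M0]; got M_t={M_t!r}, M0={M0!r}")
    return (M_t * d0 ** 3 / M0) ** (1.0 / 3.0)


def total_surface_area(M_t: float, M0: float, d0: float, rho: float) -> float:
    """Total surface area of the powder when its remaining mass is M_t.

    The particle count N = 6 M_0 / (π d_0^3 ρ) is fixed at deposition; each
    sphere has area π d_t^2, so S_t = 6 M_0 d_t^2 / (d_0^3 ρ), which scales
    as S_0 (M_t/M_0)^(2/3).
    """
    if rho <= 0:
        raise InvalidParameterError(f"density rho must be > 0, got {rho!r}")
    d_t = particle_diameter_at(M_t, M0, d0)
    return 6.0 * M0 * d_t ** 2 / (d0 ** 3 * rho)


def donor_concentration(mass_dissolved: float, Vd: float) -> float:
    """Concentration of dissolved drug in the mucus film, g cm^-3."""
    if Vd <= 0:
        raise InvalidParameterError(f"mucus volume Vd must be > 0, got {Vd!r}")
    return mass_dissolved / Vd


def dissolution_mass_rate(k: float, S_t: float, Cs: float, C: float) -> float:
    """Noyes–Whitney mass dissolution rate k·S_t·(C_s − C), g min^-1.

    The driving force is clamped at zero when the film is at or above
    saturation: precipitation is not modelled, so a saturated (or, for
    pre-dissolved doses, supersaturated) film simply stops dissolving.
    """
    if k < 0:
        raise InvalidParameterError(f"rate constant k must be >= 0, got {k!r}")
    if S_t < 0:
        raise InvalidParameterError(f"surface area S_t must be >= 0, got {S_t!r}")
    return max(0.0, k * S_t * (Cs - C))


def depletion_fraction(state: SystemState, M0: float) -> float:
    """Fraction f_d of the dose that has left the mucus film.

    Drug in the receiver and drug already swept into the collection tube have
    both crossed the membrane, so both count toward the depletion zone:
    f_d = (mass_receiver + mass_collected) / M_0.
    """
    if M0 <= 0:
        raise InvalidParameterError(f"M0 must be > 0, got {M0!r}")
    return (state.mass_receiver + state.mass_collected) / M0


def permeability(stirring: Stirring, Pexp: float, hexp: float, hm: float,
                 f_d: float = 0.0, h_t: float = 0.0) -> float:
    """Membrane permeability coefficient, cm min^-1.

    The experimental coefficient P_exp = D/h_exp is rescaled to the modelled
    barrier. Well-stirred: the barrier is the membrane alone, P = P_exp
    h_exp / h_m, constant in time. Unstirred: the depletion zone h_d = f_d
    h_t adds series resistance, P_t = P_exp h_exp / (h_m + f_d h_t), which is
    non-increasing as drug leaves the film.
    """
    if hm <= 0:
        raise InvalidParameterError(f"membrane thickness hm must be > 0, got {hm!r}")
    if Pexp <= 0 or hexp <= 0:
        raise InvalidParameterError(
            f"Pexp and hexp must be > 0, got Pexp={Pexp!r}, hexp={hexp!r}")
    if Stirring(stirring) is Stirring.WELL_STIRRED:
        return Pexp * hexp / hm
    if not 0.0 <= f_d <= 1.0:
        raise InvalidStateError(f"depletion fraction f_d must lie in [0, 1], got {f_d!r}")
    if h_t < 0:
        raise InvalidParameterError(f"mucus thickness h_t must be >= 0, got {h_t!r}")
    return Pexp * hexp / (hm + f_d * h_t)


def permeation_rate(P: float, S: float, C_mucus: float, C_perfusate: float) -> float:
    """Trans-membrane mass flux P·S·(C_mucus − C_perfusate), g min^-1.

    Signed: a receiver concentration exceeding the donor would drive back-flux
    (never arises in the scenarios modelled here, but the law permits it).
    """
    if P < 0 or S < 0:
        raise InvalidParameterError(f"P and S must be >= 0, got P={P!r}, S={S!r}")
    return P * S * (C_mucus - C_perfusate)


def collection_rate(C_perfusate: float, Q: float) -> float:
    """Rate at which the perfusate sweeps drug into the collection tube.

    Equals the receiver (perfusate) concentration times the flow rate Q.
    """
    if Q < 0:
        raise InvalidParameterError(f"flow rate Q must be >= 0, got {Q!r}")
    return C_perfusate * Q


def saturation_capacity(Cs: float, Vd: float) -> float:
    """Maximum mass the mucus film can hold in solution: C_s · V_d (g)."""
    if Cs <= 0 or Vd <= 0:
        raise InvalidParameterError(
            f"Cs and Vd must be > 0, got Cs={Cs!r}, Vd={Vd!r}")
    return Cs * Vd
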