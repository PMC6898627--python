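"""Four-stock ODE system and fixed-step integrator.

The donor mucus film, the membrane, the perfused receiver and the collection
tube form a chain of four mass stocks:

    solid --dissolution--> dissolved --permeation--> receiver --flow--> collected

with rates given by the laws in :mod:`mucoperm.kinetics`. The system is
integrated with a fixed-step scheme (classical RK4 by default, forward Euler
selectable) so the time grid, and hence the reported profiles, are exactly
reproducible. After each step, outgoing overshoot is clamped: a stock driven
slightly below zero by the finite step is zeroed and the deficit handed to the
downstream stock, which keeps the mass balance exact to rounding.

The public surface follows the model/results convention:
:class:`DissolutionPermeationModel` holds a scenario and
:meth:`~DissolutionPermeationModel.simulate` returns a
:class:`SimulationResult` with the stored trajectory, derived kinetic
quantities, a ``summary()`` and data-frame/plot accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import __version__ as _pkg_version
from .exceptions import IntegrationError, InvalidParameterError
from .kinetics import (
    KineticSnapshot,
    SystemState,
    collection_rate,
    dissolution_mass_rate,
    dissolution_rate_constant,
    donor_concentration,
    particle_diameter_at,
    permeability,
    permeation_rate,
    total_surface_area,
)
from .params import ApparatusParams, DoseForm, DrugParams, Integrator, RunSpec, Stirring

__all__ = [
    "SimulationResult",
    "DissolutionPermeationModel",
    "derivatives",
    "simulate",
    "time_to_fraction",
]


def derivatives(state: SystemState, drug: DrugParams, app: ApparatusParams,
                run: RunSpec) -> tuple[float, float, float, float]:
    """Instantaneous mass rates (g min^-1) of the four stocks.

    Returns ``(d_solid, d_dissolved, d_receiver, d_collected)``. The four
    rates sum to zero: the chain only moves mass between stocks.
    """
    M0 = run.dose_M0
    C = donor_concentration(state.mass_dissolved, app.mucus_volume_Vd)
    Cp = state.mass_receiver / app.receiver_volume_Vr

    if run.dose_form is DoseForm.PARTICLES and state.mass_solid > 0:
        k = dissolution_rate_constant(drug.intrinsic_dissolution_rate_IDR,
                                      drug.solubility_Cs)
        S_t = total_surface_area(min(state.mass_solid, M0), M0,
                                 drug.initial_diameter_d0, drug.density_rho)
        dissolution = dissolution_mass_rate(k, S_t, drug.solubility_Cs, C)
    else:
        dissolution = 0.0

    f_d = (state.mass_receiver + state.mass_collected) / M0
    P = permeability(run.stirring, drug.permeability_exp_Pexp,
                     drug.membrane_thickness_exp_hexp, app.membrane_thickness_hm,
                     f_d=min(f_d, 1.0), h_t=app.mucus_thickness_ht)
    permeation = permeation_rate(P, app.membrane_area_S, C, Cp)
    collection = collection_rate(Cp, app.perfusate_flow_Q)

    return (-dissolution, dissolution - permeation, permeation - collection,
            collection)


@dataclass
class SimulationResult:
    """Stored trajectory of one simulation.

    Attributes
    ----------
    times
        Output time grid, min.
    mass_solid, mass_dissolved, mass_receiver, mass_collected
        Stock masses on the grid, g.
    donor_conc, receiver_conc
        Film and receiver concentrations, g cm^-3.
    particle_diameter, surface_area
        Shrinking-sphere diameter (cm) and total powder area (cm^2);
        zero for solution doses.
    permeability_coeff
        Instantaneous membrane permeability, cm min^-1.
    depletion_thickness
        Depletion-zone thickness h_d, cm (zero when well-stirred).
    pct_collected
        Cumulative % of the dose in the collection tube.
    metadata
        Full provenance: every input parameter, the integrator, dt and the
        package version.
    """

    times: np.ndarray
    mass_solid: np.ndarray
    mass_dissolved: np.ndarray
    mass_receiver: np.ndarray
    mass_collected: np.ndarray
    donor_conc: np.ndarray
    receiver_conc: np.ndarray
    particle_diameter: np.ndarray
    surface_area: np.ndarray
    permeability_coeff: np.ndarray
    depletion_thickness: np.ndarray
    pct_collected: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def states(self) -> list[SystemState]:
        """Trajectory as :class:`~mucoperm.kinetics.SystemState` objects."""
        return [
            SystemState(t=float(t), mass_solid=float(ms), mass_dissolved=float(md),
                        mass_receiver=float(mr), mass_collected=float(mc))
            for t, ms, md, mr, mc in zip(self.times, self.mass_solid,
                                         self.mass_dissolved, self.mass_receiver,
                                         self.mass_collected)
        ]

    @property
    def snapshots(self) -> list[KineticSnapshot]:
        """Derived kinetic quantities as snapshot objects."""
        return [
            KineticSnapshot(t=float(t), donor_conc_C=float(c),
                            receiver_conc_Cp=float(cp),
                            particle_diameter_dt=float(d),
                            surface_area_St=float(s), permeability_P=float(p),
                            depletion_thickness_hd=float(hd))
            for t, c, cp, d, s, p, hd in zip(
                self.times, self.donor_conc, self.receiver_conc,
                self.particle_diameter, self.surface_area,
                self.permeability_coeff, self.depletion_thickness)
        ]

    @property
    def dose_M0(self) -> float:
        return self.metadata["run"]["dose_M0"]

    def to_frame(self):
        """Trajectory as a :class:`pandas.DataFrame` (one row per stored point)."""
        import pandas as pd

        return pd.DataFrame({
            "time_min": self.times,
            "mass_solid_g": self.mass_solid,
            "mass_dissolved_g": self.mass_dissolved,
            "mass_receiver_g": self.mass_receiver,
            "mass_collected_g": self.mass_collected,
            "pct_collected": self.pct_collected,
            "donor_conc_g_cm3": self.donor_conc,
            "receiver_conc_g_cm3": self.receiver_conc,
            "permeability_cm_min": self.permeability_coeff,
            "particle_diameter_cm": self.particle_diameter,
        })

    def time_to_fraction(self, fraction: float) -> Optional[float]:
        """Earliest time at which the collected fraction reaches ``fraction``.

        Linearly interpolated between stored points; ``None`` if the horizon
        ends first.
        """
        return time_to_fraction(self, fraction)

    def summary(self) -> str:
        """Human-readable run summary."""
        md = self.metadata
        m0_ug = self.dose_M0 * 1e6
        lines = [
            "Dissolution–permeation simulation",
            "=" * 49,
            f"drug:            {md['drug']['name']}",
            f"dose:            {m0_ug:.3g} ug ({md['run']['dose_form']})",
            f"stirring:        {md['run']['stirring']}",
            f"integrator:      {md['run']['integrator']} (dt = {md['run']['dt']} min)",
            f"horizon:         {md['run']['t_end']} min",
            f"mucus film:      {md['apparatus']['mucus_volume_Vd'] * 1e3:.3g} uL over "
            f"{md['apparatus']['membrane_area_S']} cm2 "
            f"({md['apparatus']['mucus_thickness_ht'] * 1e4:.1f} um)",
            "-" * 49,
            f"final %% collected:     {self.pct_collected[-1]:.2f}",
        ]
        for frac in (0.5, 0.9, 0.99):
            t = self.time_to_fraction(frac)
            label = f"{t:.1f} min" if t is not None else "not reached"
            lines.append(f"time to {100 * frac:>4.0f}%% collected: {label}")
        lines.append(
            f"peak donor conc:       "
            f"{self.donor_conc.max() * 1e3:.3g} mg/mL")
        return "\n".join(lines).replace("%%", "%")

    def plot(self, ax=None, label: str | None = None, **kwargs):
        """Plot cumulative % of dose collected vs time."""
        from .plotting import plot_profile

        return plot_profile(self, ax=ax, label=label, **kwargs)


def time_to_fraction(result: SimulationResult, fraction: float) -> Optional[float]:
    """Earliest stored time with pct_collected >= 100*fraction (interpolated).

    Returns ``None`` ("not reached") if the simulation horizon ends before the
    threshold is crossed.
    """
    if not 0.0 < fraction <= 1.0:
        raise InvalidParameterError(
            f"fraction must lie in (0, 1], got {fraction!r}")
    if len(result.times) == 0:
        raise InvalidParameterError("empty simulation result")
    target = 100.0 * fraction
    pct = result.pct_collected
    idx = np.argmax(pct >= target)
    if pct[idx] < target:
        return None
    if idx == 0:
        return float(result.times[0])
    t0, t1 = result.times[idx - 1], result.times[idx]
    p0, p1 = pct[idx - 1], pct[idx]
    if p1 == p0:
        return float(t1)
    return float(t0 + (target - p0) * (t1 - t0) / (p1 - p0))


class DissolutionPermeationModel:
    """A dissolution–permeation scenario ready to integrate.

    Parameters
    ----------
    drug, apparatus, run
        Scenario parameters; see :mod:`mucoperm.params`.

    Examples
    --------
    >>> from mucoperm import DissolutionPermeationModel
    >>> model = DissolutionPermeationModel.from_preset("ethionamide_table1")
    >>> result = model.simulate()
    >>> round(result.pct_collected[-1])  # doctest: +SKIP
    92
    """

    def __init__(self, drug: DrugParams, apparatus: ApparatusParams, run: RunSpec):
        self.drug = drug
        self.apparatus = apparatus
        self.run = run

    @classmethod
    def from_preset(cls, name: str, **run_overrides) -> "DissolutionPermeationModel":
        """Build a model from a shipped preset, optionally overriding run fields."""
        from .presets import get_preset

        preset = get_preset(name)
        run = preset.run.replace(**run_overrides) if run_overrides else preset.run
        return cls(preset.drug, preset.app, run)

    def derivatives(self, state: SystemState) -> tuple[float, float, float, float]:
        """Instantaneous stock mass rates at ``state`` (g min^-1)."""
        return derivatives(state, self.drug, self.apparatus, self.run)

    def simulate(self) -> SimulationResult:
        """Integrate the four-stock system over the run horizon."""
        drug, app, run = self.drug, self.apparatus, self.run

        M0 = run.dose_M0
        Vd = app.mucus_volume_Vd
        Vr = app.receiver_volume_Vr
        Q = app.perfusate_flow_Q
        S_mem = app.membrane_area_S
        h_t = app.mucus_thickness_ht
        hm = app.membrane_thickness_hm
        Cs = drug.solubility_Cs
        d0 = drug.initial_diameter_d0
        Pexp_hexp = drug.permeability_exp_Pexp * drug.membrane_thickness_exp_hexp
        k = dissolution_rate_constant(drug.intrinsic_dissolution_rate_IDR, Cs)
        S0 = 6.0 * M0 / (drug.density_rho * d0)  # initial powder area
        particles = run.dose_form is DoseForm.PARTICLES
        well_stirred = run.stirring is Stirring.WELL_STIRRED
        P_const = Pexp_hexp / hm

        two_thirds = 2.0 / 3.0

        def rates(ms: float, md: float, mr: float, mc: float):
            C = md / Vd
            Cp = mr / Vr
            if particles and ms > 0.0:
                S_t = S0 * (min(ms, M0) / M0) ** two_thirds
                dis = k * S_t * (Cs - C)
                if dis < 0.0:
                    dis = 0.0
                # within-step flux limit: dissolution may not remove more
                # solid than remains over one step (keeps very fast
                # dissolution well-behaved at a fixed dt)
                elif dis * dt > ms:
                    dis = ms / dt
            else:
                dis = 0.0
            if well_stirred:
                P = P_const
            else:
                f_d = (mr + mc) / M0
                P = Pexp_hexp / (hm + f_d * h_t)
            perm = P * S_mem * (C - Cp)
            coll = Cp * Q
            return -dis, dis - perm, perm - coll, coll

        dt = run.dt
        n_steps = int(round(run.t_end / dt))
        stride = max(1, int(round(run.output_stride / dt)))
        use_rk4 = run.integrator is Integrator.RK4

        if particles:
            ms, md = M0, 0.0
        else:
            # Pre-dissolved dose: the whole dose starts in solution even if
            # that exceeds Cs*Vd (no precipitation is modelled).
            ms, md = 0.0, M0
        mr = mc = 0.0

        ts = [0.0]
        traj = [(ms, md, mr, mc)]

        for step in range(1, n_steps + 1):
            if use_rk4:
                a1, b1, c1, d1 = rates(ms, md, mr, mc)
                h = dt / 2.0
                a2, b2, c2, d2 = rates(ms + h * a1, md + h * b1,
                                       mr + h * c1, mc + h * d1)
                a3, b3, c3, d3 = rates(ms + h * a2, md + h * b2,
                                       mr + h * c2, mc + h * d2)
                a4, b4, c4, d4 = rates(ms + dt * a3, md + dt * b3,
                                       mr + dt * c3, mc + dt * d3)
                sixth = dt / 6.0
                ms += sixth * (a1 + 2 * a2 + 2 * a3 + a4)
                md += sixth * (b1 + 2 * b2 + 2 * b3 + b4)
                mr += sixth * (c1 + 2 * c2 + 2 * c3 + c4)
                mc += sixth * (d1 + 2 * d2 + 2 * d3 + d4)
            else:
                a1, b1, c1, d1 = rates(ms, md, mr, mc)
                ms += dt * a1
                md += dt * b1
                mr += dt * c1
                mc += dt * d1

            # Clamp finite-step overshoot: hand any deficit downstream so the
            # total stays exact. A deficit reaching the terminal stock means
            # the step size cannot resolve the dynamics.
            if ms < 0.0:
                md += ms
                ms = 0.0
            if md < 0.0:
                mr += md
                md = 0.0
            if mr < 0.0:
                mc += mr
                mr = 0.0
            t = step * dt
            if not (np.isfinite(ms) and np.isfinite(md)
                    and np.isfinite(mr) and np.isfinite(mc)):
                raise IntegrationError(
                    f"non-finite state at step {step} (t = {t:g} min); "
                    f"reduce dt or switch integrator", step=step, time=t)
            if mc < 0.0:
                raise IntegrationError(
                    f"step {step} (t = {t:g} min) drove the collected stock "
                    f"negative; dt = {dt:g} min is too large for these "
                    f"kinetics", step=step, time=t)

            if step % stride == 0 or step == n_steps:
                ts.append(t)
                traj.append((ms, md, mr, mc))

        times = np.asarray(ts)
        arr = np.asarray(traj)
        mass_solid, mass_dissolved, mass_receiver, mass_collected = arr.T

        donor_conc = mass_dissolved / Vd
        receiver_conc = mass_receiver / Vr
        if particles:
            frac = np.clip(mass_solid / M0, 0.0, 1.0)
            diam = d0 * frac ** (1.0 / 3.0)
            area = S0 * frac ** two_thirds
        else:
            diam = np.zeros_like(times)
            area = np.zeros_like(times)
        f_d = (mass_receiver + mass_collected) / M0
        if well_stirred:
            perm_coeff = np.full_like(times, P_const)
            depletion = np.zeros_like(times)
        else:
            depletion = f_d * h_t
            perm_coeff = Pexp_hexp / (hm + depletion)
        pct = 100.0 * mass_collected / M0

        metadata = {
            "drug": {
                "name": drug.name,
                "solubility_Cs": Cs,
                "intrinsic_dissolution_rate_IDR": drug.intrinsic_dissolution_rate_IDR,
                "initial_diameter_d0": d0,
                "density_rho": drug.density_rho,
                "permeability_exp_Pexp": drug.permeability_exp_Pexp,
                "membrane_thickness_exp_hexp": drug.membrane_thickness_exp_hexp,
            },
            "apparatus": {
                "membrane_area_S": S_mem,
                "membrane_thickness_hm": hm,
                "mucus_volume_Vd": Vd,
                "receiver_volume_Vr": Vr,
                "perfusate_flow_Q": Q,
                "mucus_thickness_ht": h_t,
            },
            "run": {
                "dose_M0": M0,
                "dose_form": run.dose_form.value,
                "stirring": run.stirring.value,
                "t_end": run.t_end,
                "dt": dt,
                "integrator": run.integrator.value,
                "output_stride": run.output_stride,
            },
            "software": {"package": "mucoperm", "version": _pkg_version},
        }

        return SimulationResult(
            times=times, mass_solid=mass_solid, mass_dissolved=mass_dissolved,
            mass_receiver=mass_receiver, mass_collected=mass_collected,
            donor_conc=donor_conc, receiver_conc=receiver_conc,
            particle_diameter=diam, surface_area=area,
            permeability_coeff=perm_coeff, depletion_thickness=depletion,
            pct_collected=pct, metadata=metadata)


def simulate(drug: DrugParams, app: ApparatusParams, run: RunSpec) -> SimulationResult:
    """Functional wrapper: integrate a scenario and return its result."""
    return DissolutionPermeationModel(drug, app, run).simulate()
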