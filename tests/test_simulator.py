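"""Four-stock integrator: conservation, limits, and cross-checks."""

import numpy as np
import pytest

from mucoperm import (
    DissolutionPermeationModel,
    IntegrationError,
    InvalidParameterError,
    InvalidStateError,
    SimulationResult,
    SystemState,
    derivatives,
    simulate,
    time_to_fraction,
)
from oracles import euler_oracle, sink_donor_mass

FAST = dict(dt=0.02, t_end=60.0)


def _run(preset, **overrides):
    run = preset.run.replace(**overrides)
    return simulate(preset.drug, preset.app, run)


@pytest.mark.parametrize("form", ["particles", "solution"])
@pytest.mark.parametrize("stirring", ["well_stirred", "unstirred"])
@pytest.mark.parametrize("integrator", ["rk4", "euler"])
def test_mass_conserved_everywhere(ethio, form, stirring, integrator):
    res = _run(ethio, dose_form=form, stirring=stirring,
               integrator=integrator, **FAST)
    total = (res.mass_solid + res.mass_dissolved + res.mass_receiver
             + res.mass_collected)
    assert np.all(np.abs(total - res.dose_M0) <= 1e-6 * res.dose_M0)
    assert np.all(res.mass_solid >= 0) and np.all(res.mass_dissolved >= 0)
    assert np.all(res.mass_receiver >= 0) and np.all(res.mass_collected >= 0)


def test_monotone_stocks_and_bounded_collection(ethio):
    res = _run(ethio, **FAST)
    assert np.all(np.diff(res.mass_solid) <= 1e-18)
    assert np.all(np.diff(res.mass_collected) >= -1e-18)
    assert np.all(res.pct_collected <= 100.0 + 1e-9)
    assert np.all(np.diff(res.pct_collected) >= -1e-12)


def test_donor_never_exceeds_solubility_for_particle_doses(ethio, moxi):
    for preset in (ethio, moxi):
        res = _run(preset, **FAST)
        assert np.all(res.donor_conc <= preset.drug.solubility_Cs * (1 + 1e-9))


def test_solution_dose_may_exceed_solubility(ethio):
    # 50 ug pre-dissolved in 25 uL is 2 mg/mL, >4x the 0.46 mg/mL solubility.
    res = _run(ethio, dose_form="solution", **FAST)
    assert res.donor_conc[0] > ethio.drug.solubility_Cs


def test_closed_form_sink_limit(moxi):
    """Pre-dissolved, well-stirred, sweep flow fast enough to keep the
    receiver a sink: the donor drains as M0 exp(-Pexp S t / Vd)."""
    app = moxi.app.replace(perfusate_flow_Q=50.0)
    run = moxi.run.replace(dose_form="solution", t_end=30.0, dt=0.01)
    res = simulate(moxi.drug, app, run)
    expected = sink_donor_mass(run.dose_M0, moxi.drug.permeability_exp_Pexp,
                               app.membrane_area_S, app.mucus_volume_Vd, 30.0)
    assert res.mass_dissolved[-1] == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize("stirring", ["well_stirred", "unstirred"])
def test_rk4_matches_independent_euler_oracle(ethio, stirring):
    """Particle runs cross-checked against a naive per-sphere Euler loop."""
    res = _run(ethio, stirring=stirring, dt=0.01, t_end=45.0)
    d = ethio.drug
    a = ethio.app
    _, _, _, mc = euler_oracle(
        Cs=d.solubility_Cs, IDR=d.intrinsic_dissolution_rate_IDR,
        d0=d.initial_diameter_d0, rho=d.density_rho,
        Pexp=d.permeability_exp_Pexp, hexp=d.membrane_thickness_exp_hexp,
        hm=a.membrane_thickness_hm, S=a.membrane_area_S,
        Vd=a.mucus_volume_Vd, Vr=a.receiver_volume_Vr, Q=a.perfusate_flow_Q,
        M0=ethio.run.dose_M0, particles=True,
        well_stirred=(stirring == "well_stirred"), t_end=45.0, dt=1e-3)
    oracle_pct = 100.0 * mc / ethio.run.dose_M0
    assert res.pct_collected[-1] == pytest.approx(oracle_pct, abs=0.1)


def test_euler_converges_to_rk4_under_step_halving(moxi):
    r1 = _run(moxi, integrator="euler", dt=0.02, t_end=60.0)
    r2 = _run(moxi, integrator="euler", dt=0.002, t_end=60.0)
    r3 = _run(moxi, integrator="rk4", dt=0.02, t_end=60.0)
    assert abs(r2.pct_collected[-1] - r3.pct_collected[-1]) < \
        abs(r1.pct_collected[-1] - r3.pct_collected[-1]) + 1e-12
    assert r2.pct_collected[-1] == pytest.approx(r3.pct_collected[-1], abs=0.1)


def test_unstirred_never_ahead_of_well_stirred(ethio):
    rw = _run(ethio, stirring="well_stirred", **FAST)
    ru = _run(ethio, stirring="unstirred", **FAST)
    assert np.all(ru.pct_collected <= rw.pct_collected + 1e-9)


def test_fast_dissolution_converges_to_solution_run(moxi):
    """Scaling the intrinsic dissolution rate up by 1000x makes the particle
    run indistinguishable from the pre-dissolved run — the mechanism behind
    the freely soluble drug's superimposed profiles. (Only meaningful for a
    dose the film can fully solubilize: a suspension can never exceed Cs,
    while a pre-dissolved dose may start supersaturated.)"""
    fast_drug = moxi.drug.replace(
        intrinsic_dissolution_rate_IDR=moxi.drug.intrinsic_dissolution_rate_IDR * 1e3)
    run = moxi.run.replace(**FAST)
    rp = simulate(fast_drug, moxi.app, run)
    rs = simulate(fast_drug, moxi.app, run.replace(dose_form="solution"))
    assert np.max(np.abs(rp.pct_collected - rs.pct_collected)) < 0.5


def test_derivatives_zero_dose_state_is_stationary(moxi):
    state = SystemState(0.0, 0.0, 0.0, 0.0, 0.0)
    rates = derivatives(state, moxi.drug, moxi.app, moxi.run)
    assert rates == (0.0, 0.0, 0.0, 0.0)


def test_derivatives_absorbing_state(moxi):
    run = moxi.run.replace(dose_form="solution")
    state = SystemState(120.0, 0.0, 0.0, 0.0, run.dose_M0)
    assert derivatives(state, moxi.drug, moxi.app, run) == (0.0, 0.0, 0.0, 0.0)


def test_derivatives_initial_solution_permeation_rate(moxi):
    run = moxi.run.replace(dose_form="solution")
    state = SystemState(0.0, 0.0, run.dose_M0, 0.0, 0.0)
    _, d_diss, d_recv, _ = derivatives(state, moxi.drug, moxi.app, run)
    assert d_recv == pytest.approx(1.768e-6, rel=1e-3)
    assert d_diss == pytest.approx(-1.768e-6, rel=1e-3)
    rates = derivatives(state, moxi.drug, moxi.app, run)
    assert sum(rates) == pytest.approx(0.0, abs=1e-20)


def test_derivatives_rejects_invalid_state(moxi):
    with pytest.raises(InvalidStateError):
        derivatives(SystemState(0.0, float("nan"), 0.0, 0.0, 0.0),
                    moxi.drug, moxi.app, moxi.run)


def test_oversized_step_raises_integration_error(moxi):
    # Forward Euler at dt far beyond the donor/receiver equilibration
    # timescale of a tiny, unswept receiver: the step oscillation drives the
    # terminal stock negative, which must be reported, not silently clamped.
    app = moxi.app.replace(perfusate_flow_Q=0.0, receiver_volume_Vr=1e-3)
    run = moxi.run.replace(dose_form="solution", integrator="euler",
                           dt=10.0, t_end=100.0)
    with pytest.raises(IntegrationError) as excinfo:
        simulate(moxi.drug, app, run)
    assert excinfo.value.step is not None


class TestTimeToFraction:
    @staticmethod
    def _fake_result(times, pct):
        times = np.asarray(times, dtype=float)
        pct = np.asarray(pct, dtype=float)
        zeros = np.zeros_like(times)
        return SimulationResult(
            times=times, mass_solid=zeros, mass_dissolved=zeros,
            mass_receiver=zeros, mass_collected=pct * 1e-6 / 100,
            donor_conc=zeros, receiver_conc=zeros, particle_diameter=zeros,
            surface_area=zeros, permeability_coeff=zeros,
            depletion_thickness=zeros, pct_collected=pct,
            metadata={"run": {"dose_M0": 1e-6}})

    def test_interpolates_between_stored_points(self):
        res = self._fake_result([0.0, 1.0, 2.0], [0.0, 50.0, 100.0])
        assert time_to_fraction(res, 0.5) == pytest.approx(1.0)
        assert time_to_fraction(res, 0.25) == pytest.approx(0.5)

    def test_not_reached_returns_none(self):
        res = self._fake_result([0.0, 1.0, 2.0], [0.0, 10.0, 20.0])
        assert time_to_fraction(res, 0.5) is None

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, fraction):
        res = self._fake_result([0.0, 1.0], [0.0, 100.0])
        with pytest.raises(InvalidParameterError):
            time_to_fraction(res, fraction)

    def test_simulation_hits_expected_window(self, ethio):
        # Sink closed form predicts ~44 min plus receiver lag for 99%.
        res = _run(ethio, dose_form="solution", t_end=90.0, dt=0.02)
        t99 = res.time_to_fraction(0.99)
        assert t99 is not None and 40.0 <= t99 <= 60.0


def test_result_accessors_consistent(moxi):
    res = _run(moxi, t_end=10.0, dt=0.02)
    frame = res.to_frame()
    assert len(frame) == len(res.times)
    states = res.states
    snaps = res.snapshots
    assert states[0].mass_solid == pytest.approx(res.dose_M0)
    assert snaps[0].particle_diameter_dt == pytest.approx(
        moxi.drug.initial_diameter_d0)
    assert "version" in res.metadata["software"]
    assert "moxifloxacin" in res.summary()
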