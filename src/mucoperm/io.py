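"""Configuration files, time-series CSV output, and test-fixture generation.

Configuration is YAML with units spelled out in the key names (µL, µm, µg,
mg mL^-1, mL min^-1 — the units a bench scientist records); values are
converted to the internal cm–g–min system exactly once on load. Unknown keys
are rejected by name so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from . import units
from .exceptions import ConfigError, InvalidParameterError
from .fitting import ConcentrationSeries
from .params import ApparatusParams, DrugParams, RunSpec
from .simulate import SimulationResult

__all__ = [
    "Preset",
    "FixtureSpec",
    "load_config",
    "write_timeseries",
    "read_timeseries",
    "write_concentration_csv",
    "read_concentration_csv",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# Apparatus used when generating fixtures: the Table-1 perfusion cell.
_FIXTURE_AREA_CM2 = 4.91
_FIXTURE_VD_CM3 = 25e-3
_FIXTURE_C0_G_CM3 = 2.0e-3  # 50 ug dissolved in 25 uL


@dataclass(frozen=True)
class Preset:
    """A fully specified scenario: drug + apparatus + run, with a label."""

    drug: DrugParams
    app: ApparatusParams
    run: RunSpec
    label: str = ""


_DRUG_KEYS = {
    "name",
    "solubility_mg_per_mL",
    "intrinsic_dissolution_rate_mg_per_cm2_min",
    "particle_diameter_um",
    "density_g_per_cm3",
    "permeability_exp_cm_per_min",
    "membrane_thickness_exp_um",
}
_APP_KEYS = {
    "membrane_area_cm2",
    "membrane_thickness_um",
    "mucus_volume_uL",
    "receiver_volume_uL",
    "perfusate_flow_mL_per_min",
}
_RUN_KEYS = {
    "dose_ug",
    "dose_form",
    "stirring",
    "t_end_min",
    "dt_min",
    "integrator",
    "output_stride_min",
}
_RUN_OPTIONAL = {"dose_form", "stirring", "t_end_min", "dt_min", "integrator",
                 "output_stride_min"}
_TOP_KEYS = {"label", "drug", "apparatus", "run"}


def _check_keys(section: str, data: dict, allowed: set, required: set) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {', '.join(unknown)}; "
            f"allowed: {', '.join(sorted(allowed))}")
    missing = sorted(required - set(data))
    if missing:
        raise ConfigError(f"missing key(s) in '{section}': {', '.join(missing)}")


def _number(section: str, data: dict, key: str) -> float:
    value = data[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"'{section}.{key}' must be a number, got {value!r}")
    return float(value)


def drug_from_dict(data: dict) -> DrugParams:
    """Build :class:`DrugParams` from a unit-suffixed mapping."""
    _check_keys("drug", data, _DRUG_KEYS, _DRUG_KEYS)
    try:
        return DrugParams(
            name=str(data["name"]),
            solubility_Cs=units.mg_per_mL_to_g_per_cm3(
                _number("drug", data, "solubility_mg_per_mL")),
            intrinsic_dissolution_rate_IDR=units.mg_per_mL_to_g_per_cm3(
                _number("drug", data, "intrinsic_dissolution_rate_mg_per_cm2_min")),
            initial_diameter_d0=units.um_to_cm(
                _number("drug", data, "particle_diameter_um")),
            density_rho=_number("drug", data, "density_g_per_cm3"),
            permeability_exp_Pexp=_number("drug", data, "permeability_exp_cm_per_min"),
            membrane_thickness_exp_hexp=units.um_to_cm(
                _number("drug", data, "membrane_thickness_exp_um")),
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"invalid drug parameters: {exc}") from exc


def apparatus_from_dict(data: dict) -> ApparatusParams:
    """Build :class:`ApparatusParams` from a unit-suffixed mapping."""
    _check_keys("apparatus", data, _APP_KEYS, _APP_KEYS)
    try:
        return ApparatusParams(
            membrane_area_S=_number("apparatus", data, "membrane_area_cm2"),
            membrane_thickness_hm=units.um_to_cm(
                _number("apparatus", data, "membrane_thickness_um")),
            mucus_volume_Vd=units.uL_to_cm3(
                _number("apparatus", data, "mucus_volume_uL")),
            receiver_volume_Vr=units.uL_to_cm3(
                _number("apparatus", data, "receiver_volume_uL")),
            perfusate_flow_Q=_number("apparatus", data, "perfusate_flow_mL_per_min"),
        )
    except InvalidParameterError as exc:
        raise ConfigError(f"invalid apparatus parameters: {exc}") from exc


def run_from_dict(data: dict) -> RunSpec:
    """Build :class:`RunSpec` from a unit-suffixed mapping."""
    _check_keys("run", data, _RUN_KEYS, _RUN_KEYS - _RUN_OPTIONAL)
    kwargs = {"dose_M0": units.ug_to_g(_number("run", data, "dose_ug"))}
    if "dose_form" in data:
        kwargs["dose_form"] = data["dose_form"]
    if "stirring" in data:
        kwargs["stirring"] = data["stirring"]
    if "t_end_min" in data:
        kwargs["t_end"] = _number("run", data, "t_end_min")
    if "dt_min" in data:
        kwargs["dt"] = _number("run", data, "dt_min")
    if "integrator" in data:
        kwargs["integrator"] = data["integrator"]
    if "output_stride_min" in data:
        kwargs["output_stride"] = _number("run", data, "output_stride_min")
    try:
        return RunSpec(**kwargs)
    except (InvalidParameterError, ValueError) as exc:
        raise ConfigError(f"invalid run parameters: {exc}") from exc


def load_config(path: PathLike) -> Preset:
    """Load and validate a scenario configuration file.

    Raises :class:`~mucoperm.exceptions.ConfigError` naming missing, unknown
    or out-of-range fields.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("top-level", data, _TOP_KEYS, {"drug", "apparatus", "run"})
    preset = Preset(
        drug=drug_from_dict(data["drug"]),
        app=apparatus_from_dict(data["apparatus"]),
        run=run_from_dict(data["run"]),
        label=str(data.get("label", path.stem)),
    )
    logger.info("loaded config %s (label=%s)", path, preset.label)
    return preset


def write_timeseries(result: SimulationResult, path: PathLike) -> Path:
    """Write a simulation trajectory to CSV with a JSON metadata sidecar.

    Floats are rendered at full round-trip precision so a re-parse reproduces
    the stored values bit-for-bit. The sidecar is ``<path>.meta.json``.
    """
    path = Path(path)
    frame = result.to_frame()
    # shortest round-trip rendering so a re-parse reproduces float64 exactly
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    sidecar = path.with_name(path.name + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(result.metadata, fh, indent=2)
    logger.info("wrote %d rows to %s (+ %s)", len(frame), path, sidecar.name)
    return path


def read_timeseries(path: PathLike):
    """Read back a trajectory CSV as a :class:`pandas.DataFrame`.

    Uses the round-trip float parser so re-parsed values equal the stored
    float64 bit-for-bit.
    """
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic noisy donor-decay series.

    The series emulates the donor-side observable of a membrane permeation
    experiment: exponential concentration decay C(t) = C0 exp(-P S t / Vd) in
    the Table-1 perfusion cell, corrupted by multiplicative log-normal noise
    of scale ``noise_sigma`` (the noise model under which ln-linear
    regression sees additive Gaussian errors). The seed fully determines the
    output.
    """

    true_Pexp: float          # cm min^-1
    n_points: int = 30
    t_max: float = 60.0       # min
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.true_Pexp <= 0:
            raise InvalidParameterError(f"true_Pexp must be > 0, got {self.true_Pexp!r}")
        if self.n_points < 2:
            raise InvalidParameterError(f"n_points must be >= 2, got {self.n_points!r}")
        if self.t_max <= 0:
            raise InvalidParameterError(f"t_max must be > 0, got {self.t_max!r}")
        if self.noise_sigma < 0:
            raise InvalidParameterError(
                f"noise_sigma must be >= 0, got {self.noise_sigma!r}")


def generate_fixture(spec: FixtureSpec) -> ConcentrationSeries:
    """Generate a seeded synthetic donor concentration–time series."""
    times = np.linspace(0.0, spec.t_max, spec.n_points)
    decay = np.exp(-spec.true_Pexp * _FIXTURE_AREA_CM2 * times / _FIXTURE_VD_CM3)
    conc = _FIXTURE_C0_G_CM3 * decay
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        conc = conc * np.exp(rng.normal(0.0, spec.noise_sigma, size=conc.shape))
    return ConcentrationSeries(
        times=times, donor_concentrations=conc,
        donor_volume_Vd=_FIXTURE_VD_CM3, membrane_area_S=_FIXTURE_AREA_CM2)


def write_concentration_csv(series: ConcentrationSeries, path: PathLike) -> Path:
    """Write a donor concentration series as CSV (time_min, donor_conc_mg_per_mL)."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame({
        "time_min": series.times,
        "donor_conc_mg_per_mL": [units.g_per_cm3_to_mg_per_mL(c)
                                 for c in series.donor_concentrations],
    }).to_csv(path, index=False)
    return path


def read_concentration_csv(path: PathLike, donor_volume_uL: float = 25.0,
                           membrane_area_cm2: float = _FIXTURE_AREA_CM2,
                           ) -> ConcentrationSeries:
    """Read a donor concentration series from CSV.

    The file must have a header with columns ``time_min`` and
    ``donor_conc_mg_per_mL``. The donor volume and membrane area are supplied
    separately (they are properties of the apparatus, not of the assay trace).
    """
    import pandas as pd

    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"time_min", "donor_conc_mg_per_mL"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(
            f"{path}: missing column(s) {', '.join(sorted(missing))}")
    return ConcentrationSeries(
        times=frame["time_min"].to_numpy(dtype=float),
        donor_concentrations=units.mg_per_mL_to_g_per_cm3(1.0)
        * frame["donor_conc_mg_per_mL"].to_numpy(dtype=float),
        donor_volume_Vd=units.uL_to_cm3(donor_volume_uL),
        membrane_area_S=membrane_area_cm2)
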