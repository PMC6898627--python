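"""Permeability-coefficient estimation from donor concentration decay.

Under sink conditions the donor concentration of a membrane permeation
experiment decays exponentially,

    ln C_d(t) = ln C_d0 − (P S / V_d) t,

so an ordinary least-squares fit of ln C_d on t recovers the permeability
coefficient from the slope: P̂ = −slope · V_d / S. The late tail of a real
experiment departs from this line (receiver back-pressure, depleted donor),
so the fit is restricted to a window covering at most a configurable
cumulative-permeation fraction (default 80%) of the initial concentration
drop.

Model/results surface: :class:`PermeabilityRegression` wraps a
:class:`ConcentrationSeries`; :meth:`~PermeabilityRegression.fit` returns a
:class:`PermeabilityFit` with the estimate, intercept, R², and a
``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "ConcentrationSeries",
    "PermeabilityFit",
    "PermeabilityRegression",
    "estimate_Pexp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Donor concentration–time data with the apparatus constants of the assay.

    ``times`` in min (strictly increasing), ``donor_concentrations`` in
    g cm^-3 (non-negative), ``donor_volume_Vd`` in cm^3 and
    ``membrane_area_S`` in cm^2.
    """

    times: np.ndarray
    donor_concentrations: np.ndarray
    donor_volume_Vd: float
    membrane_area_S: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.donor_concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "donor_concentrations", conc)
        if times.ndim != 1 or conc.shape != times.shape:
            raise InvalidParameterError(
                "times and donor_concentrations must be 1-D and equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(conc < 0):
            raise InvalidParameterError("concentrations must be >= 0")
        if self.donor_volume_Vd <= 0 or self.membrane_area_S <= 0:
            raise InvalidParameterError(
                "donor_volume_Vd and membrane_area_S must be > 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PermeabilityFit:
    """Result of a ln-linear permeability regression.

    ``Pexp_hat`` (cm min^-1) is the permeability estimate, ``Cd0_hat``
    (g cm^-3) the back-extrapolated initial donor concentration,
    ``r_squared`` the coefficient of determination of the ln-linear fit,
    ``n_points_used`` the number of points inside the fit window, and
    ``window`` a human-readable description of the inclusion rule applied.
    """

    Pexp_hat: float
    Cd0_hat: float
    r_squared: float
    n_points_used: int
    window: str

    def summary(self) -> str:
        lines = [
            "Permeability regression (ln C_d vs t)",
            "=" * 45,
            f"P_exp estimate:   {self.Pexp_hat:.4g} cm/min",
            f"C_d0 estimate:    {self.Cd0_hat * 1e3:.4g} mg/mL",
            f"R^2:              {self.r_squared:.6f}",
            f"points used:      {self.n_points_used}",
            f"window:           {self.window}",
        ]
        return "\n".join(lines)


class PermeabilityRegression:
    """Ln-linear permeability estimator for one concentration series.

    Parameters
    ----------
    series
        Donor concentration decay data.
    window_fraction
        Points are included while the cumulative permeated fraction
        1 − C/C(0) stays at or below this value (default 0.8, i.e. the fit
        covers the first 80% of the concentration drop).
    min_points
        Minimum number of usable (positive-concentration, in-window) points;
        below it the fit refuses with an insufficient-data error. Two points
        determine a line exactly, so tests may relax this to 2.
    """

    def __init__(self, series: ConcentrationSeries, window_fraction: float = 0.8,
                 min_points: int = 3):
        if not 0.0 < window_fraction <= 1.0:
            raise InvalidParameterError(
                f"window_fraction must lie in (0, 1], got {window_fraction!r}")
        if min_points < 2:
            raise InvalidParameterError(
                f"min_points must be >= 2, got {min_points!r}")
        self.series = series
        self.window_fraction = window_fraction
        self.min_points = min_points

    def fit(self) -> PermeabilityFit:
        """Run the regression and return the fit results."""
        series = self.series
        times = series.times
        conc = series.donor_concentrations
        if len(series) == 0:
            raise InsufficientDataError("empty concentration series")

        c0 = conc[0]
        if c0 <= 0:
            raise InsufficientDataError(
                "initial concentration must be > 0 to define the fit window")
        # Cumulative permeated fraction from the donor trace itself.
        permeated = 1.0 - conc / c0
        in_window = permeated <= self.window_fraction

        nonpositive = in_window & (conc <= 0)
        if np.any(nonpositive):
            warnings.warn(
                f"excluding {int(nonpositive.sum())} non-positive "
                f"concentration(s) from the ln-linear fit", stacklevel=2)
            logger.warning("excluded %d non-positive concentrations",
                           int(nonpositive.sum()))
        usable = in_window & (conc > 0)

        n_used = int(usable.sum())
        if n_used < self.min_points:
            raise InsufficientDataError(
                f"only {n_used} usable point(s) inside the fit window; "
                f"need at least {self.min_points}")

        t_fit = times[usable]
        log_c = np.log(conc[usable])
        fit = stats.linregress(t_fit, log_c)
        slope = float(fit.slope)
        Pexp_hat = -slope * series.donor_volume_Vd / series.membrane_area_S
        r_squared = float(fit.rvalue) ** 2 if len(t_fit) > 2 else 1.0
        window = (f"cumulative permeation <= {self.window_fraction:.0%} "
                  f"(t in [{t_fit[0]:g}, {t_fit[-1]:g}] min)")
        return PermeabilityFit(
            Pexp_hat=Pexp_hat,
            Cd0_hat=float(np.exp(fit.intercept)),
            r_squared=r_squared,
            n_points_used=n_used,
            window=window,
        )


def estimate_Pexp(series: ConcentrationSeries, window_fraction: float = 0.8,
                  min_points: int = 3) -> PermeabilityFit:
    """Estimate the permeability coefficient from donor decay data.

    Convenience wrapper around
    ``PermeabilityRegression(series, window_fraction, min_points).fit()``.
    """
    return PermeabilityRegression(series, window_fraction, min_points).fit()
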