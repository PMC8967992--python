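"""1D Gaussian fitting with the FWHM = 2.355 x SD convention.

Used for single-NPC lateral size, exclusion-zone dips and averaged profiles.
All fits share :class:`GaussianFit`, which carries the fitted parameters,
their asymptotic standard errors, and a convergence flag; non-convergent fits
are returned flagged rather than raised, so callers can exclude them from
averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: FWHM of a Gaussian in units of its SD: 2 * sqrt(2 ln 2), printed as 2.355.
FWHM_FACTOR = 2.355


@dataclass
class GaussianFit:
    """Result of a 1D Gaussian (+ constant baseline) fit.

    ``fwhm_nm`` is always exactly ``2.355 * sd_nm``; the 95% CI on the FWHM
    is ``2.355 * (sd +- 1.96 * se_sd)`` from the fit covariance.
    """

    amplitude: float
    center_nm: float
    sd_nm: float
    baseline: float
    se_sd_nm: float
    converged: bool
    inverted: bool = False

    @property
    def fwhm_nm(self) -> float:
        return FWHM_FACTOR * self.sd_nm

    @property
    def fwhm_ci95_nm(self) -> tuple[float, float]:
        lo = FWHM_FACTOR * (self.sd_nm - 1.96 * self.se_sd_nm)
        hi = FWHM_FACTOR * (self.sd_nm + 1.96 * self.se_sd_nm)
        return (lo, hi)


def _model(x, amp, center, sd, baseline):
    return baseline + amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _failed(x: np.ndarray, y: np.ndarray, inverted: bool) -> GaussianFit:
    return GaussianFit(0.0, float(np.mean(x)), np.nan, float(np.mean(y)),
                       np.nan, converged=False, inverted=inverted)


def fit_gaussian_1d(positions_nm: np.ndarray, values: np.ndarray,
                    inverted: bool = False) -> GaussianFit:
    """Least-squares fit of ``baseline + amp * exp(-(x-c)^2 / 2 sd^2)``.

    With ``inverted=True`` the amplitude is constrained negative (a dip);
    the reported ``amplitude`` is then the dip depth (positive).

    Degenerate inputs (flat data, no curvature) return a flagged,
    non-converged fit with zero amplitude instead of raising.
    """
    x = np.asarray(positions_nm, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 5:
        return _failed(x, y, inverted)
    span = float(y.max() - y.min())
    if span <= 0 or not np.isfinite(span):
        return _failed(x, y, inverted)

    if inverted:
        amp0 = -span
        c0 = x[int(np.argmin(y))]
        base0 = float(np.max(y))
        bounds = ([-np.inf, x.min(), 1e-6, -np.inf], [0.0, x.max(), np.ptp(x), np.inf])
    else:
        amp0 = span
        c0 = x[int(np.argmax(y))]
        base0 = float(np.min(y))
        bounds = ([0.0, x.min(), 1e-6, -np.inf], [np.inf, x.max(), np.ptp(x), np.inf])
    sd0 = max(np.ptp(x) / 10.0, 1e-3)
    try:
        popt, pcov = curve_fit(_model, x, y, p0=[amp0, c0, sd0, base0],
                               bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return _failed(x, y, inverted)
    amp, center, sd, baseline = popt
    se_sd = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.nan
    # An amplitude indistinguishable from zero is a degenerate (flat) fit.
    if abs(amp) < 1e-12 * max(1.0, abs(baseline)) or sd <= 0:
        return _failed(x, y, inverted)
    return GaussianFit(
        amplitude=float(abs(amp)), center_nm=float(center), sd_nm=float(sd),
        baseline=float(baseline), se_sd_nm=se_sd, converged=True, inverted=inverted,
    )
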