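"""Hyperbolic (Langmuir) binding-isotherm fitting and cytometry summaries.

The membrane surface fraction of a peripheral protein at bulk concentration C
follows, for non-cooperative binding,

    Phi(C) = Phi_max * C / (C + Kd),

with Phi_max the saturating surface fraction (percent) and Kd the dissociation
constant (uM). Kd can be fitted with Phi_max free or fixed (coverage data are
often reported against a known saturation level such as Phi_max = 12%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

KD_BOUNDS_UM = (1e-4, 1e4)


def langmuir(c, phi_max, kd):
    """Phi(C) = Phi_max * C / (C + Kd)."""
    c = np.asarray(c, dtype=float)
    return phi_max * c / (c + kd)


@dataclass
class BindingFit:
    """Result of a hyperbolic binding fit."""

    phi_max: float
    kd: float
    phi_max_fixed: bool
    covariance: np.ndarray
    residuals: np.ndarray = field(repr=False)

    def predict(self, c):
        return langmuir(c, self.phi_max, self.kd)


def fit_langmuir(table: pd.DataFrame,
                 fix_phi_max: float | None = None) -> BindingFit:
    """Fit Phi(C) = Phi_max*C/(C+Kd) by unweighted nonlinear least squares.

    Parameters
    ----------
    table : DataFrame with columns ``concentration_um`` and ``phi_percent``.
    fix_phi_max : optional percent
        When given, Phi_max is held fixed and only Kd is fitted.

    The fit is bounded (Kd in [1e-4, 1e4] uM, Phi_max in (0, 100]) and
    multi-started from three log-spaced Kd initializations to avoid local
    minima; the best (lowest SSR) solution is kept. At least three
    concentration points are required, and a warning-free fit expects points
    on both sides of the apparent Kd.
    """
    c = np.asarray(table["concentration_um"], dtype=float)
    phi = np.asarray(table["phi_percent"], dtype=float)
    if c.size < 3:
        raise ValueError(
            "insufficient support: need >= 3 concentration points to fit "
            "a two-parameter hyperbola")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")

    pos = c[c > 0]
    kd_inits = np.geomspace(max(pos.min(), KD_BOUNDS_UM[0]),
                            min(pos.max() * 2, KD_BOUNDS_UM[1]), 3)
    best = None
    for kd0 in kd_inits:
        try:
            if fix_phi_max is not None:
                popt, pcov = curve_fit(
                    lambda cc, kd: langmuir(cc, fix_phi_max, kd),
                    c, phi, p0=[kd0], bounds=([KD_BOUNDS_UM[0]],
                                              [KD_BOUNDS_UM[1]]))
                phi_max, kd = float(fix_phi_max), float(popt[0])
            else:
                phi0 = min(max(phi.max(), 1e-3), 100.0)
                popt, pcov = curve_fit(
                    langmuir, c, phi, p0=[phi0, kd0],
                    bounds=([1e-6, KD_BOUNDS_UM[0]], [100.0, KD_BOUNDS_UM[1]]))
                phi_max, kd = float(popt[0]), float(popt[1])
        except RuntimeError:
            continue
        resid = phi - langmuir(c, phi_max, kd)
        ssr = float(np.dot(resid, resid))
        if best is None or ssr < best[0]:
            best = (ssr, phi_max, kd, pcov, resid)
    if best is None:
        raise RuntimeError("Langmuir fit did not converge from any start")
    _, phi_max, kd, pcov, resid = best
    return BindingFit(phi_max=phi_max, kd=kd,
                      phi_max_fixed=fix_phi_max is not None,
                      covariance=np.atleast_2d(pcov), residuals=resid)


def predict_phi(fit: BindingFit, c) -> np.ndarray | float:
    """Evaluate the fitted hyperbola at bulk concentration(s) C >= 0 uM."""
    if np.any(np.asarray(c) < 0):
        raise ValueError("concentration must be >= 0")
    out = fit.predict(c)
    return float(out) if np.ndim(c) == 0 else out


def cytometry_median(intensities, threshold: float) -> float:
    """Median of the intensity distribution strictly above a threshold.

    Mirrors flow-cytometry gating of vesicle events: returns NaN (flagged
    empty) when no event passes the gate.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity list")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = x[x > threshold]
    if above.size == 0:
        return float("nan")
    return float(np.median(above))
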