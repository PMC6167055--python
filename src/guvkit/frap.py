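"""FRAP photobleaching correction and mobile-fraction estimation.

Acquisition photobleaching is corrected with an unbleached reference region
imaged under the same laser settings: the bleached-region intensity is
divided frame-by-frame by the reference intensity and rescaled so a fully
recovered signal reads 1 relative to the pre-bleach level. A single
exponential

    y(t) = y0 + M * (1 - exp(-t / tau))

is then fitted to the corrected curve; the mobile fraction is M / (1 - y0)
(the recovered share of the bleached signal), clipped to [0, 1]. The
recovery time tau is a nuisance parameter. Traces are analyzed one at a
time — recovery curves from different vesicles are not averaged — with a
separate pooling summary across per-trace estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class FrapTrace:
    """Background-subtracted FRAP intensities (frame 0 = first post-bleach).

    ``prebleach`` is the bleached-region intensity before the bleach pulse;
    ``reference`` is an unbleached region used for acquisition-bleaching
    correction. Its own pre-bleach level defaults to ``prebleach`` (regions
    chosen at comparable signal), but can be given separately.
    """

    times_s: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray
    prebleach: float
    reference_prebleach: float | None = None

    def __post_init__(self) -> None:
        t, b, r = (np.asarray(a, dtype=float)
                   for a in (self.times_s, self.bleached, self.reference))
        if not (len(t) == len(b) == len(r)):
            raise ValueError("times, bleached and reference must align")
        if self.prebleach <= 0:
            raise ValueError("prebleach must be > 0")
        self.times_s, self.bleached, self.reference = t, b, r


def correct_and_normalize(trace: FrapTrace) -> np.ndarray:
    """Bleaching-corrected, pre-bleach-normalized recovery curve.

    out(t) = (bleached(t) / reference(t)) * (reference_prebleach / prebleach)

    Any per-frame multiplicative acquisition factor shared by both regions
    cancels exactly. Raises on non-positive reference values.
    """
    if np.any(trace.reference <= 0):
        raise ValueError("reference intensities must be > 0 for correction")
    ref_pre = (trace.reference_prebleach
               if trace.reference_prebleach is not None else trace.prebleach)
    return (trace.bleached / trace.reference) * (ref_pre / trace.prebleach)


def _recovery(t, y0, m, tau):
    return y0 + m * (1.0 - np.exp(-t / tau))


def fit_mobile_fraction(curve: np.ndarray, times_s: np.ndarray
                        ) -> tuple[float, float]:
    """Fit y(t) = y0 + M(1 - exp(-t/tau)); return (mobile_fraction, tau).

    Mobile fraction = M / (1 - y0), clipped to [0, 1]. Needs at least five
    post-bleach frames. A flat curve returns mobile fraction 0 with tau NaN.
    """
    y = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if len(y) != len(t):
        raise ValueError("curve and times must align")
    if len(y) < 5:
        raise ValueError("need >= 5 post-bleach frames")

    if np.allclose(y, y[0]):
        return 0.0, float("nan")

    span = max(y.max() - y.min(), 1e-12)
    t_span = max(t.max() - t.min(), 1e-12)
    p0 = [max(y[0], 0.0), span, t_span / 5.0]
    try:
        popt, _ = curve_fit(
            _recovery, t, y, p0=p0,
            bounds=([-0.5, 0.0, 1e-6], [1.5, 2.0, 100.0 * t_span]),
            maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"mobile-fraction fit did not converge: {exc}") from exc
    y0, m, tau = popt
    denom = 1.0 - y0
    mobile = m / denom if denom > 1e-9 else 1.0
    return float(np.clip(mobile, 0.0, 1.0)), float(tau)


def analyze_trace(trace: FrapTrace) -> dict:
    """Correct, normalize and fit one trace; returns a result record."""
    curve = correct_and_normalize(trace)
    mobile, tau = fit_mobile_fraction(curve, trace.times_s)
    return {"mobile_fraction": mobile, "tau_s": tau,
            "final_recovery": float(curve[-1])}


def pool_mobile_fractions(estimates) -> pd.Series:
    """Pooling summary (median, IQR, n) across per-trace estimates."""
    x = np.asarray(list(estimates), dtype=float)
    if x.size == 0:
        raise ValueError("no estimates to pool")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return pd.Series({"n": x.size, "median": med, "iqr": q3 - q1,
                      "mean": x.mean(),
                      "sd": x.std(ddof=1) if x.size > 1 else 0.0})
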