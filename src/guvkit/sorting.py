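"""Curvature sorting ratio and membrane-tube radius estimation.

The sorting ratio compares protein enrichment on a nanotube (highly curved)
with the flat vesicle it was pulled from, normalized by the membrane dye to
cancel the geometric tube/vesicle signal difference:

    S = (I_tube / I_vesicle)_protein / (I_tube / I_vesicle)_membrane.

S = 1 means no curvature preference, S > 1 curvature-driven enrichment, and
S = 0 is the convention for tubes whose protein signal is below detection.

Tube radii come by three routes that agree on self-consistent data:
from membrane mechanics R = sqrt(kappa / (2 sigma)); from the tube-holding
force R = f / (4 pi sigma); and from fluorescence R = Rc * (I_tube /
I_vesicle)_membrane with a per-dye calibration factor Rc (200 +/- 50 nm for
BODIPY TR ceramide, 312 +/- 15 nm for GM1*, obtainable from force-calibrated
reference pairs via :func:`fit_rc`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .units import KBT_J, m_to_nm, tension_si

RC_BODIPY_TR_NM = 200.0
RC_BODIPY_TR_SD_NM = 50.0
RC_GM1_NM = 312.0
RC_GM1_SD_NM = 15.0

# Documented qualitative anchor for the inward-tubulation assay, where no
# force/lipid calibration exists: membrane ratio 0.3 ~ 20 nm, 0.4 ~ 30 nm
# tubule radius. Opt-in only; see ratio_to_radius_anchor.
IBAR_ANCHOR_RATIO_TO_NM = {0.3: 20.0, 0.4: 30.0}

DEFAULT_COVERAGE_EDGES = (0.0, 2.0, 5.0, np.inf)


@dataclass
class SortingMeasurement:
    """Background-subtracted tube/vesicle intensities for both channels."""

    i_tube_protein: float
    i_ves_protein: float
    i_tube_membrane: float
    i_ves_membrane: float
    phi_v_percent: float = np.nan
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.i_ves_protein <= 0 or self.i_ves_membrane <= 0:
            raise ValueError("vesicle intensities must be > 0")
        if self.i_tube_membrane <= 0:
            raise ValueError("membrane tube intensity must be > 0")
        if self.i_tube_protein < 0 and not self.below_detection:
            raise ValueError(
                "negative protein tube intensity only allowed when flagged "
                "below detection")


def sorting_ratio(m: SortingMeasurement) -> float:
    """Sorting ratio S; 0 when the tube protein signal is below detection."""
    if m.below_detection:
        return 0.0
    return ((m.i_tube_protein / m.i_ves_protein)
            / (m.i_tube_membrane / m.i_ves_membrane))


def radius_from_tension(kappa_j: float, sigma_mn_per_m: float) -> float:
    """Tube radius R = sqrt(kappa / (2 sigma)), nm.

    ``kappa_j`` is the bending rigidity in joules (use
    ``kappa_kbt * units.KBT_J`` for values quoted in kBT), ``sigma`` the
    membrane tension in mN/m.
    """
    if kappa_j <= 0 or sigma_mn_per_m <= 0:
        raise ValueError("kappa and sigma must be > 0")
    return m_to_nm(np.sqrt(kappa_j / (2.0 * tension_si(sigma_mn_per_m))))


def radius_from_force(f_pn: float, sigma_mn_per_m: float) -> float:
    """Tube radius R = f / (4 pi sigma), nm, from the tube-holding force (pN)."""
    if f_pn <= 0 or sigma_mn_per_m <= 0:
        raise ValueError("force and sigma must be > 0")
    return m_to_nm(f_pn * 1e-12 / (4.0 * np.pi * tension_si(sigma_mn_per_m)))


def radius_from_fluorescence(ratio: float, rc_nm: float = RC_BODIPY_TR_NM,
                             rc_sd_nm: float | None = None
                             ) -> float | tuple[float, float]:
    """Tube radius R = Rc * (I_tube/I_vesicle)_membrane, nm.

    With ``rc_sd_nm`` given, returns (R, SD) with the calibration uncertainty
    propagated linearly.
    """
    if ratio <= 0 or rc_nm <= 0:
        raise ValueError("ratio and Rc must be > 0")
    r = rc_nm * ratio
    if rc_sd_nm is None:
        return r
    return r, rc_sd_nm * ratio


def ratio_to_radius_anchor(ratio: float) -> float:
    """Approximate tubule radius (nm) for the inward-tubulation assay.

    Affine-through-origin interpolation of the documented anchor points
    (membrane ratio 0.3 -> ~20 nm, 0.4 -> ~30 nm, slope ~67 nm per unit
    ratio about them). Qualitative; use only where no lipid-calibration
    factor exists.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    ratios = np.array(sorted(IBAR_ANCHOR_RATIO_TO_NM))
    radii = np.array([IBAR_ANCHOR_RATIO_TO_NM[r] for r in ratios])
    slope = float(np.dot(ratios, radii) / np.dot(ratios, ratios))
    return slope * ratio


def fit_rc(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Zero-intercept fit of reference radius vs membrane fluorescence ratio.

    ``pairs`` are (ratio, R_reference_nm), the reference radii measured
    independently (force route). Returns (Rc, SD of the slope).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (ratio, radius) pairs")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("degenerate calibration: all ratios are zero")
    rc = float(np.dot(x, y)) / sxx
    resid = y - rc * x
    dof = max(len(x) - 1, 1)
    sd = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return rc, sd


def bin_by_coverage(measurements: Sequence[SortingMeasurement],
                    bin_edges: Sequence[float] = DEFAULT_COVERAGE_EDGES
                    ) -> pd.DataFrame:
    """Group sorting measurements by vesicle coverage and summarize S.

    Bins are half-open [lo, hi) over ``phi_v_percent``; the defaults
    (0-2, 2-5, >5 %) follow the conventional low/intermediate/high coverage
    classes. Dispersion summaries (mean, SD, min, max) exclude S = 0
    (below-detection) values, which are tallied separately; a bin with only
    S = 0 entries is flagged ``no detected sorting``. Measurements outside
    all bins land in an ``unbinned`` group.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    for m in measurements:
        s = sorting_ratio(m)
        phi = m.phi_v_percent
        idx = np.searchsorted(edges, phi, side="right") - 1
        if np.isnan(phi) or idx < 0 or idx >= len(edges) - 1:
            label = "unbinned"
        else:
            hi = edges[idx + 1]
            hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
            label = f"[{edges[idx]:g}, {hi_s})%"
        rows.append({"bin": label, "phi_v_percent": phi, "S": s})
    df = pd.DataFrame(rows)
    out = []
    for label, grp in df.groupby("bin", sort=False):
        s = grp["S"].to_numpy()
        detected = s[s > 0]
        rec = {"bin": label, "n": len(s), "n_below_detection": int((s == 0).sum())}
        if detected.size:
            rec.update(mean_S=detected.mean(),
                       sd_S=detected.std(ddof=1) if detected.size > 1 else 0.0,
                       min_S=detected.min(), max_S=detected.max(),
                       no_detected_sorting=False)
        else:
            rec.update(mean_S=np.nan, sd_S=np.nan, min_S=np.nan, max_S=np.nan,
                       no_detected_sorting=True)
        out.append(rec)
    return pd.DataFrame(out)
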