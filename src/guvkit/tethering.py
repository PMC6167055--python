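"""GUV-GUV tethering energetics from the contact force balance.

When two protein-decorated vesicles adhere, the test vesicle (held at tension
sigma) deforms against the high-tension spherical reference vesicle; the
contact angle theta satisfies the force balance

    sigma * cos(theta) = sigma - gamma,

so the adhesion (tethering) energy per unit contact area is
gamma = sigma * (1 - cos theta). Dividing gamma by the areal density of
molecular bonds in the contact zone (protein dimers for ezrin-like tethers,
streptavidin molecules for biotin-streptavidin references) gives the energy
per bond, expressed in kBT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .density import SurfaceDensityCalibration, protein_density
from .units import joules_to_kbt, per_um2_to_per_m2, tension_si


@dataclass
class TetherGeometry:
    """One measured two-vesicle contact.

    ``sigma_test_mn_per_m`` is the (adjustable) tension of the deformable
    test vesicle; the reference vesicle is kept at high tension (> 0.4 mN/m)
    to stay spherical, recorded as metadata only.
    """

    sigma_test_mn_per_m: float
    theta_rad: float
    contact_area_um2: float = np.nan
    protein_intensity_at_zone: float = np.nan
    sigma_reference_mn_per_m: float = np.nan

    def __post_init__(self) -> None:
        if self.sigma_test_mn_per_m <= 0:
            raise ValueError("sigma_test must be > 0")
        if not (0 <= self.theta_rad < np.pi / 2):
            raise ValueError("theta must be in [0, pi/2)")


def gamma_from_angle(sigma_mn_per_m: float, theta_rad: float) -> float:
    """Tethering energy per area, J/m^2, from the contact force balance."""
    if sigma_mn_per_m <= 0:
        raise ValueError("sigma must be > 0")
    theta = np.asarray(theta_rad, dtype=float)
    if np.any((theta < 0) | (theta >= np.pi / 2)):
        raise ValueError("theta must be in [0, pi/2)")
    out = tension_si(sigma_mn_per_m) * (1.0 - np.cos(theta))
    return float(out) if np.ndim(theta_rad) == 0 else out


def energy_per_bond(gamma_j_m2: float, bond_density_per_um2: float) -> float:
    """Tethering energy per molecular bond, in kBT.

    ``bond_density_per_um2`` is the areal density of load-bearing bonds in
    the contact zone: half the protein monomer density for dimeric tethers,
    the streptavidin density for biotin-streptavidin.
    """
    if bond_density_per_um2 <= 0:
        raise ValueError("bond density must be > 0")
    e_j = gamma_j_m2 / per_um2_to_per_m2(bond_density_per_um2)
    return joules_to_kbt(e_j)


def bond_density_from_intensity(intensity: float,
                                cal: SurfaceDensityCalibration,
                                bonds_per_molecule: float = 0.5,
                                efficiency: float = 1.0) -> float:
    """Bond density (bonds/um^2) from contact-zone protein fluorescence.

    ``bonds_per_molecule`` is 0.5 for dimeric tethers (one bond per two
    monomers) and 1.0 for streptavidin. ``efficiency`` (<= 1) scales for the
    fraction of zone protein actually engaged; the default 1 assumes all
    protein in the zone contributes to tethering.
    """
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    return protein_density(intensity, cal) * bonds_per_molecule * efficiency


def contact_angle_from_points(contour_points, contact_line_points
                              ) -> tuple[float, float, float]:
    """Contact angle from clicked test-vesicle contour and contact-line points.

    Fits a least-squares (Kasa) circle to the vesicle contour, then takes the
    contact line as the chord through the two clicked contact points; the
    angle between membrane and contact plane at the contact line satisfies
    cos(theta) = d / R with d the center-to-chord distance.

    Returns (theta_rad, circle_radius, d).
    """
    pts = np.asarray(contour_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 contour points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b_vec = x ** 2 + y ** 2
    (cx, cy, c0), *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    radius = float(np.sqrt(c0 + cx ** 2 + cy ** 2))

    p1, p2 = (np.asarray(p, dtype=float) for p in contact_line_points)
    chord = p2 - p1
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("degenerate contact line (identical points)")
    # distance from circle center to the chord line (2-D cross product)
    v = np.array([cx, cy]) - p1
    d = float(abs(chord[0] * v[1] - chord[1] * v[0]) / norm)
    cos_theta = np.clip(d / radius, -1.0, 1.0)
    return float(np.arccos(cos_theta)), radius, d


def tension_series_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-tension summary of a (sigma, gamma, E_per_bond) series.

    Groups by unique test tension; reports median and IQR of gamma and of
    the per-bond energy, plus a Spearman rank correlation of gamma with
    sigma across all records (the monotonic tension-dependence statistic).
    The correlation is attached as ``spearman_rho`` / ``spearman_p`` in the
    result's ``attrs``.
    """
    req = {"sigma_mn_per_m", "gamma_j_m2", "energy_per_bond_kbt"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ValueError("empty record table")

    def iqr(v):
        return float(np.subtract(*np.percentile(v, [75, 25])))

    grouped = records.groupby("sigma_mn_per_m", sort=True)
    out = grouped.agg(
        n=("gamma_j_m2", "size"),
        median_gamma_j_m2=("gamma_j_m2", "median"),
        iqr_gamma_j_m2=("gamma_j_m2", iqr),
        median_energy_kbt=("energy_per_bond_kbt", "median"),
        iqr_energy_kbt=("energy_per_bond_kbt", iqr),
    ).reset_index()
    if records["gamma_j_m2"].nunique() > 1 and len(records) > 1:
        rho, p = stats.spearmanr(records["sigma_mn_per_m"],
                                 records["gamma_j_m2"])
    else:
        rho, p = 0.0, 1.0
    out.attrs["spearman_rho"] = float(rho)
    out.attrs["spearman_p"] = float(p)
    return out
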