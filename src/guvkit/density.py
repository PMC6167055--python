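"""Fluorescence-to-surface-density calibration via a reference lipid dye.

The chain converts a background-subtracted vesicle fluorescence intensity to
an absolute protein surface density and membrane surface fraction:

1. GUVs doped with known mole fractions of a fluorescent reference lipid
   (e.g. 0.04-0.16 mole% of BODIPY FL-C5-HPC, i.e. 1120-4480 dyes/um^2 at
   0.7 nm^2 per lipid over both leaflets) give a linear, zero-intercept
   relation n_dye = A * I_vesicle; the slope A (molecules/um^2 per a.u.)
   is per-illumination-setting and must be measured per dataset.
2. Protein density follows as n_protein = A * I_protein / (brightness_ratio
   * n*), where brightness_ratio is the dye-vs-reference intensity ratio at
   equal bulk concentration and n* the protein's degree of labeling.
3. Surface fraction is Phi = n_protein * a_protein (protein footprint,
   ~20 nm^2 for ezrin, ~50 nm^2 for the IRSp53 I-BAR domain), in percent.

Calibration intensities are treated as reporting dye in both leaflets, as the
1120-4480 /um^2 reference densities carry no leaflet correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

A_EZRIN_NM2 = 20.0
A_IBAR_NM2 = 50.0
LIPID_AREA_NM2 = 0.7


@dataclass
class SurfaceDensityCalibration:
    """Constants converting fluorescence to molecules/um^2 and coverage.

    Attributes
    ----------
    a_per_au : float
        Slope A of the reference-dye fit, (molecules/um^2) per a.u.
    brightness_ratio : float
        Protein-dye vs reference-dye intensity ratio at equal bulk
        concentration under identical acquisition.
    labeling_degree : float
        Dyes per protein molecule (n*).
    footprint_nm2 : float
        Membrane area of a single bound protein, nm^2.
    """

    a_per_au: float
    brightness_ratio: float = 1.0
    labeling_degree: float = 1.0
    footprint_nm2: float = A_EZRIN_NM2
    lipid_area_nm2: float = LIPID_AREA_NM2

    def __post_init__(self) -> None:
        for name in ("a_per_au", "brightness_ratio", "labeling_degree",
                     "footprint_nm2", "lipid_area_nm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def fit_hpc_calibration(pairs: Sequence[tuple[float, float]],
                        free_intercept: bool = False) -> float:
    """Fit the slope A of density = A * intensity through the origin.

    ``pairs`` are (dye_density_per_um2, vesicle_intensity_au). The default
    zero-intercept fit follows the n = A*I relation; ``free_intercept=True``
    fits an affine line instead (diagnostic only) and still returns the slope.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (density, intensity) pairs")
    dens, inten = arr[:, 0], arr[:, 1]
    if np.any(dens < 0) or np.any(inten < 0):
        raise ValueError("densities and intensities must be >= 0")
    if not np.any(inten > 0):
        raise ValueError("all intensities are zero; cannot fit a slope")
    if free_intercept:
        slope, _ = np.polyfit(inten, dens, 1)
        return float(slope)
    return float(np.dot(inten, dens) / np.dot(inten, inten))


def protein_density(i_protein: float, cal: SurfaceDensityCalibration) -> float:
    """Protein surface density, molecules/um^2, from vesicle intensity."""
    if np.any(np.asarray(i_protein) < 0):
        raise ValueError("intensity must be >= 0")
    return (cal.a_per_au * i_protein
            / (cal.brightness_ratio * cal.labeling_degree))


def surface_fraction(density_per_um2: float, footprint_nm2: float) -> float:
    """Membrane surface fraction Phi in percent from density and footprint.

    Phi = density * footprint; 1e6 nm^2 per um^2, times 100 for percent.
    Values above 100% are physically impossible (overlapping footprints)
    and raise.
    """
    if footprint_nm2 <= 0:
        raise ValueError("footprint_nm2 must be > 0")
    phi = np.asarray(density_per_um2, dtype=float) * footprint_nm2 * 1e-6 * 100.0
    if np.any(phi > 100.0):
        raise ValueError(f"nonphysical surface fraction {phi} > 100%")
    return float(phi) if np.ndim(density_per_um2) == 0 else phi


def density_from_fraction(phi_percent: float, footprint_nm2: float) -> float:
    """Inverse of :func:`surface_fraction` (molecules/um^2)."""
    if footprint_nm2 <= 0:
        raise ValueError("footprint_nm2 must be > 0")
    return phi_percent / 100.0 / (footprint_nm2 * 1e-6)
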