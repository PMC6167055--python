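"""Synthetic data generation for the whole analysis chain.

Every input the pipeline consumes — confocal-like two-channel images of GUVs
with pulled nanotubes, binding titrations, FRAP time series, two-vesicle
tethering geometries and nanotube class counts — can be generated here from
known ground-truth parameters, so each downstream estimator is testable by
parameter recovery.

The image model is deliberately minimal: a single equatorial confocal section
in which the vesicle membrane is an anti-aliased circle of ~1.5 px line width
and the nanotube a straight segment leaving the vesicle edge, both rendered as
Gaussian cross-sections, then blurred by a Gaussian PSF, corrupted with
additive Gaussian read noise and offset by a constant background. This matches
the line-profile quantification geometry used downstream; it does not attempt
realistic confocal optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .units import tension_si

# Gaussian cross-section sigma of rendered membrane structures, px.
# Corresponds to a 1-2 px apparent line width before PSF blur.
_LINE_SIGMA_PX = 0.7

_SCENE_KINDS = ("guv_with_tube", "two_guv_contact", "guv_only")


@dataclass
class SyntheticScene:
    """Ground-truth parameter bundle for one rendered two-channel image.

    Intensities are in arbitrary camera units; ``gain_membrane`` and
    ``gain_protein`` are the peak amplitudes (above background) of the vesicle
    membrane in each channel for unit dye/protein density. The nanotube peak
    in the membrane channel is ``gain_membrane * tube_ratio_membrane`` and in
    the protein channel ``gain_protein * tube_ratio_membrane * sorting_true``,
    so the ground-truth sorting ratio of the scene is ``sorting_true`` by
    construction.
    """

    scene_kind: str = "guv_with_tube"
    guv_radius_um: float = 3.0
    tube_ratio_membrane: float = 0.3
    sorting_true: float = 1.0
    psf_sigma_px: float = 1.0
    background_level: float = 100.0
    noise_sd: float = 5.0
    gain_membrane: float = 2000.0
    gain_protein: float = 1500.0
    pixel_size_um: float = 0.1
    shape: tuple[int, int] = (128, 160)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene_kind not in _SCENE_KINDS:
            raise ValueError(f"scene_kind must be one of {_SCENE_KINDS}")
        if self.guv_radius_um <= 0:
            raise ValueError("guv_radius_um must be > 0")
        if not (0 < self.tube_ratio_membrane <= 1):
            raise ValueError("tube_ratio_membrane must be in (0, 1]")
        if self.sorting_true < 0:
            raise ValueError("sorting_true must be >= 0")
        if self.psf_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma_px and noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def guv_radius_px(self) -> float:
        return self.guv_radius_um / self.pixel_size_um


def _dist_to_circle(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                    r: float) -> np.ndarray:
    return np.abs(np.hypot(yy - cy, xx - cx) - r)


def _dist_to_hsegment(yy: np.ndarray, xx: np.ndarray, y0: float, x0: float,
                      x1: float) -> np.ndarray:
    """Distance to a horizontal segment from (y0, x0) to (y0, x1)."""
    xc = np.clip(xx, min(x0, x1), max(x0, x1))
    return np.hypot(yy - y0, xx - xc)


def _dist_to_vsegment(yy: np.ndarray, xx: np.ndarray, x0: float, y0: float,
                      y1: float) -> np.ndarray:
    yc = np.clip(yy, min(y0, y1), max(y0, y1))
    return np.hypot(yy - yc, xx - x0)


def _gauss_line(dist: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * (dist / _LINE_SIGMA_PX) ** 2)


def render_scene(scene: SyntheticScene) -> tuple[np.ndarray, dict]:
    """Render a two-channel confocal-like image from ground truth.

    Returns
    -------
    image : float ndarray, shape (2, H, W)
        Channel 0 is the membrane dye, channel 1 the labeled protein.
    record : dict
        Ground-truth geometry (px) and intensity ratios, including suggested
        perpendicular profile lines for the vesicle and (if present) the tube,
        each long enough for the rectangle background rule.

    Raises
    ------
    ValueError
        If the vesicle does not fit in the frame or the tube would be shorter
        than a usable ROI.
    """
    h, w = scene.shape
    r = scene.guv_radius_px
    margin = 6.0 + 4.0 * scene.psf_sigma_px

    if scene.scene_kind == "guv_with_tube":
        cy, cx = h / 2.0, w / 3.0
    elif scene.scene_kind == "guv_only":
        cy, cx = h / 2.0, w / 2.0
    else:  # two_guv_contact: two vesicles touching at the frame center
        cy, cx = h / 2.0, w / 2.0 - r

    if cy - r < margin or cy + r > h - margin or cx - r < margin:
        raise ValueError(
            f"GUV radius {r:.1f} px does not fit in a {h}x{w} frame "
            f"with margin {margin:.1f} px")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    membrane = np.zeros((h, w))
    protein = np.zeros((h, w))

    record: dict = {
        "scene_kind": scene.scene_kind,
        "guv_center_px": (cy, cx),
        "guv_radius_px": r,
        "tube_ratio_membrane": scene.tube_ratio_membrane,
        "sorting_true": scene.sorting_true,
        "vesicle_peak_membrane": scene.gain_membrane,
        "vesicle_peak_protein": scene.gain_protein,
        "background_level": scene.background_level,
        "noise_sd": scene.noise_sd,
    }

    d_circle = _dist_to_circle(yy, xx, cy, cx, r)
    membrane += _gauss_line(d_circle, scene.gain_membrane)
    protein += _gauss_line(d_circle, scene.gain_protein)

    # Perpendicular profile across the vesicle membrane at its top pole,
    # long enough for the 15+15 rectangle background rule.
    half = 20
    record["vesicle_profile_line"] = ((cy - r - half, cx), (cy - r + half, cx))

    if scene.scene_kind == "guv_with_tube":
        x0, x1 = cx + r, w - margin
        if x1 - x0 < 12:
            raise ValueError(
                "tube does not fit in the frame: increase image width or "
                "decrease GUV radius")
        d_tube = _dist_to_hsegment(yy, xx, cy, x0, x1)
        tube_mem = scene.gain_membrane * scene.tube_ratio_membrane
        tube_pro = tube_mem / scene.gain_membrane * scene.gain_protein \
            * scene.sorting_true
        membrane += _gauss_line(d_tube, tube_mem)
        protein += _gauss_line(d_tube, tube_pro)
        xm = 0.5 * (x0 + x1)
        record.update({
            "tube_row_px": cy,
            "tube_x_span_px": (x0, x1),
            "tube_peak_membrane": tube_mem,
            "tube_peak_protein": tube_pro,
            "tube_profile_line": ((cy - half, xm), (cy + half, xm)),
        })
    elif scene.scene_kind == "two_guv_contact":
        cx2 = cx + 2 * r
        if cx2 + r > w - margin:
            raise ValueError("second GUV does not fit in the frame")
        d2 = _dist_to_circle(yy, xx, cy, cx2, r)
        membrane += _gauss_line(d2, scene.gain_membrane)
        protein += _gauss_line(d2, scene.gain_protein)
        # Protein enrichment along the contact chord between the vesicles.
        xt = cx + r
        chord = 0.6 * r
        d_contact = _dist_to_vsegment(yy, xx, xt, cy - chord / 2, cy + chord / 2)
        protein += _gauss_line(d_contact, 2.0 * scene.gain_protein)
        record.update({
            "guv2_center_px": (cy, cx2),
            "contact_x_px": xt,
            "contact_profile_line": ((cy, xt - 15), (cy, xt + 15)),
        })

    image = np.stack([membrane, protein])
    if scene.psf_sigma_px > 0:
        image = np.stack([
            ndimage.gaussian_filter(ch, scene.psf_sigma_px) for ch in image])
    rng = np.random.default_rng(scene.seed)
    if scene.noise_sd > 0:
        image = image + rng.normal(0.0, scene.noise_sd, size=image.shape)
    image = image + scene.background_level
    return image, record


@dataclass
class TitrationTruth:
    """Ground truth for a hyperbolic (Langmuir) binding titration.

    ``phi_max`` is the saturating membrane surface fraction in percent and
    ``kd`` the dissociation constant in uM; measured coverages carry
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.
    """

    phi_max: float = 12.0
    kd: float = 1.2
    concentrations_um: Sequence[float] = field(
        default_factory=lambda: tuple(np.geomspace(0.02, 4.0, 8)))
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.phi_max <= 100):
            raise ValueError("phi_max must be in (0, 100]")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        c = np.asarray(self.concentrations_um, dtype=float)
        if c.size == 0:
            raise ValueError("concentrations_um must be non-empty")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")


def simulate_titration(truth: TitrationTruth) -> pd.DataFrame:
    """Simulate one noisy titration table (concentration_um, phi_percent)."""
    c = np.asarray(truth.concentrations_um, dtype=float)
    rng = np.random.default_rng(truth.seed)
    phi = truth.phi_max * c / (c + truth.kd)
    if truth.noise_cv > 0:
        phi = phi * (1.0 + rng.normal(0.0, truth.noise_cv, size=c.shape))
    return pd.DataFrame({"concentration_um": c, "phi_percent": phi})


@dataclass
class FrapTruth:
    """Ground truth for a FRAP trace with acquisition photobleaching.

    The underlying recovery is single-exponential,
    ``M(t) = mobile_fraction * (1 - exp(-t / recovery_tau))`` (full bleach at
    t=0), and both the bleached and the reference region decay by a factor
    ``(1 - acq_bleach_rate)`` per acquired frame.
    """

    mobile_fraction: float = 0.10
    recovery_tau_s: float = 5.0
    acq_bleach_rate: float = 0.005
    prebleach_level: float = 1000.0
    frame_interval_s: float = 0.5
    n_frames: int = 60
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mobile_fraction <= 1):
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be > 0")
        if not (0 <= self.acq_bleach_rate < 1):
            raise ValueError("acq_bleach_rate must be in [0, 1)")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.noise_sd < 0 or self.prebleach_level <= 0:
            raise ValueError("noise_sd >= 0 and prebleach_level > 0 required")


def frap_recovery_ideal(truth: FrapTruth, times: np.ndarray) -> np.ndarray:
    """Noiseless, bleach-free normalized recovery curve (closed form)."""
    return truth.mobile_fraction * (1.0 - np.exp(-times / truth.recovery_tau_s))


def simulate_frap(truth: FrapTruth) -> pd.DataFrame:
    """Simulate a FRAP table (time_s, bleached, reference).

    Frame 0 is the first post-bleach frame. Both regions share the per-frame
    acquisition bleaching; the reference region is unbleached by the FRAP
    pulse, so its un-decayed level equals ``prebleach_level``.
    """
    rng = np.random.default_rng(truth.seed)
    frames = np.arange(truth.n_frames)
    times = frames * truth.frame_interval_s
    decay = (1.0 - truth.acq_bleach_rate) ** frames
    bleached = truth.prebleach_level * frap_recovery_ideal(truth, times) * decay
    reference = truth.prebleach_level * decay
    if truth.noise_sd > 0:
        bleached = bleached + rng.normal(0, truth.noise_sd, size=times.shape)
        reference = reference + rng.normal(0, truth.noise_sd, size=times.shape)
        reference = np.maximum(reference, 1e-9)
    return pd.DataFrame(
        {"time_s": times, "bleached": bleached, "reference": reference})


@dataclass
class TetherTruth:
    """Ground truth for a two-vesicle tethering series.

    ``gamma_true_j_m2`` is the adhesion energy per unit contact area;
    ``n_pairs_per_um2`` the areal density of protein pair bonds in the
    contact zone. Contact angles follow the force balance
    ``cos(theta) = 1 - gamma / sigma`` plus Gaussian angle noise.
    """

    gamma_true_j_m2: float = 5e-6
    n_pairs_per_um2: float = 500.0
    angle_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_true_j_m2 < 0:
            raise ValueError("gamma_true_j_m2 must be >= 0")
        if self.n_pairs_per_um2 <= 0:
            raise ValueError("n_pairs_per_um2 must be > 0")
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be >= 0")


def simulate_tether_series(truth: TetherTruth,
                           sigmas_mn_per_m: Sequence[float],
                           calibration=None) -> pd.DataFrame:
    """Simulate (sigma_mn_per_m, theta_rad, protein_intensity) records.

    The protein-channel intensity at the contact zone is generated to be
    consistent with ``2 * n_pairs_per_um2`` protein monomers per um^2 (one
    pair bond per dimer) through the supplied surface-density calibration;
    with no calibration the intensity equals that monomer density in a.u.

    Raises
    ------
    ValueError
        If ``gamma_true >= sigma`` for any tension (impossible geometry:
        the force balance has no solution).
    """
    sig = np.asarray(sigmas_mn_per_m, dtype=float)
    sig_si = tension_si(sig)
    if np.any(truth.gamma_true_j_m2 >= sig_si):
        raise ValueError(
            "gamma_true must be < every test tension (sigma*cos(theta) = "
            "sigma - gamma has no contact angle otherwise)")
    rng = np.random.default_rng(truth.seed)
    theta = np.arccos(1.0 - truth.gamma_true_j_m2 / sig_si)
    if truth.angle_noise_sd > 0:
        theta = theta + rng.normal(0, truth.angle_noise_sd, size=sig.shape)
        theta = np.clip(theta, 0.0, np.pi / 2 - 1e-9)
    monomer_density = 2.0 * truth.n_pairs_per_um2
    if calibration is not None:
        intensity = (monomer_density * calibration.brightness_ratio
                     * calibration.labeling_degree / calibration.a_per_au)
    else:
        intensity = monomer_density
    return pd.DataFrame({
        "sigma_mn_per_m": sig,
        "theta_rad": theta,
        "protein_intensity": np.full(sig.shape, float(intensity)),
    })


def simulate_class_counts(probabilities: Sequence[float], n_tubes: int,
                          seed: int, labels: Sequence[str] | None = None
                          ) -> pd.Series:
    """Draw one multinomial nanotube class-count table.

    ``probabilities`` must sum to 1; ``labels`` default to class_0..class_k.
    """
    p = np.asarray(probabilities, dtype=float)
    if n_tubes < 0:
        raise ValueError("n_tubes must be >= 0")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_tubes, p)
    if labels is None:
        labels = [f"class_{i}" for i in range(p.size)]
    return pd.Series(counts, index=list(labels), name="count")
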