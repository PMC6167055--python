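"""End-to-end measurement helpers tying image extraction to the estimators."""

from __future__ import annotations

import numpy as np

from .profiles import LineRoi, extract_profile, peak_minus_background
from .sorting import SortingMeasurement, sorting_ratio


def measure_sorting_from_scene(image: np.ndarray, record: dict,
                               width: int = 6,
                               phi_v_percent: float = float("nan")
                               ) -> SortingMeasurement:
    """Measure a SortingMeasurement from a rendered tube-pulling scene.

    Uses the scene record's suggested perpendicular profile lines (vesicle
    pole and tube midpoint), the line background rule (6-px wide profile,
    pooled first/last 10 values) for every intensity, and the detection flag
    of the tube protein signal for the S = 0 convention.
    """
    if "tube_profile_line" not in record:
        raise ValueError("no tube ROI: scene was rendered without a tube")
    tube_line = LineRoi(*[tuple(p) for p in record["tube_profile_line"]],
                        width=width)
    ves_line = LineRoi(*[tuple(p) for p in record["vesicle_profile_line"]],
                       width=width)
    membrane, protein = np.asarray(image)[0], np.asarray(image)[1]

    i_ves_mem, _ = peak_minus_background(
        extract_profile(membrane, ves_line, "membrane"), rule="line")
    i_ves_pro, _ = peak_minus_background(
        extract_profile(protein, ves_line, "protein"), rule="line")
    i_tube_mem, _ = peak_minus_background(
        extract_profile(membrane, tube_line, "membrane"), rule="line")
    i_tube_pro, detected = peak_minus_background(
        extract_profile(protein, tube_line, "protein"), rule="line")

    return SortingMeasurement(
        i_tube_protein=max(i_tube_pro, 0.0),
        i_ves_protein=i_ves_pro,
        i_tube_membrane=i_tube_mem,
        i_ves_membrane=i_ves_mem,
        phi_v_percent=phi_v_percent,
        below_detection=not detected,
    )


def scene_sorting_ratio(image: np.ndarray, record: dict, **kwargs) -> float:
    """Sorting ratio S measured from a rendered scene (see above)."""
    return sorting_ratio(measure_sorting_from_scene(image, record, **kwargs))
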