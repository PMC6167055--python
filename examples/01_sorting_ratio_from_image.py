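"""Measure a curvature sorting ratio from a rendered tube-pulling image.

Renders a two-channel confocal-like scene (membrane dye + labeled protein)
of a GUV with a pulled nanotube at a known ground-truth sorting ratio, then
runs the full quantification chain: perpendicular line profiles, background
subtraction, tube/vesicle intensity ratios, and S.
"""

from guvkit.pipeline import measure_sorting_from_scene
from guvkit.sorting import radius_from_fluorescence, sorting_ratio
from guvkit.synthetic import SyntheticScene, render_scene

scene = SyntheticScene(scene_kind="guv_with_tube", guv_radius_um=3.0,
                       tube_ratio_membrane=0.25, sorting_true=2.5,
                       psf_sigma_px=1.0, noise_sd=3.0, seed=4)
image, record = render_scene(scene)

m = measure_sorting_from_scene(image, record)
s = sorting_ratio(m)
ratio_mem = m.i_tube_membrane / m.i_ves_membrane
radius, radius_sd = radius_from_fluorescence(ratio_mem, rc_nm=200.0,
                                             rc_sd_nm=50.0)

print(f"ground-truth sorting ratio      S = {scene.sorting_true:.2f}")
print(f"measured sorting ratio          S = {s:.2f}")
print(f"membrane tube/vesicle ratio       = {ratio_mem:.3f}")
print(f"tube radius (fluorescence route)  = {radius:.0f} +/- {radius_sd:.0f} nm")
print()
print("S > 1 means the protein is enriched on the highly curved tube")
print("relative to the flat vesicle; the radius follows from the membrane")
print("ratio times the dye calibration factor Rc = 200 nm.")
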