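"""Removing a positioning cushion from a synthetic pressure map.

Generates a supine phantom with a foam cushion beside the trunk,
calibrates the retention threshold by the supervised grid search, and
reports how much body and object signal energy survive the cleaning.
"""

import numpy as np

from presscope import (
    default_scene_spec,
    generate_scene,
    grid_search_threshold,
    mask_energy_fraction,
    psnr,
    remove_external_objects,
    rmse,
)

scenes = [
    generate_scene(default_scene_spec("supine", with_object=True, seed=s))
    for s in range(10)
]
th = grid_search_threshold(scenes)
print(f"grid-searched retention threshold: {th:.0f} mmHg")

frame, truth = scenes[0]
result = remove_external_objects(frame, th=th)
body_kept = mask_energy_fraction(frame, result.body_frame, truth.body_mask)
obj_kept = mask_energy_fraction(frame, result.body_frame, truth.object_only_mask)
print(f"body-mask energy retained:    {100 * body_kept:.1f}%")
print(f"object-only energy surviving: {100 * obj_kept:.1f}%")
print("High body retention with near-zero object survival means the cushion")
print("was cut out of the map while the patient's pressure image is intact.")

clean = truth.clean_frame
print(f"cleaned-vs-truth RMSE (normalized): {rmse(clean, result.body_frame, normalize=True):.3f}")
print(f"cleaned-vs-truth PSNR: {psnr(clean, result.body_frame):.2f} dB")
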