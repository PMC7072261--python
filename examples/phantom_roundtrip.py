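"""Synthetic ellipsoid phantom: generate, save, reload, re-measure.

Creates a seeded ellipsoid ablation-mask phantom with known diameters,
writes it to NIfTI, reloads it and runs both volume estimators —
demonstrating that the whole quantification chain closes on an input
with analytic ground truth.
"""

import tempfile
from pathlib import Path

from expandep import (
    EllipsoidMeasure,
    diameters_from_mask,
    ellipsoid_volume,
    load_mask,
    make_ellipsoid_mask,
    save_mask,
    voxel_volume,
)

diameters = (2.05, 1.53, 1.77)
truth = ellipsoid_volume(EllipsoidMeasure(*diameters))
phantom = make_ellipsoid_mask(diameters, spacing_mm=0.2, noise_voxels=100, seed=42)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "phantom.nii.gz"
    save_mask(phantom, path)
    back = load_mask(path)

recovered = diameters_from_mask(back)
print(f"ground-truth diameters : {diameters} cm, volume {truth:.3f} cm^3")
print(f"recovered diameters    : "
      f"({recovered.diameter_a_cm:.2f}, {recovered.diameter_b_cm:.2f}, "
      f"{recovered.diameter_c_cm:.2f}) cm")
print(f"voxel-count estimate   : {voxel_volume(back):.3f} cm^3 "
      f"({(voxel_volume(back) - truth) / truth:+.2%} vs analytic)")
print(f"ellipsoid estimate     : {ellipsoid_volume(recovered):.3f} cm^3")
print(
    "\nEven with ~100 seeded boundary-voxel flips the estimators stay within "
    "a couple\npercent of ground truth at 0.2 mm spacing."
)
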