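"""Ablated-volume table from post-treatment diameter triples.

Applies the ellipsoid estimator V = (4/3) pi a b c to the maximum
orthogonal diameters of three ablation zones (one per electrode
variant), and shows the voxel-count estimator's sensitivity to pixel
spacing on a synthetic mask.
"""

from expandep import EllipsoidMeasure, ellipsoid_volume, make_ellipsoid_mask
from expandep.reporting import volume_report
from expandep.volumetrics import SegmentationVolume, voxel_volume

triples = {
    "5 needles, zero divergence": (2.05, 1.53, 1.77),
    "4 needles, 10 deg divergence": (2.6, 2.14, 2.14),
    "5 needles, 20 deg divergence": (3.04, 2.49, 2.57),
}
for label, d in triples.items():
    print(f"{label:30s} 2a,2b,2c = {d} cm -> "
          f"V_ellipsoid = {ellipsoid_volume(EllipsoidMeasure(*d)):.2f} cm^3")

# voxel-count estimator: n_pixel x PS_o x PS_v x SBS.  V_CT scales with
# PS^2, so quoting the in-plane spacing as 0.9766 vs 0.98 mm (a 0.35%
# difference) moves the same segmentation's volume by ~0.7%.
phantom = make_ellipsoid_mask((2.05, 1.53, 1.77), spacing_mm=0.2)
for scale, note in ((1.0, "native spacing"), (0.98 / 0.9766, "PS quoted 0.35% high")):
    ps = phantom.ps_o_mm * scale
    vol = SegmentationVolume(
        mask=phantom.mask, ps_o_mm=ps, ps_v_mm=ps,
        st_mm=phantom.st_mm, sbs_mm=phantom.sbs_mm,
    )
    print(f"n_pixel = {vol.n_pixel}, PS = {ps:.4f} mm ({note}): "
          f"V_CT = {voxel_volume(vol):.3f} cm^3")

table = volume_report(
    [(label, EllipsoidMeasure(*d)) for label, d in triples.items()]
)
print("\n" + table.to_string(index=False))
print(
    "\nV_ellipsoid bounds the ablation from its extremal diameters; V_CT "
    "counts the\nsegmented voxels, so a 0.3% error in pixel spacing moves "
    "the volume by ~0.7%."
)
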