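"""Segment a synthetic contrast-CT phantom and profile it with depth.

A 0.59 mm^3 ellipsoidal tumor (the smallest in the treated series) is
voxelised at 97 um with Gaussian noise, thresholded, reduced to the
largest connected component, and converted to tumor volume per depth
bin measured from the skin surface.
"""

import numpy as np

from mrtplan import (
    PhantomSpec,
    generate_phantom,
    mask_volume,
    segment_threshold,
    volume_vs_depth,
)

center = 47 * 0.097 / 2  # grid midpoint, mm
radius = (3 * 0.59 / (4 * np.pi)) ** (1 / 3)
spec = PhantomSpec(
    shape=(48, 48, 48),
    center_mm=(center, center, center),
    semi_axes_mm=(radius, radius, radius),
    tumor_intensity=200.0,
    background_intensity=100.0,
    noise_sd=10.0,
    seed=3,
)
image, truth = generate_phantom(spec)

seg = segment_threshold(image, threshold=150.0, keep_largest=True)
volume = mask_volume(seg, image.spacing_mm)
agreement = np.mean(seg.mask == truth)

# place the tumor center at the 5.5 mm treatment depth
profile = volume_vs_depth(seg, image, skin_depth_offset_mm=5.5 - center)
occupied = profile.volume_mm3 > 0

print(f"target volume   = 0.59 mm^3 (analytic ellipsoid)")
print(f"segmented       = {volume:.3f} mm^3, voxel agreement {agreement:.2%}")
print(f"depth extent    = {profile.bin_edges_mm[:-1][occupied].min():.2f}"
      f"-{profile.bin_edges_mm[1:][occupied].max():.2f} mm")
print(f"bins sum check  = {abs(profile.total_volume_mm3 - volume):.1e} mm^3")
# Voxelisation at 97 um limits volume accuracy to a few percent for
# sub-millimeter tumors; the depth bins always conserve the mask volume.
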