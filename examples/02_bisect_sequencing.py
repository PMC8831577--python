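"""Show the bisected look-ahead slab plan on a phantom heart.

The heart's axial slices are split into two halves; the lower half is
presented bottom-to-middle and the upper half top-to-middle, so the sac's
cross-sectional area never shrinks along either presented sequence, and
each target slice is stacked with its two look-ahead neighbours.
"""

import deepfat as df
from deepfat.preprocess import assemble_slab, bisect_plan, hu_window_to_8bit

phantom = df.generate_phantom(df.PhantomSpec(), seed=2)
extent = phantom.extent
plan = bisect_plan(extent)

areas = phantom.sac.voxels[extent.bottom : extent.top + 1].sum(axis=(1, 2))
print("presented order (k, step) with truth sac area in pixels:")
for k, s in plan:
    print(f"  slice {k:2d}  step {s:+d}  sac area {areas[k]:4d}")

v8 = hu_window_to_8bit(phantom.ct)[extent.bottom : extent.top + 1]
k, s = plan.entries[0]
slab = assemble_slab(v8, k, s)
print(f"\nfirst slab: target {slab.target}, channels are slices "
      f"({k}, {k + s}, {k + 2 * s}), shape {slab.shape}, dtype 8-bit")
# The area column is non-decreasing within each half: the network always
# sees the sac growing, which is what the bisect sequencing guarantees.
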