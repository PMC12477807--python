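"""Image degradations and the cost of maximum intensity projections.

Applies the three post-generation degradation filters (diffuse blur, edge
darkening, per-plane defocus) to a simulated stack, then compares spot
counts obtained from the 3D stack with counts from its 2D maximum
intensity projection on dense data.
"""

from punctakit import (
    SimParams,
    apply_defocus,
    apply_edge_darkening,
    apply_gfp_blur,
    max_intensity_projection,
    select_threshold,
    simulate_stack,
)
from punctakit.pipeline import detect_image

stack, truth = simulate_stack(SimParams(width=192, height=192, depth=12,
                                        n_spots=120, n_clusters=10,
                                        spots_per_cluster=6, seed=23))

darkened, factor = apply_edge_darkening(stack, 1)
defocused, strength = apply_defocus(darkened, 2)
blurred = apply_gfp_blur(stack)
print(f"edge darkening factor {factor:.3f}; defocus max strength {strength:.2f}")
print(f"max intensity: raw {stack.voxels.max():.0f}, "
      f"degraded {defocused.voxels.max():.0f}, diffuse-blurred {blurred.voxels.max():.0f}")


def count_spots(s):
    _, _, calls, curve = detect_image(s)
    return int((calls.intensity >= select_threshold(curve).selected).sum())


n3 = count_spots(stack)
n2 = count_spots(max_intensity_projection(stack))
print(f"spots from 3D stack: {n3}; from its MIP: {n2} (truth: {len(truth.spots)})")
# Projection collapses spots that overlap in xy but sit on different z
# planes, so MIP-derived counts trail the 3D counts on dense images.
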