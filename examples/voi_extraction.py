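"""Hottest-voxel VOI extraction on a simulated 4D phantom: localise the
aorta on the early summed image, the tumor on the last frame, extract
both TACs and quantify Ki."""

import numpy as np

from petki import (
    PhantomGeometry,
    extract_tac,
    hottest_voxels_mask,
    ki_standard,
    make_phantom,
    simulate_cohort,
    sum_frames,
)

patient = simulate_cohort(n=1, seed=11, protocol="long")[0]
img, aorta_region, tumor_region = make_phantom(
    patient.plasma_long, patient.tissue_long, PhantomGeometry()
)

# aorta VOI: five hottest voxels on three slices of the 0-45-s summed image
early = [i for i, (a, b) in enumerate(img.schedule.frames) if b <= 45.0]
aorta_voi = hottest_voxels_mask(sum_frames(img, early), aorta_region)
# tumor VOI: same rule on the last frame
tumor_voi = hottest_voxels_mask(img.voxels[..., -1], tumor_region)

cp = extract_tac(img, aorta_voi, role="plasma")
ct = extract_tac(img, tumor_voi, role="tissue")
res = ki_standard(cp, ct, patient.sample)

print(f"aorta VOI voxels : {int(aorta_voi.mask.sum())} on slices {aorta_voi.slice_indices}")
print(f"tumor VOI voxels : {int(tumor_voi.mask.sum())} on slices {tumor_voi.slice_indices}")
print(f"peak aorta value : {np.max(cp.values):.2f} kBq/ml")
print(f"Patlak Ki        : {res.Ki:.5f} 1/min (truth {patient.truth.ki_true:.5f})")
print()
print("With a noiseless, blur-free phantom the VOI TACs reproduce the")
print("generating curves exactly, so image-based Ki equals TAC-based Ki.")
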