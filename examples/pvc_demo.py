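"""GTM partial-volume correction: exact recovery, noisy amplification.

Builds a two-region phantom, smears it with a known PSF, and shows that
the geometric transfer matrix recovers the true regional values exactly
from noise-free observed means — and amplifies noise when the observed
means are noisy, the more so the smaller the region.
"""

import numpy as np
from scipy import ndimage

from o17mri import RegionTimeCourse, apply_gtm, build_gtm
from o17mri.psf import PSFModel

# synthetic Gaussian PSF (sigma 2 voxels) standing in for a simulated kernel
x = np.arange(13) - 6
r2 = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
psf = PSFModel(
    tissue="demo", kernel=np.exp(-0.5 * r2 / 4.0), fine_spacing_voxels=1.0,
    peak_index=(6, 6, 6), fwhm_voxels=4.7, effective_resolution_mm=35.3,
    t1_ms=5.0, t2star_ms=2.8, apodization="none",
)

n = 24
small = np.zeros((n, n, n), dtype=bool)
small[11:14, 11:14, 11:14] = True          # 27 voxels, PSF-sized
large = np.zeros_like(small)
large[4:20, 4:20, 2:9] = True              # 1792 voxels

masks = {"lesion": small, "tissue": large}
truth = {"lesion": 0.9, "tissue": 1.18}
kern = psf.centered_coarse_kernel()
img = sum(truth[r] * ndimage.convolve(masks[r].astype(float), kern, mode="constant")
          for r in masks)
observed = {
    r: RegionTimeCourse(r, np.array([img[masks[r]].mean()]), np.array([30.0]))
    for r in masks
}
gtm = build_gtm(masks, {r: psf for r in masks})
corrected = apply_gtm(gtm, observed)

print("GTM:\n", np.round(gtm.matrix, 3), " condition:", round(gtm.condition_number, 2))
for r in masks:
    print(f"{r:7s} true {truth[r]:.3f}  observed {observed[r].values[0]:.3f}  "
          f"corrected {corrected[r].values[0]:.6f}")

rng = np.random.default_rng(0)
amp = {}
for i, r in enumerate(masks):
    raw, cor = [], []
    for _ in range(500):
        noisy = np.array([observed[k].values[0] for k in masks])
        noisy += rng.normal(0, 0.01, 2)
        c = apply_gtm(gtm, {
            k: RegionTimeCourse(k, noisy[j : j + 1], np.array([30.0]))
            for j, k in enumerate(masks)
        })
        raw.append(noisy[i])
        cor.append(c[r].values[0])
    amp[r] = np.var(cor) / np.var(raw)
print("\nnoise variance amplification:",
      {r: round(v, 2) for r, v in amp.items()})
print("Correction is exact without noise, but a PSF-sized lesion pays a "
      "far larger noise penalty than an extended region - why corrected "
      "curves of a small stroke ROI become unusably noisy.")
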