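# Methods

## The experiment being modelled

A three-phase ¹⁷O₂ inhalation experiment under continuous 3D radial MRI:
5 min breathing room air (baseline), ≈6 min breathing 70% ¹⁷O₂-enriched
gas, then room air until 30 min of data exist. Only ¹⁷O bound in water is
MR visible, so the signal rise during inhalation reflects metabolic water
production (CMRO₂); CSF, which produces no water of its own and only
drains it from surrounding tissue, rises less. The analysis compares a
stroke ROI against its left–right mirror on the healthy hemisphere, with
the ventricles (dilated twice) subtracted from both to limit CSF spill-in.

## Phantom and kinetics

The phantom is deliberately schematic: an ellipsoidal brain (semi-axes
0.30/0.36/0.28 of the FOV), a white-matter inner ellipsoid at 0.72 scale
with the grey-matter shell outside it, paired paramedian box ventricles
(mirror-symmetric about the midsagittal voxel plane of axis 0), a
spherical lesion placed against the outer face of the left ventricle (CSF
label wins on overlap, which leaves a face-adjacent boundary), and the
lesion's exact reflection as the control label. Geometry scales with the
FOV so the same code runs at any desk-scale matrix. The default lesion
radius is 15 mm: a small basal-ganglia infarct that yields a ~26-voxel
mask at (7.5 mm)³, of which only a handful of voxels survive the
two-fold ventricle-dilation margin — deliberately reproducing the
"very small ROI" regime in which partial-volume-corrected curves drown
in noise.

Tissue kinetics are piecewise linear in the three phases — constant
baseline, uptake-rate rise during inhalation, a configurable post-switch
rate (default 0, a plateau) — continuous at both switches and clipped at
zero. This is the simplest model with the protocol's phase structure;
true inhalation kinetics are smooth exponential approaches, so the
synthetic curves have sharp corners real data would not show. Defaults:
baseline 1.0 for every tissue (natural-abundance H₂¹⁷O taken as uniform;
tissue contrast arises from T2\* weighting in the acquisition, not from
the concentration map), healthy uptake 0.030 units/min (plateau 1.18
after 6 min), CSF 0.0225 (plateau 1.135), stroke/control default to
healthy kinetics. Relaxation: T1 = 5 ms for all tissues; T2\* = 2.5 ms
(GM), 2.8 ms (WM), 5 ms (CSF).

## Acquisition model

Spoke `n` is acquired at `n·TR`. The shared radius schedule is linear up
to `t0 = 0.3 × readout` and density-adapted beyond: `k(t) = (k0³ +
c(t−t0))^(1/3)` with `c` fixed by slope continuity, giving sample density
∝ 1/k² and closed-form density-compensation weights (`k² dk/dt`: ∝ k² on
the ramp, constant beyond `t0`). The overall slope is solved so
`k(readout end) = 1/(2·Δx)`. Spoke directions follow a two-dimensional
golden-means spherical scheme, so every contiguous 3000-spoke window
covers the sphere near-uniformly (mean resultant < 0.05); additionally
each odd spoke is the exact left–right reflection of the preceding even
spoke. This mirror pairing is a design choice of this package: it makes
the sampling pattern symmetric about the midsagittal plane, so the
stroke-vs-mirrored-control comparison carries no systematic sampling
asymmetry (and the zero-contrast symmetry property holds to floating
point on odd matrices, where the mirror plane is a voxel plane).

Each sample is the sum over tissues of `steady_state × exp(−(TE+t)/T2*)
× F_mask(k)` scaled by the tissue's current concentration, plus circular
complex Gaussian noise. `steady_state = sin α (1−E1)/(1−cos α E1)` with
`E1 = e^(−TR/T1)`; at TR = 20 ms and T1 = 5 ms, `E1 = e⁻⁴`, so T1 only
scales amplitude and leaves the PSF shape untouched. The phantom is held
piecewise-constant over 1-min intervals (the frame rate of the
reconstruction; configurable). B0/B1 inhomogeneity, flow, and gradient
imperfections are not modelled. Mask spectra are evaluated with a
type-2 NUFFT (Kaiser–Bessel interpolation on a 2× oversampled FFT grid,
width-4 kernel, Beatty shape parameter), accurate to ~10⁻³ relative —
verified against a direct DFT in the tests.

## Reconstruction

Convolution gridding: density compensation and optional radial Hamming
window `0.54 + 0.46 cos(π|k|/k_max)` applied to the samples, adjoint
Kaiser–Bessel interpolation onto the oversampled grid, inverse FFT,
deapodization with the numerically integrated kernel transform, magnitude.
Sliding windows are non-overlapping by default (stride = window), which is
what makes 90 000 projections exactly 30 one-minute frames; an overlapping
stride is available. Zero-filling pads the centred spectrum symmetrically
(even-size Nyquist bins split Hermitian-symmetrically so real images stay
real); the interpolant is exact at the original voxel centres and
preserves the DC value. Quadrature and kernel choices are validated
against a brute-force inverse DFT of the identical weighted samples
(≤1% RMS of the kernel peak).

## PSF, FWHM and T2* bias

The PSF is the reconstruction of a unit point source at the geometric
grid centre whose samples carry the steady-state and readout-decay
weights; it is zero-filled ≥8× *as a complex image* before the magnitude
is taken (rectifying first would distort the mainlobe whenever sidelobes
are negative), and FWHM is measured on the three axis profiles through
the peak by linear interpolation at half maximum and averaged — the
radial trajectory makes the kernel near-isotropic. Effective resolution
is FWHM × nominal voxel size. With the reference protocol this yields
≈2.29 voxels (WM), ≈2.33 (GM) and ≈2.16 (CSF); a 1D Hamming-only
Cartesian reference gives 1.815 voxels. The T2\* bias at the echo time is
`exp(−TE/T2*)`, quoted relative to CSF (WM 92%, GM 89%).

## GTM partial-volume correction

`G_ij = mean over region i of (mask_j ⊛ PSF_j)`, with the PSF sampled at
whole-voxel offsets from its peak, truncated at the cube enclosing 99.9%
of the kernel sum, normalised to unit DC gain, and applied by FFT-based
convolution. Corrected regional values solve `G x = observed` per frame
(frames are independent); the condition number is reported and a
configurable ceiling (default 10⁶) makes degenerate region sets fail
loudly with advice to merge regions. Corrected values are not constrained
to be nonnegative. Regions corrected jointly: GM, WM, CSF and the stroke
area; the mirrored control is analysed only in the uncorrected pathway.

## ROI statistics

Relative curves divide each ROI's frame means by the mean of the first
five (baseline) frames. The "signal increase" of a region is the mean of
five frames centred on the second switch; the centre frame is the one
whose mid-time is nearest the switch instant, with ties resolved to the
later frame — equivalently, under the half-open `[start, end)` frame
convention, the frame that contains the switch. Baseline variability is
the sample (n−1) standard deviation of the first five points over their
mean, in percent. The CSF margin dilates the ventricle mask with the
6-connected structuring element (the most conservative margin), twice by
default. The hemispheric contrast is `(1 − stroke/control) × 100` — the
ratio definition, which reproduces the printed worked example
(1.158 vs 1.168 → 0.9%). Relative increase maps divide the difference of
two 3-min condition images (first three baseline frames; the last three
inhalation frames) by the baseline image after Hamming filtering and
eightfold zero-filling, masking voxels whose baseline falls below 10% of
the in-brain median.

## Noise calibration and problem sizes

The in vivo SNR is not known a priori, so the k-space noise level is
calibrated to the one observable anchor: the baseline coefficient of
variation of the mirrored-control ROI, ≈2.2% in healthy volunteers. At
the full scale (90 000 projections, 64 samples/spoke) this gives
`noise_sd = 62` (the `RunConfig` default); the test suite runs a
20×-reduced configuration — the identical 30-frame/1-min time axis with
300 projections per frame at TR 200 ms and 32 samples per spoke — whose
calibrated value is 15. Even the noise-free pipeline shows a small
frame-to-frame baseline variability (different spoke directions per
window); the calibration targets the total CV.

The detectability analysis imposes a 30% uptake deficit in the lesion.
At the reference lesion size the measured hemispheric deficit (mean over
20 noise seeds) stays below the control ROI's baseline CV — the null
finding as a power statement: blur over a ≈17 mm PSF attenuates a small
periventricular lesion's contrast below the noise floor. A lesion of 4×
the volume placed cortically is compared against twice *its own*
measured baseline CV, the detection threshold appropriate to its curve
(a larger ROI averages noise down, so its threshold is lower); its mean
deficit clearly exceeds it. Note the uncorrected ROI mean of even a
large lesion cannot reach the full 4.6% kinetic contrast — blur always
mixes in surrounding healthy tissue — which is precisely the bias the
GTM correction removes at the cost of noise.

## Numerical choices and degenerate inputs

* Gridding: width-4 Kaiser–Bessel, 2× oversampling; accuracy enforced by
  oracle tests rather than kernel tuning.
* Density weights use trapezoid end-corrections; the k=0 sample has zero
  weight (the DC level is carried by the near-centre samples).
* FWHM measurement requires a unique profile maximum and a genuine
  half-maximum crossing; both are errors otherwise.
* `mean_around_switch` refuses windows extending outside the series;
  ROI means refuse empty masks; an ROI emptied by the ventricle margin
  is a warning, not an error — the margin procedure can legitimately
  produce one for a tiny periventricular lesion.
* Ties in the switch-centre frame go to the later frame (see above).
* The lesion must fit inside the brain ellipsoid, must not be swallowed
  by the ventricle label, and must not cross the midline.

## Limitations

Synthetic geometry is topological, not anatomical: no cortical folding,
no realistic ventricle shape, no partial-volume fractions at tissue
interfaces (labels are binary at the acquisition grid). Kinetics are
piecewise linear with a hard plateau; recirculation of labelled water
through the body is ignored. The acquisition model omits B0/B1
inhomogeneity, flow and motion — so passing tests demonstrate the
correctness of the reconstruction/correction/statistics chain under the
stated signal model, not robustness to scanner non-idealities. Real-data
use assumes images and masks are already registered to the oxygen grid
(registration and segmentation are upstream, external steps).
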