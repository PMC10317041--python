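# o17mri — dynamic oxygen-17 brain MRI at desk scale

Dynamic oxygen-17 (¹⁷O) MRI measures cerebral oxygen metabolism directly:
during a three-phase inhalation experiment (room air → 70% ¹⁷O₂-enriched gas
→ room air, under continuous imaging) metabolically produced ¹⁷O water
(H₂¹⁷O) accumulates in tissue, while the inhaled ¹⁷O₂ gas itself is MR
invisible. The slope of the H₂¹⁷O signal during inhalation therefore proxies
the cerebral metabolic rate of oxygen consumption (CMRO₂) — the quantity
that could separate viable from non-viable tissue in stroke.

`o17mri` implements the complete measurement and analysis chain of such an
experiment as a tested Python library, with a synthetic digital brain
phantom standing in for patient data:

* **phantom** — labelled brain geometry (GM/WM shell, paired ventricles, a
  spherical stroke lesion face-adjacent to one ventricle, and its exact
  mirror as a contralateral control ROI) with piecewise-linear three-phase
  H₂¹⁷O kinetics per tissue;
* **acquisition** — spoiled steady-state, density-adapted 3D radial k-space
  sampling (TE/TR = 0.56/20 ms, flip 60°, 5.5 ms readout, (7.5 mm)³ nominal
  resolution, 90 000 projections = 30 min), with per-sample T2\* decay
  `exp(−(TE+t)/T2*)` and complex Gaussian noise;
* **recon** — sliding-window Kaiser–Bessel gridding reconstruction with
  closed-form density compensation (∝ k² on the ramp, flat in the
  density-adapted segment), radial Hamming apodization and zero-filling
  (3000 projections = one 1-min frame; 30 frames for the patient protocol,
  40 for volunteers);
* **psf** — tissue-specific point-spread functions from trajectory,
  relaxation and filter; FWHM, effective resolution, and the T2\* signal
  bias `exp(−TE/T2*)` at the echo time;
* **pvc** — geometric transfer matrix (GTM) partial-volume correction of
  regional means, `G⁻¹ · observed` with `G_ij = mean_i(mask_j ⊛ PSF_j)`;
* **analysis** — baseline normalisation, five-point averaging around the
  second gas switch, baseline coefficient of variation, mirrored ROIs,
  ventricle-dilation CSF margins, Dice overlap, and voxel-wise relative
  ¹⁷O increase maps;
* **pipeline** — the end-to-end reference experiment with provenance
  (seed, config hash, versions) and NIfTI/CSV outputs.

## Worked example

`python examples/psf_report.py` simulates the per-tissue PSF of the
reference protocol and prints:

```
tissue  t2star_ms  fwhm_voxels  effective_resolution_mm  bias_vs_csf_pct
    GM        2.5        2.330                   17.474           89.404
    WM        2.8        2.293                   17.197           91.576
   CSF        5.0        2.159                   16.191          100.000
```

Although the voxel grid is (7.5 mm)³, T2\* decay during the 5.5 ms readout
plus the Hamming filter widen the point response to ≈2.3 voxels for brain
tissue — a true resolution of ≈17 mm — and by TE = 0.56 ms grey and white
matter have lost 11% and 8% of their signal relative to CSF, biasing mixed
voxels toward the CSF value.

`python examples/reference_experiment.py` runs the whole chain at reduced
k-space load (identical 30-frame time axis) and prints the per-ROI summary:

```
    region  mean_around_second_switch  baseline_cv_pct  n_voxels
   healthy                      1.167            0.115      3984
ventricles                      1.149            1.040        84
    stroke                      1.186            2.296         5
   control                      1.161            1.473         5

stroke vs mirrored control: -2.20% deficit
```

Healthy tissue reaches a relative H₂¹⁷O level of ≈1.17 around the second
switch, CSF stays lower, and with default (healthy) stroke kinetics the
stroke-vs-control deficit is pure noise of the same order as the baseline
CV — a measured deficit is only meaningful once it clearly exceeds that
variability. `examples/pvc_demo.py` shows the GTM correction recovering
true regional values exactly without noise and amplifying noise ~54-fold
for a PSF-sized lesion versus ~2.5-fold for an extended region.

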