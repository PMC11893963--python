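# Methods

This note documents the models, conventions, numerical choices and known
limitations of `lsfquant`.

## Coordinate and grid conventions

Patient coordinates are DICOM LPS millimetres (+x left, +y posterior, +z
superior).  NIfTI affines (RAS) are converted on read and restored on write.
Voxel indices are 0-based, `origin` is the *centre* of voxel (0,0,0), and a
grid is the pair (4×4 affine, shape).  DICOM series are sorted geometrically
along the slice normal, so superior-first and inferior-first stored series
produce identical patient-space volumes; slices with mixed frame-of-reference
UIDs, mixed orientations, or a slice-gap deviation above 1% of the median gap
are rejected outright.  No registration is performed anywhere: SPECT and CT
are assumed hardware-fused on one gantry, and a frame-of-reference mismatch
is an error, not a warning.

## Mask providers

Three interchangeable sources of liver / left-lung / right-lung masks on the
CT grid:

* **Files** — NIfTI volumes binarized at 0.5 (probabilistic maps accepted);
  the grid must match the CT within 1e-3 mm.
* **Hounsfield thresholding** — lungs from the (−950, −300) HU window
  (two largest connected components ≥ 50 cm³, left/right split by the
  component centroid on the patient L–R axis, exact tie → the larger
  component is the right lung), liver from the (−50, 200) HU window (largest
  component), per-organ morphological hole filling.  Adequate for phantoms
  and synthetic data, where densities are controlled; not a clinical
  segmenter.
* **External ML adapter** — an out-of-process command template
  (`{input}`/`{outdir}` placeholders) for tools of the TotalSegmentator
  family.  The adapter treats output naming as configuration and is never
  required by the test suite, keeping the package buildable offline.

## VOI transfer and augmentation

Masks are transferred to the SPECT grid by nearest-neighbour sampling of
target voxel centres through the two affines.  This is deliberately the
simplest possible resampler: binary masks admit no meaningful interpolation,
and the voxel-centre rule makes the operation exactly checkable against a
brute-force loop.  Volume drift is bounded by a one-target-voxel surface
shell (tested for grid ratios up to 5).

Augmentation dilates each transferred organ by a structuring element defined
in *millimetres* — a ball of radius r, stretched into an ellipsoid by an
extra cranio-caudal term — so anisotropic SPECT grids behave isotropically.
Contested voxels resolve by precedence

    original lung > original liver > augmented lung > augmented liver,

i.e. the augmented liver is adjusted to avoid the lung VOIs, and original
evidence is never discarded.  When both augmented lungs claim a voxel, the
nearer original lung (Euclidean mm distance) wins; exact ties go to the
right lung.  Defaults are liver 5 mm, lung 5 mm, +5 mm cranio-caudal:
roughly one SPECT voxel in-plane, and 10 mm along S–I to cover the ±7.5 mm
excursion of typical 15 mm peak-to-peak breathing.  The two organs get
*equal* radii by default because the LSF is a count ratio: an asymmetric
margin recovers one organ's displaced counts preferentially and biases the
ratio (measurably, on the digital phantom, a 10 mm liver / 5 mm lung margin
moves the LSF further from truth than no augmentation at all).  All radii
are configurable and echoed into every report.

### Cropped lung apex

If the lung mask touches the superior face of the SPECT volume and a
reference (full anatomical) lung volume is supplied, the missing volume is
imputed at the mean count concentration of the most-superior 20 mm of imaged
lung.  Counts are imputed, not mask voxels, so reported volumes stay honest
about what was imaged; the imaged volume and apex concentration are measured
on the original (pre-augmentation) lung voxels, since the augmentation shell
is a capture margin, not anatomy.  The 20 mm apex window is configurable.
If the reference exceeds the imaged volume by more than 25% *without* the
lung touching the face, a warning is logged and nothing is corrected.

## Quantification

* 3D LSF: lung/(lung+liver) count percentage; crop-imputed counts fold into
  the lung total.
* Planar LSF: the posterior camera records a left-right mirrored image; it
  is un-mirrored exactly once (at count extraction), then per-view organ
  totals are combined as geometric means.  The geometric mean is applied to
  organ *totals* per view (standard clinical practice), not pixelwise.  No
  background/scatter ROI subtraction is performed.
* Ground truth: net activities (assay − residual) decay-corrected to the
  reference time with T½ = 6.0067 h.  Residuals may carry their own assay
  time; a negative net activity after correction is an assay-inconsistency
  error.  When all assays share one clock time the decay factor cancels out
  of the ratio.
* Cohort statistics: percentage difference PD = (PL − TF)/TF × 100 per case;
  because "average difference" is ambiguous, both the mean of per-case PDs
  and the PD of the cohort means are computed and reported.  Quartiles use
  the (n+1)-rank definition — Q1 at rank (n+1)/4, Q3 at 3(n+1)/4, linear
  interpolation between order statistics, ranks clipped to [1, n] (numpy's
  `method="weibull"`).
* Reports round LSF to 2 dp for display; internal values keep full
  precision, and a report whose recorded counts do not reproduce its
  recorded LSF to 1e-9 relative is rejected at construction.

## Digital phantom

The simulator stands in for a fillable anthropomorphic liver/lung phantom
scanned on a SPECT/CT system.  Default compartments are ellipsoids sized to
the physical phantom: liver 1785 cm³, left lung 883 cm³, right lung
1308 cm³ (2191 cm³ of lung), in patient configuration; scenario presets add
a 10 cm liver–lung separation (B, D) and water-filled lungs (C, D).
Default concentrations (0.10 MBq/mL liver, 0.0127 MBq/mL lung) give a true
LSF of ≈13.5%, a realistic elevated-shunt case.  Ground-truth activities
are concentration × rasterized compartment volume — exactly what was "put
into" each digital compartment — so the truth and the emulated image share
one discretization.

* **CT**: HU from the material map (water 0, bead-lung −700 with seeded
  Gaussian speckle of SD 50 HU, air −1000) on a 2.4 mm grid.
* **SPECT**: the activity map on a 4.8 mm grid (the clinical 128-matrix
  scale) passes through respiratory blur → Gaussian PSF (default FWHM
  12 mm) → global count scaling (default 2×10⁶ total counts, or a fixed
  counts-per-MBq sensitivity) → optional Poisson draw.  The simulator
  emulates the *reconstructed* AC SPECT directly instead of projecting and
  running OSEM: the LSF is a count ratio and is robust to reconstruction
  corrections, so the quantification layer can be exercised without a
  tomographic engine.  Grids are auto-sized with 30/30/40 mm margins so the
  blurs conserve counts to <0.1%.
* **Respiration**: 1D sinusoidal cranio-caudal motion; the dwell
  distribution (arcsine marginal) is realised by 21 displacement samples
  uniform in phase, each split between neighbouring integer voxel offsets
  with linear weights — this conserves total counts and the count centroid
  exactly, and adds exactly the kernel variance (both tested).
* **Planar**: Beer–Lambert line integrals along the A–P axis at 140 keV
  (water/liver 0.154 cm⁻¹, bead lung 0.05 cm⁻¹, air 0 by default); each
  voxel's own thickness counts half toward either face, so anterior and
  posterior path lengths sum exactly to the column thickness and a point
  source's geometric mean is depth-independent (tested).  The posterior
  view is returned in camera orientation (mirrored).  Views are scaled to
  10⁶ counts each (per-view scaling cancels out of the geometric-mean LSF).
* **Cropped field of view**: an optional superior crop of the SPECT grid
  emulates an acquisition that cuts the lung apex.
* All stochastic elements (CT speckle, SPECT noise, planar noise) draw from
  independent child streams of one seed; a fixed seed reproduces every
  output bit-identically.

What the phantom does *not* emulate: scatter windows and septal
penetration, OSEM convergence artefacts, heterogeneous organ uptake,
deformable (non-rigid) breathing, or a separate scatter medium between the
lungs — the physical phantom's packing layer is absorbed into the uniform
background.  Passing tests therefore demonstrate the correctness of the
quantification layer under controlled physics, not clinical segmentation
accuracy on real anatomy.

## Problem sizes and test design

Tests and the reproduction script run the phantom at its default grids
(≈0.2M SPECT voxels, ≈1.7M CT voxels), chosen so a full study simulates in
about a second while keeping ≥12 voxels across every organ axis.  Oracle
comparisons (voxel-centre resampling loop, brute-force augmentation
precedence over 100 randomized adjacent-mask cases) run on small grids where
exhaustive enumeration is exact.  The motion-robustness experiment uses
15 mm peak-to-peak motion with a 12 mm PSF over five noise seeds; the
crop-correction experiment cuts ~10% of the lung volume and uses a fixed
counts-per-MBq sensitivity so cropped and uncropped studies share a count
scale.

## Known limitations

* The nearest-neighbour transfer of a fine CT mask to the coarse SPECT grid
  carries a deterministic surface-shell volume offset (≈0.1–0.2% LSF on the
  default phantom); fractional-occupancy resampling would reduce it but
  would no longer be a binary-mask operation.
* Left/right lung assignment assumes the grid is roughly axis-aligned with
  the patient axes (true for clinical SPECT/CT and the phantom).
* The external segmenter adapter shells out and trusts the configured label
  naming; it performs no anatomical sanity checks.
* Planar ROIs are taken as given (or projected from truth masks in the
  phantom); no ROI-drawing variability is modelled, so the planar-vs-SPECT
  comparison isolates the physics (attenuation/geometric-mean) component of
  the planar bias only.
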