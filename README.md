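# lsfquant

Lung shunt fraction (LSF) quantification from ⁹⁹ᵐTc-MAA SPECT/CT for
⁹⁰Y-microsphere radioembolization (SIRT) planning.

Before delivering ⁹⁰Y microspheres to a liver tumour, a ⁹⁹ᵐTc-labelled
macroaggregated-albumin surrogate is injected into the hepatic artery and
imaged; the fraction of activity that shunts through to the lungs gates the
prescribed dose, because an overestimated shunt leads to unnecessary dose
reduction and an underestimated one risks radiation pneumonitis.  The
standard planar (2D) estimate systematically overestimates the LSF; this
package implements the volumetric alternative — CT-derived organ masks
transferred onto the attenuation-corrected SPECT grid, augmented to
compensate respiratory motion, and used to form the count-ratio LSF — plus
the planar and phantom-ground-truth estimators needed to compare against it.

## The three estimators

All share the ratio form, reported in percent:

* **3D SPECT**
  `LSF% = Total Lung Count / (Total Lung Count + Total Liver Count) × 100`,
  with voxel counts summed under the finalized volumes of interest (VOIs).
* **2D planar**
  `LSF% = GM_lung / (GM_lung + GM_liver) × 100`, where
  `GM = √(anterior × posterior)` is the geometric mean of the per-view organ
  totals from an anterior/posterior planar pair.
* **Ground truth** (fillable phantom)
  `LSF% = ((RLA − rlr) + (LLA − llr)) / ((RLA − rlr) + (LLA − llr) + (LA − lr)) × 100`
  from assayed syringe activities (RLA/LLA/LA) and residuals (rlr/llr/lr),
  decay-corrected to a common reference time with T½(⁹⁹ᵐTc) = 6.0067 h.

The pipeline around the 3D estimator: masks (supplied files, Hounsfield
thresholding, or an external ML-segmenter adapter) → nearest-neighbour
transfer to the SPECT grid → metric (mm) dilation of each organ with
lung-priority overlap resolution ("pixel augmentation", capturing counts
displaced by breathing) → optional count imputation for a lung apex cropped
by the SPECT field of view → count extraction and reporting.

A digital liver/lung phantom (`lsfquant.phantom`) emulates the whole
acquisition — two low-density lung compartments and a unit-density liver
with configurable activity concentrations, attenuation, system blur,
cranio-caudal respiratory motion and Poisson noise — emitting a CT, an
emulated AC SPECT, attenuated anterior/posterior planar projections, and the
assayed ground truth, so the complete pipeline runs and is tested without
any scanner data.

## Worked example

```python
import lsfquant as lq

# digital phantom, default ~13.5% shunt, 12 mm system PSF, Poisson noise
study = lq.build_phantom(lq.PhantomSpec(seed=1))
print(f"true LSF            {study.true_lsf_percent:.2f} %")

# 3D SPECT pipeline: CT truth masks -> resample -> augment -> counts
out = lq.spect_lsf_pipeline(study.spect, study.truth_masks)
print(f"3D SPECT LSF        {out.result.lsf_percent:.2f} %")

# 2D planar estimate from the attenuated anterior/posterior projections
pc = lq.planar_organ_counts(study.planar_ant, study.planar_post, study.planar_rois)
print(f"2D planar LSF       {lq.lsf_planar(pc).lsf_percent:.2f} %")
print(f"planar vs SPECT PD  "
      f"{lq.percentage_difference(lq.lsf_planar(pc).lsf_percent, out.result.lsf_percent):.1f} %")
```

prints

```
true LSF            13.47 %
3D SPECT LSF        13.33 %
2D planar LSF       20.73 %
planar vs SPECT PD  55.6 %
```

The volumetric estimate lands within ~0.15 percentage points of the
configured truth, while the planar geometric mean overestimates it by more
than half — the depth-dependent attenuation difference between the
low-density lungs and the water-dense liver survives the geometric mean and
inflates the apparent lung fraction.

The same analyses are available from the shell:

```sh
lsfquant phantom --scenario A --seed 1 --outdir study/
lsfquant lsf3d --ct study/ct.nii.gz --spect study/spect.nii.gz \
    --mask liver=study/mask_liver.nii.gz,lung_left=study/mask_lung_left.nii.gz,lung_right=study/mask_lung_right.nii.gz \
    --out report.json
lsfquant cohort --csv cohort.csv --out cohort.json
```

Every run ends in a JSON report that records the counts, organ volumes
before/after augmentation, and every augmentation or crop parameter applied,
so the reported LSF is reproducible from the report alone.

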