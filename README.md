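# adiposeg

Automated segmentation and quantification of abdominal body-fat
compartments — subcutaneous adipose tissue (**SAT**) and visceral adipose
tissue (**VAT**) — from T1-weighted-like abdominal MRI, with cohort-level
statistics of the **VAT/SAT volume ratio**, a body-composition biomarker
studied in wasting disorders such as amyotrophic lateral sclerosis.

The package is aimed at body-composition and medical-image-analysis
researchers who want a fully reproducible, dependency-light reference
pipeline:

* **Phantom cohorts** (`adiposeg.phantom`): seeded synthetic abdominal
  T1w-like volumes — bright SAT annulus, bright visceral fat blobs,
  mid-intensity organs, fat-like bone confounders, polynomial bias field,
  Rician noise — with exact ground-truth masks and a two-group cohort
  carrying an injected VAT/SAT effect.
* **Preprocessing** (`adiposeg.preprocess`): multi-station stitching by
  3-DOF translational registration (grid search + Nelder–Mead simplex over
  the station overlap), merging, supersampling to 1.2 mm isotropic voxels,
  median filtering, and automatic body-mask extraction.
* **CNN segmentation** (`adiposeg.cnn`): an encoder–decoder U-Net —
  three down-sampling steps with 16/32/64 feature channels, transposed-
  convolution upsampling with skip concatenations, bottleneck dropout,
  per-pixel 3-class softmax — trained with Adam on categorical
  cross-entropy (batch 16).  The network and its backpropagation are
  implemented directly on numpy and exposed as a scikit-learn-style
  estimator, `UNetSegmenter`.
* **Reference segmentation** (`adiposeg.reference`): an intensity-range +
  26-connectivity method (histogram-derived fat range; SAT from the
  subsurface band, VAT from cavity components), the classical
  semi-automatic approach the CNN is compared against.
* **Evaluation & statistics** (`adiposeg.metrics`, `adiposeg.stats`):
  slicewise Dice `2|R∩P|/(|R|+|P|)` and pixel error `100·|RΔP|/(W·H)`
  aggregated per group as mean ± SD; voxel-count volumetry in mL;
  per-group Pearson correlation of predicted vs reference volumes; and a
  two-tailed Student's t-test of the patient-vs-control VAT/SAT ratio.

See `docs/methods.md` for the full model description, parameter defaults,
and what phantom results do and do not demonstrate.

## Worked example

Train the desk-scale experiment (16 + 16 phantom subjects, shrunken
8/16/32-channel U-Net, 10 epochs, ~1 min on one CPU) and evaluate on the
held-out test subjects:

```python
from adiposeg.experiments import run_segmentation_experiment, cohort_ratio_contrast

exp = run_segmentation_experiment(seed=1, n_per_group=16, epochs=10)
for row in exp.metrics_overall:
    print(f"{row.compartment}: Dice {row.dice_mean:.3f} ± {row.dice_sd:.3f}, "
          f"pixel error {row.pixel_error_mean_pct:.2f}%  (n={row.n_slices} slices)")

rep = cohort_ratio_contrast(exp.model, seed=1001, n_per_group=34)
gs = rep.ratio_stats
print(f"VAT/SAT ratio: patients {gs.mean_a:.3f} vs controls {gs.mean_b:.3f}, "
      f"t = {gs.t:.2f}, p = {gs.p:.2e}")
```

prints (seed 1):

```
SAT: Dice 0.969 ± 0.029, pixel error 0.82%  (n=168 slices)
VAT: Dice 0.700 ± 0.214, pixel error 0.65%  (n=168 slices)
VAT/SAT ratio: patients 0.200 vs controls 0.096, t = 8.28, p = 8.25e-12
```

Reading: the subcutaneous ring is segmented almost perfectly, the
scattered visceral blobs — ambiguous against bone rims and noise — come
out clearly worse (SAT ≫ VAT, the characteristic ordering of this task),
and the injected group difference in visceral-to-subcutaneous fat ratio is
recovered as highly significant at n = 34 per group.

The same stages are scriptable from the shell:

```bash
adiposeg simulate --out cohort/ --seed 1 --n-per-group 16
adiposeg split --manifest cohort/manifest.json --seed 2 --out cohort/split.json
adiposeg train --manifest cohort/split.json --seed 1 --out model/
adiposeg predict --model model/ --in cohort/patient_000_vol.nii.gz --out pred.nii.gz
adiposeg evaluate --ref cohort/patient_000_mask.nii.gz --pred pred.nii.gz --out metrics.csv
adiposeg quantify --mask pred.nii.gz
adiposeg run-all --out runs/demo --seed 1        # everything, resumable
```

## Layout

```
src/adiposeg/
  core.py         data containers (VolumeImage, LabelMap, manifests, ...)
  io.py           NIfTI volumes, PNG mask codec ({0,255,127}), CSV/JSON
  phantom.py      synthetic cohort generator + station splitting
  preprocess.py   registration, merging, supersampling, filtering, body mask
  nn/             numpy CNN primitives (layers, U-Net, Adam)
  cnn.py          UNetSegmenter estimator, cohort split, volume inference
  reference.py    intensity-range reference segmentation
  metrics.py      Dice / pixel error, per-group aggregation
  stats.py        volumetry, t-test, Pearson, cohort report
  experiments.py  seeded desk-scale experiments
  pipeline.py     config-driven multi-stage runs
  cli.py          `adiposeg` command-line interface
```
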