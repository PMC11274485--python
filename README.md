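# mamip — segmentation-free PET/CT outcome prediction from multi-angle MIPs

`mamip` predicts recurrence-free survival of head-and-neck cancer
patients from FDG-PET/CT volumes **without any tumor segmentation**.
Instead of delineating lesions, it:

1. windows the CT to the bone Hounsfield range [700, 2000] and locates
   the anatomical head-and-neck region from coronal/sagittal bone MIPs
   (annotation files or a rule-based landmark heuristic);
2. crops the co-registered PET volume with the resulting 3D box;
3. rotates the crop about the superior-inferior axis in 5° steps and
   captures a maximum intensity projection per step — 72 views per
   patient;
4. runs each view through a frozen convolutional encoder and reduces the
   C×H×W activation tensor with a global pooling
   (avg / max / median / std) to a views × channels feature matrix;
5. fuses the views into one vector per patient (channel-wise
   mean/median/max/std, per-channel ICA, or an autoencoder bottleneck);
6. fits a Cox proportional-hazards model
   h(t | x) = h₀(t)·exp(βᵀx) after standard scaling, correlated-feature
   elimination and ICA dimensionality reduction, and reports Harrell's
   concordance index (c-index) under nested 5-fold cross-validation
   with repetition.

It is aimed at imaging researchers who want a reproducible,
delineation-free survival baseline, and ships a synthetic PET/CT phantom
generator with Cox-linked outcomes so the entire pipeline is testable on
a laptop without access-gated clinical data.

## Worked example

```python
from mamip.phantom import PhantomSpec, make_cohort
from mamip.pipeline import FeatureConfig, run_cohort_analysis
from mamip.survival import CVConfig, concordance_index

spec = PhantomSpec()                      # beta=1.5, 20% censoring
cohort = make_cohort(spec, n=60, seed=7)
result, features = run_cohort_analysis(
    cohort,
    feature_config=FeatureConfig(step_deg=30.0),   # 12 views
    fusion="cw_mean",
    cv_config=CVConfig(n_repeats=2, seed=1, n_components_grid=(5, 10)),
)
oracle = concordance_index(cohort.records, cohort.true_risk)
print(f"true-risk c-index : {oracle:.3f}")
print(f"pipeline  c-index : {result.mean:.3f} +/- {result.std:.3f} "
      f"over {len(result.per_split_cindex)} outer splits")
```

prints

```
true-risk c-index : 0.757
pipeline  c-index : 0.719 +/- 0.084 over 10 outer splits
```

The phantom cohort plants a Cox effect of the lesion burden
s = log Σ peak·volume on the hazard. The first line is the concordance
of the *true* risk score β·s_std — the ceiling any method can reach on
this cohort; the second is what the image pipeline recovers end to end
(bone-guided crop → 12-view MIP features → channel-wise mean fusion →
nested-CV Cox), a few points below the ceiling, with the spread over the
2×5 outer test folds.

A c-index of 0.5 is chance ordering of event times, 1.0 is perfect;
run the same analysis with `PhantomSpec(beta=0.0)` replacing the spec
(via `dataclasses.replace`) to verify the pipeline stays at chance when
the outcome is independent of the images.

## Command line

```bash
mamip resample --in pet.nii.gz --out pet_1mm.nii.gz --spacing 1.0 --order 3
mamip crop --ct ct.nii.gz --pet pet_1mm.nii.gz --boxes auto --out pet_crop.nii.gz
mamip mamip --in pet_crop.nii.gz --step 5 --out mips/
mamip make-cohort --n 200 --seed 7 --out cohort/
mamip predict-rfs --features features.csv --survival survival.csv --out cv.json
```

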