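# spinefat

Automated segmentation of lumbar vertebral bodies on water-fat (Dixon/IDEAL)
MRI and quantification of per-vertebra bone-marrow-fat (BMF) fraction.

## The problem

Bone-marrow fat content of the vertebral bodies is an emerging imaging
biomarker in chronic low back pain, osteoporosis and metabolic disease.
Chemical-shift water-fat MRI yields co-registered water, fat, fat-fraction
(FF) and R2* maps from which BMF can be read directly — but drawing the
vertebral regions of interest by hand takes minutes per slice. `spinefat`
automates the whole workflow:

1. a 2D multi-channel **U-Net** consumes each sagittal slice as a 4-channel
   image (water, fat, FF, R2*) and emits a vertebra probability map;
2. the map is binarised at 0.5 and decomposed into per-slice 8-connected
   components, which are linked across slices and labelled **L1–L5**
   (partially imaged T12/sacrum are recognised and excluded);
3. per level, only slices covering more than half of that body's maximal
   cross-sectional area are retained: the per-vertebra BMF is the mean of
   the FF map over each retained ROI, averaged slice-wise then body-wise:

   `BMF(level) = mean_slices( mean_pixels( FF ) )`  (percent);

4. an evaluation battery compares automatic and reference segmentations:
   Dice `DSC = 2TP/(2TP+FP+FN)` and Jaccard `IoU = TP/(TP+FP+FN)` overlap,
   sensitivity/specificity/precision/F1/accuracy, Cohen's κ, ROC AUC with
   DeLong 95% CI, precision-recall AUC, Bland-Altman bias ± 1.96 SD limits
   of agreement for BMF values, and test-retest repeatability (ICC(2,1) and
   RMS-CV short-term precision error).

Because clinical lumbar water-fat series are rarely shareable, the package
includes a **synthetic spine-phantom generator** with voxel-accurate ground
truth (known per-body fat fractions, cortical rims excluded from truth
masks, confounder tissues, optional partially-imaged T12/S1) so every stage
can be trained and validated end to end with known answers. The U-Net,
backpropagation and Adam optimiser are implemented in NumPy; training of
reduced-scale models is practical on a single CPU.

## Worked example

Train a reduced model on a synthetic cohort and quantify an unseen subject:

```python
import numpy as np
import spinefat as sf
from spinefat.segmentation import cohort_to_arrays
from spinefat.pipeline import segment_series

spec = sf.PhantomSpec(image_size=64, cortical_rim_px=1, seed=0)
cohort = sf.generate_cohort(20, spec=spec, seed=7)
X, y, groups = cohort_to_arrays([(s, t.mask) for s, t in cohort])

model = sf.VertebraSegmenter(model_scale=0.25, max_epochs=12,
                             early_stopping_patience=4,
                             validation_fraction_subjects=4/20, seed=0)
model.fit(X, y, groups=groups)

series, truth = sf.generate_cohort(1, spec=spec, seed=900)[0]
prob, binary, rois = segment_series(model, series, min_area_px=10,
                                    match_radius_px=8)
counts = sf.metrics.confusion_counts(binary, truth.mask)
dsc, iou = sf.metrics.overlap_scores(counts)
report = sf.quantify(series, rois)
print(f"DSC {dsc:.3f}  IoU {iou:.3f}")
for lv in report.levels:
    print(f"{lv}: BMF {report.mean_bmf(lv):5.2f}%  "
          f"(truth {truth.true_ff_pct[lv]:5.2f}%)")
```

Output from this exact script (seeds as shown):

```
DSC 0.987  IoU 0.974
L1: BMF 38.45%  (truth 38.14%)
L2: BMF 31.81%  (truth 32.70%)
L3: BMF 19.88%  (truth 20.57%)
L4: BMF 37.60%  (truth 38.73%)
L5: BMF 19.79%  (truth 19.56%)
```

The held-out Dice near 0.99 says the reduced network recovers phantom
vertebrae almost perfectly; the per-level BMF errors (all ~1.1
percentage points or less here) are dominated by boundary pixels where
predicted ROIs differ slightly from the rim-excluded truth.

The same stages are available from the shell:

```bash
spinefat simulate --n-subjects 20 --out cohort/ --image-size 64 \
    --cortical-rim-px 1 --seed 7
spinefat train --cohort-dir cohort/ --model-scale 0.25 --max-epochs 12 \
    --out model.npz --seed 0
spinefat segment --model model.npz --series-dir cohort/subject-000 --out mask.nii.gz
spinefat quantify --series-dir cohort/subject-000 --mask mask.nii.gz --out bmf.csv
spinefat evaluate --pred mask.nii.gz --truth cohort/subject-000/truth_mask.nii.gz \
    --out eval.json
```

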