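# cardioseg

Multi-atlas labeling, reverse-ranking label quality scoring, and 3D U-Net
training for multi-structure cardiac CT angiography (CTA) segmentation —
exercised end to end on synthetic cardiac phantoms with exact ground truth.

## The problem

Training a segmentation network for cardiac CTA requires thousands of
labeled volumes, but expert delineation of the left and right ventricular
cavities (LV, RV), left and right atria (LA, RA), and LV myocardium (LVM)
over hundreds of slices per study is prohibitively expensive. This package
implements a hybrid answer for researchers studying label-efficient medical
image segmentation:

1. **Computer label generator (CLG).** A bounding box around the heart is
   found from the contrast-filled blood pool (SLIC supervoxels +
   thresholding + connected-group extent). The k = 9 most similar atlases
   (windowed structural similarity) are deformably registered to the target
   (multiresolution demons), their labels warped and fused by per-voxel
   majority vote with a fixed priority tie-break, and the consensus refined
   by a seeded random walker run in multiple passes — the walker solves the
   combinatorial Dirichlet problem on the intensity-weighted voxel graph
   with Grady weights w_ij = exp(−β(I_i − I_j)²).

2. **Reverse-ranking (RR) quality score.** With no ground truth for a
   computer label, the registration direction is reversed: the target is
   registered *to* each of its k atlases, the computer label is warped into
   atlas space, and its mean Dice against the atlas reference labels is the
   RR score. Ranking a cohort by RR yields a strong-label (best fraction)
   or weak-label (worst fraction) training subset.

3. **Patch-based 3D U-Net.** Trained on bounding-box crops of the selected
   computer labels with a per-channel soft Dice loss
   1 − (2Σpt + ε)/(Σp + Σt + ε), sigmoid outputs (five binary channels),
   Adam with multi-step learning-rate decay, and group normalization.
   Prediction averages overlapping patch probabilities, thresholds at 0.5,
   and combines channels by the priority LV, LA, RV, RA, LVM.

Because clinical CTA cohorts are rarely shareable, a phantom module
generates contrast-CTA-like volumes (blood pool ≈ 400 HU, myocardium ≈ 90,
lung ≈ −800, bone ≈ 700, plus noise) with per-subject affine + smooth
random deformations and exact ground-truth labels, including the controlled
degradations used to validate the RR score (graded corruption, and the
synthetic weak-label recipe: 5 mm chamber erosion with the LVM expanded
over the original LV cavity).

## Worked example

Generate a small cohort, label one target with the multi-atlas generator,
and score the label without using its ground truth:

```python
import numpy as np
from cardioseg.phantom import PhantomParams, make_cohort
from cardioseg.mas import Atlas, AtlasLibrary, CLGConfig, run_clg
from cardioseg.ols import reverse_rank_score
from cardioseg.metrics import dice
from cardioseg.core import MAIN_STRUCTURES

atlases, targets = make_cohort(PhantomParams(), n_atlases=9, n_targets=1,
                               master_seed=0)
library = AtlasLibrary([Atlas(a.case_id, a.volume, a.label) for a in atlases])
target = targets[0]

label = run_clg(target.volume, library, CLGConfig(k=9))
for s in MAIN_STRUCTURES:
    print(f"{s}: Dice vs ground truth = "
          f"{dice(label.mask(s), target.label.mask(s)):.3f}")

rr = reverse_rank_score(target.volume, label, library, k=3)
print(f"aggregate RR score (no ground truth used): {rr.aggregate:.3f}")
```

Output:

```
LV: Dice vs ground truth = 1.000
RV: Dice vs ground truth = 1.000
LA: Dice vs ground truth = 1.000
RA: Dice vs ground truth = 1.000
LVM: Dice vs ground truth = 0.992
aggregate RR score (no ground truth used): 0.910
```

The per-structure Dice compares the computer label against the phantom's
exact ground truth (the thin myocardial shell is the hardest structure —
at 2.5 mm voxels a single-voxel boundary error costs it several points).
The RR score is computed *without* that ground truth; on cohorts with
graded label corruption it tracks true Dice with a Spearman rank
correlation around 0.7, which is what makes it usable for selecting
training labels.

The four-arm experiment (train on All / best fraction / worst fraction /
synthetically degraded labels, evaluate on held-out phantoms) is driven by
`cardioseg.pipeline.run_experiment` or the CLI:

```
cardioseg phantom-gen --out cohort/ --n-atlases 9 --n-targets 5
cardioseg experiment-run --out runs/exp1 --seed 0
```

## Layout

```
src/cardioseg/
  core.py        volumes, label maps, NIfTI I/O, warping, morphology, EDT
  phantom.py     synthetic CTA phantoms, weak-label degradations
  bbox.py        whole-heart bounding box (supervoxels + blood-pool threshold)
  mas.py         atlas selection, demons registration, label fusion, CLG
  corrective.py  seed extraction, random walker, multi-pass refinement
  ols.py         reverse-ranking scores, best/worst subset selection
  segnet/        numpy 3D U-Net: layers, model, Dice loss, train/predict
  metrics.py     Dice, Hausdorff, mean surface distance, cohort summaries
  pipeline.py    four-arm experiment orchestration, k-fold splits
  cli.py         `cardioseg` command-line entry points
docs/methods.md  model, parameters, design decisions, limitations
```
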