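# Methods

`cardioseg` implements a hybrid labeling-and-learning framework for
multi-structure segmentation of contrast-enhanced cardiac CT angiography
(CTA): a classical multi-atlas computer label generator (CLG) produces
labels for unlabeled volumes; a reverse-ranking (RR) score grades those
labels without any ground truth; and a patch-based 3D U-Net is trained on
the best-ranked labels. Because clinical CTA cohorts with expert labels are
rarely shareable, the package ships a synthetic phantom generator with exact
ground truth and exercises the whole chain on it.

## Data model and conventions

Volumes and label maps are axis-aligned grids with physical spacing in mm:
world coordinate = origin + index · spacing, indices 0-based, bounding boxes
half-open. Direction cosines are deliberately out of scope (phantoms are
axis-aligned; NIfTI affines written by the package are diagonal). Structure
codes are fixed: background 0, LV 1, RV 2, LA 3, RA 4, LVM 5, then
auxiliary tissues lung 6, chest wall 7, liver 8, spine 9, descending
aorta 10. Codes 1–5 are the five main cardiovascular structures carried by
final outputs; 6–10 are internal scaffolding for corrective segmentation.

Morphology uses Euclidean-ball structuring elements measured in mm via the
exact anisotropy-aware distance transform, so "erode by 5 mm" is the same
physical operation at any voxel size. Erosion keeps a voxel iff no
background voxel center lies within the closed ball (EDT > r); dilation adds
voxels whose distance to the mask is ≤ r. The two are exact adjoints, which
gives opening/closing their lattice properties (opening ⊆ mask ⊆ closing).
On coarse grids this quantizes: at 5 mm spacing a "5 mm erosion" removes
exactly one voxel shell.

## Phantom generator

The phantom emulates what the framework actually relies on in a contrast
CTA: topology and contrast, not anatomy. A parametric template in a fixed
160 mm field of view contains ellipsoidal chamber cavities (LV, RV, LA,
RA), a 6 mm ellipsoidal-shell LV myocardium closed around the LV, a tubular
descending aorta, bone-density spine, flanking lungs, a liver, and a chest
wall ring. Intensities are HU-like per-structure means — blood pool 400
(contrast-enhanced), LVM 90, soft tissue 30, liver 60, lung −800, spine
700, outside-body air −1000 — plus Gaussian noise (default SD 15). The
constructor enforces the contrast ordering blood pool > myocardium > lung.

Per-subject variation is a random affine (per-axis scale 0.92–1.08,
rotation ±7° about z, translation ±5 mm) composed with a smooth random warp
(5³ control points, 3 mm amplitude, cubic upsampling). Image and labels are
sampled from the same warped template coordinates, so the ground truth is
exact by construction. Defaults are 64³ voxels at 2.5 mm; tests also use
40³ @ 4 mm and 32³ @ 5 mm profiles of the same anatomy.

What the phantom does *not* model: partial-volume blur, beam hardening,
motion, anatomical pathology, inter-subject topology changes. Passing tests
therefore demonstrate that the pipeline's logic and numerics are correct
and that its quality signals behave as designed under realistic contrast
and geometric variation — not that clinical accuracy numbers transfer.

Two controlled degradations support the quality-scoring experiments:

- **Synthetic weak labels**: each chamber is replaced by its exact 5 mm
  Euclidean erosion and the LVM is expanded over the ring between the
  original and eroded LV cavity, i.e. the myocardium covers the entire
  original LV cavity outside the shrunken blood pool. Only labels are
  degraded; images are untouched. A chamber thinner than the erosion
  radius vanishes with a warning.
- **Graded corruption**: each chamber is eroded by 3·severity mm (like the
  weak-label recipe, the myocardium is not eroded) and every main structure
  loses voxels within 4 mm of its boundary at rate 0.45·severity. The
  random removal draws
  depend only on the seed, not the severity, so corruptions at increasing
  severity are *nested* and true Dice is monotone non-increasing by
  construction — which is what makes the rank-correlation experiment a
  clean test of the RR score. The mapping is bounded below the synthetic
  weak-label damage on purpose: graded corruption emulates the organic
  quality spread of computer labels, whose worst members are still milder
  than the deliberate negative control; were severity 1 allowed to exceed
  the weak-label recipe, the weak-label arm would no longer be the worst
  condition and the subset-ordering experiment would measure nothing.

## Bounding-box detection

The heart is localized from its contrast-filled blood pool: SLIC
supervoxels (spacing-aware, default 1500 segments, compactness 0.05),
keep supervoxels with mean intensity above 200 HU-like, bridge nearby kept
supervoxels with a 12 mm morphological closing, take the largest connected
group, box its voxel extent, and expand by a 10 mm margin per face. The
closing step is needed because the four chambers are separate bright
components separated by sub-threshold myocardium and mediastinum; without
it the "largest group" would be a single chamber (or the aorta–spine
column). All thresholds live in `BBoxConfig`.

## Multi-atlas computer label generator

**Atlas selection.** Similarity between the bounding-box-cropped target and
each cropped atlas is the mean local structural similarity (windowed
luminance/contrast/structure product) on 4× downsampled images — a fast
selection strategy. Intensities are normalized by clipping at the 1st/99th
percentile and rescaling to [0, 1]; percentile (rather than fixed-window)
normalization makes the ranking invariant to global affine intensity
rescaling of the target. The k = 9 best atlases are used; ties break by
ascending atlas id.

**Registration.** A compact multiresolution demons-style registrar: per
pyramid level (default ¼, ½, full resolution with 60/40/20 iterations), the
update force is diff · ∇(warped)/(|∇|² + α²·diff²), smoothed by a fluid
Gaussian (4 mm), composed additively, with the total field smoothed by a
diffusion Gaussian (2 mm). The best-seen field (including the identity) is
returned, so registration can never degrade the similarity metric. The
registrar sits behind a narrow interface so an external engine could be
substituted. Constant images return a zero field with a warning.

**Fusion.** Per-voxel majority vote over the warped atlas labels,
background votes included. Ties break by a fixed priority — LV, LA, RV,
RA, LVM, then auxiliary codes ascending, then background — the same
precedence used when combining network output channels.

## Corrective segmentation (seeded random walker)

Seeds: each fused main structure contributes its 3 mm erosion; non-cardiac
tissues are seeded by intensity heuristics outside an 8 mm margin around
the fused heart (lung < −400; bone > 550; descending aorta = largest bright
component in 250–550; liver ≈ 48–140 HU-like; chest wall / mediastinum
−60–48), each eroded 2 mm for confidence.

The walker solves the combinatorial Dirichlet problem on the 6-connected
voxel graph with Grady edge weights w_ij = exp(−β (I_i − I_j)²) + 10⁻⁶,
β = 90, on intensities normalized to [0, 1]. Normalization clips to a
*soft-tissue window* (−100 to 250 HU-like) rather than the full intensity
range: with full-range scaling the myocardium/soft-tissue step (~60 HU) is
only ~4 % of the scale and β = 90 cannot see it, while the narrow window
makes that edge weight ≈ 0.07 and keeps noise-level weights ≈ 0.85. The
sparse system is solved directly (sparse LU) up to 40 000 unknowns and by
Jacobi-preconditioned conjugate gradients beyond; probabilities partition
unity to solver tolerance, seeded voxels are fixed, and unseeded graph
components fall back to background with a warning.

"Multiple passes" means: one global pass with all seeded codes (carving
non-cardiac tissue off the fused heart), then one binary pass per main
structure in priority order, each restricted to a 10 mm neighborhood of the
structure. In the binary passes the opposing seeds are a tight 2 mm erosion
of the *current complement*, not the original distant tissue seeds —
otherwise the unseeded band is wide and the structure inflates into
unclaimed territory. Voxels leaving a structure take the global pass's
runner-up code; earlier-priority structures are never overwritten, so the
five structures stay pairwise disjoint. Post-processing keeps each
structure's largest 6-connected component and applies a 2 mm closing,
assembling in priority order. On correct input, refinement is
non-destructive for chambers (Dice ≥ 0.99); the thin LVM shell (~2 voxels
at 2.5 mm) may see up to a few percent Dice change from single-voxel
boundary jitter, which is a quantization effect, not a logic error.

## Reverse-ranking score and label selection

To grade a computer label without ground truth, the registration direction
is reversed: the target (moving) is registered to each of its k most
similar atlases (fixed), the computer label is warped into each atlas
space, and its per-structure Dice against the atlas's reference label is
averaged over the k atlases. The aggregate RR score is the unweighted mean
over the five structures (per-structure scores are always retained).
Structures missing from a computer label count as Dice 0 rather than being
skipped, so catastrophic failures sink in the ranking. Ranking a cohort by
aggregate RR and keeping the best/worst round(fraction·n) cases (round
half-up; ties by ascending case id) yields the strong-label (SL) and
weak-label (WL) training subsets.

On phantom cohorts with graded corruptions, aggregate RR correlates with
true mean Dice (Spearman ρ ≈ 0.7 in the shipped experiments), and
mean RR orders SL ≥ full cohort ≥ WL > synthetically degraded labels.

## Network

A 3D U-Net implemented as a compact numpy layer library with explicit
backpropagation (convolutions via im2col, analytically verified gradients).
Each block is (3³ conv → ReLU → group norm) ×2; downsampling is 2× max
pooling, upsampling nearest-neighbor, skips concatenated; a 1³ convolution
and a sigmoid produce five binary channels — segmentation is five binary
tasks, not one multiclass task. The loss is the per-channel soft Dice loss
1 − (2Σpt + ε)/(Σp + Σt + ε), averaged over channels, with ε = 1 (so
empty-vs-empty channels contribute zero loss). The optimizer is Adam with
L2 weight decay folded into the gradient; the learning rate drops by
γ = 0.1 at multi-step milestones.

Two profiles exist. The full-scale profile mirrors a clinical-workstation
configuration: patch 64×100×100 with stride 32×64×64, 64 base feature
maps, 16 norm groups, lr 10⁻⁴, weight decay 10⁻⁴, 100 epochs, batch 1,
milestones (50, 75). The desk profile — the configuration the test suite
exercises end to end on one CPU — uses 8 base features, 4 groups, 3
resolution levels, lr 10⁻², ~25 epochs, and a patch covering the whole
bounding-box crop of the small-grid phantoms; at these problem sizes the
full crop fits in one patch, which also gives the network the global
context needed to tell the four chambers apart (they are locally identical
blood pools).

Prediction slides the patch grid over the crop (a clamped final start
guarantees full coverage), averages overlapping channel probabilities,
thresholds each channel at 0.5, and combines channels by the priority LV,
LA, RV, RA, LVM — a voxel positive in several channels takes the earliest.

## Evaluation metrics

Dice 2|A∩B|/(|A|+|B|) (both-empty defined as 1 with a flag); Hausdorff
distance as the full maximum (not a percentile) over surface-to-surface
Euclidean distances in mm; mean surface distance as the equal-weight
average of the two directed surface means. Surfaces are mask voxels with at
least one background 6-neighbor. Distances come from the exact Euclidean
distance transform, so small-instance tests can demand agreement with
all-pairs brute force at 10⁻⁶. Cohort summaries report median and IQR
(linear-interpolation / type-7 quantiles, pinned for determinism across
implementations) plus mean ± SD, with undefined (empty-mask) distances
excluded and counted.

## Experiment orchestration

`pipeline.run_experiment` runs the four-arm comparison: **All** (every
computer label), **SL** / **WL** (best/worst fraction by RR), and **sWL**
(the synthetic weak-label degradation applied to the SL labels — never
regenerated independently). All arms share identical network
hyperparameters and the same held-out test phantoms, whose exact ground
truth plays the role of an independent expert-labeled test set. Desk-scale
defaults are 9 atlases, 30 targets, 6 test phantoms, selection fraction
0.2; the clinical-scale numbers (60 atlases, ~1 000 targets, 10 %
selection) are documented but not exercised. A 5-fold splitter
(deterministic, sizes within one) supports cross-validation layouts.
Every random draw descends from one master seed, and rerunning a config
reproduces manifests bit-identically.

## Problem sizes in the shipped experiments

Chosen as the smallest sizes at which each effect is comfortably
observable: CLG quality on 12 targets × 9 atlases at 64³; RR validity on
20 corrupted cases (severities spanning [0, 1], k = 3); the
label-quality-transfer comparison on 8 training / 4 test phantoms at 40³
@ 4 mm (4 mm is the coarsest grid at which the 5 mm weak-label erosion
still removes a voxel shell); single-case overfit at 32³ @ 5 mm with 200
optimizer steps. `scripts/acceptance.py` recomputes the same quantities at
similar sizes from a command-line seed.

## Known limitations

- The registrar is a small-deformation demons variant; it recovers the
  phantom's smooth inter-subject warps but is not a diffeomorphic clinical
  registration engine.
- Auxiliary-tissue seed heuristics are calibrated to the phantom's
  intensity model; on real CTA they would need re-windowing.
- The numpy U-Net is single-threaded BLAS-bound and meant for desk-scale
  experiments, not full-resolution clinical training.
- RR scores are computed with one registration direction and no failure
  screening; a failed reverse registration lowers a case's score, which is
  conservative for selection.
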