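# drseg

Contrast- and resolution-agnostic 3D brain segmentation, built on domain
randomization: training images are synthesized from label maps with fully
randomized per-label contrast, bias fields, and gamma transforms, so the
trained network never sees (and never relies on) a specific MR contrast.

The package is a desk-scale, fully self-contained re-implementation of that
pipeline — no datasets, no GPU, and no deep-learning framework required.
The 3D U-Net, its backpropagation, the AdamW optimizer, and the poly
learning-rate schedule are implemented in numpy (verified against
finite-difference gradients), so everything runs on a single CPU.

## Pipeline

1. **`volio`** — NIfTI I/O, LIA/RAS reorientation (pure permutation/flip),
   cubic-spline intensity resampling and one-hot/trilinear/argmax label
   resampling between voxel spacings.
2. **`labelprep`** — builds an artificial extra-cerebral label by
   closing + hole-filling + dilating the brain mask (4 or 5 voxels by
   resolution), and produces skull-stripped images.
3. **`synthgen`** — the generative model: random affine + elastic
   deformation of the label map, per-label Gaussian intensity sampling,
   multiplicative bias field (coefficient std ~ U(0, 0.9)), min-max
   rescaling and random gamma. No resolution degradation is applied. The
   extra-cerebral label is synthesized but dropped from training targets.
4. **`phantoms`** — nested-ellipsoid brain-like phantom label maps and
   rendered fixed-contrast "validation acquisitions" so the whole pipeline
   is testable with zero downloads.
5. **`network`** — configurable 3D U-Net (instance norm + leaky ReLU),
   Dice + cross-entropy loss, AdamW with decoupled weight decay and
   gradient clipping, poly LR, fold-wise training with synthetic-train /
   real-validation splits.
6. **`inference`** — Gaussian-weighted sliding-window prediction, softmax
   ensembling across folds, validated largest-component post-processing,
   and the LIA / training-resolution round trip back to the native grid.
7. **`evaluate`** — Dice, average surface distance (boundary-voxel KD-tree
   in world mm), missing-label conventions, the 27-of-35 label exclusion
   policy, bootstrap median CIs, TIV-normalized volumetry with
   Mann-Whitney U tests and Bonferroni correction.

## CLI

```bash
drseg make-phantoms --n 24 --shape 48 --spacing 0.7 --seed 1 --out maps/
drseg prepare-labels --in labels.nii --image t1.nii --dilate auto \
      --ec-id 999 --out-labels prep.nii --out-image stripped.nii
drseg generate --labels maps/ --n-per-map 1 --seed 1 --out pairs/
drseg train --pairs pairs/ --val val/ --fold 0 --out model_0/
drseg predict --in t1.nii --models model_0/ --out seg.nii --train-spacing 0.7
drseg evaluate --gt gt/ --pred pred/ --policy default27 --out report.csv
drseg volumetry --segs segs/ --tiv tiv.csv --groups groups.csv \
      --rois 12,17,18 --out stats.csv
```

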