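# zernseg

Deep-learning segmentation and 3D morphometry of micro–nano bone porosity
in Zernike phase-contrast nanoCT volumes.

## The problem

Zernike phase-contrast nano-tomography resolves the lacuno-canalicular
network (LCN) of bone — ellipsoidal osteocyte lacunae interconnected by
sub-micrometre canaliculi — at ~100 nm pixel sizes, but the contrast
mechanism produces *halo* (bright rims at interfaces) and *shade-off*
(dark gradients inside sample edges) artifacts.  These shift local gray
values by more than the separation between tissue classes, so fixed
gray-value thresholds cannot segment such volumes reliably.  `zernseg`
implements the alternative workflow end to end:

* **phantom** — seeded synthetic volumes with the full artifact pathology
  and paired ground-truth labels (background / bone / shade-off / LCN);
* **models + trainer** — a 2D U-Net and a slice-context ("Sensor3D"-style,
  2.5D) network trained with Adadelta, 80/20 splits, augmentation and an
  early-stopping rule (loss improvement ≤ 0.01 % for 10 consecutive
  epochs, cap 100), on a built-in numpy CNN engine (no GPU framework
  required);
* **bootstrap** — staged ground-truth generation (e.g. 20 → 50 → 70
  slices of a 420-slice stack, i.e. 5 % → 12 % → 16 %) with a simulated
  corrector, plus transfer learning to a contrast-shifted 3-class domain;
* **baseline_threshold** — fixed gray ranges and multi-level Otsu, the
  comparator that fails on artifact-laden data;
* **morphometry** — island removal + closing, shade/bone merge, porosity
  `100·V_LCN/(V_LCN+V_bone)`, local thickness (largest inscribed sphere),
  26-connected LCN units ≥ 100 voxels with volumes in µm³;
* **stats_compare** — Wilcoxon signed-rank and Spearman rank correlation
  over the (architecture × training size × batch size) experiment grid.

Evaluation uses the per-class Dice coefficient
`2|P∩T| / (|P|+|T|)` and categorical cross-entropy.

## Worked example

```python
from zernseg import (PhantomSpec, generate_phantom, ModelConfig, StagePlan,
                     run_bootstrap, predict_volume, label_porosity)
from zernseg.morphometry import report

spec = PhantomSpec(seed=7)          # 64x128x128, 8 lacunae, target porosity 2.1 %
vol, labels = generate_phantom(spec)
print(f"label porosity: {100*label_porosity(labels):.2f} %")

plan = StagePlan(sizes=(8, 20, 28))  # staged ground truth, scaled to 64 slices
cfg = ModelConfig(architecture="sensor3d", patch_size_vox=64, seed=7)
boot = run_bootstrap(vol, labels, plan, cfg, seed=7,
                     architectures=("sensor3d",), max_epochs=20)
_, pred = predict_volume(boot.final_models["sensor3d"], vol)
rep = report(pred)
print(f"CNN porosity: {rep.porosity_percent:.2f} %  "
      f"({rep.n_components} LCN units, "
      f"max thickness {rep.thickness_stats.max_um:.2f} um)")
```

Typical output (seed 7):

```
label porosity: 1.99 %
CNN porosity: 1.99 %  (4 LCN units, max thickness 1.02 um)
```

The label porosity sits within the generator's ±20 % band of the 2.1 %
target; the porosity recovered by the bootstrapped slice-context model
lands within half a percentage point of the oracle value, and the LCN
units are clusters of the 8 seeded lacunae joined by their canaliculi
(prediction errors can split a thin canaliculus, so the unit count can
sit slightly above the phantom's connectivity-graph component count).

A CLI mirrors the library: `zernseg phantom|train|bootstrap|segment|
threshold|morph|compare --help`.

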