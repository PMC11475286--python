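# pectseg

Pectoral-muscle segmentation toolkit for mediolateral-oblique (MLO)
mammograms. In MLO views the pectoral muscle appears as a bright corner
wedge whose intensity profile interferes with automated breast-tissue
analysis, and burned-in annotations (machine labels, radiologist marks)
add a fourth spurious class. `pectseg` provides the full pipeline for
reducing such images to three clean classes — background (0), breast
(1), pectoral muscle (2) — and training a semantic segmentation model
on them:

- **preprocess** — binarization (Otsu or fixed threshold), 4-connected
  island labelling, largest-island breast isolation
  `S = argmax_k area(I_k)`, annotation stripping with CSV metadata
  export, and VOI-LUT contrast windowing (DICOM/PNG/PGM input).
- **imbalance** — frequency-derived loss weights
  `α = λ·Y⁺/(Y⁺+Y⁻)`, `β = Y⁻/(Y⁺+Y⁻)` and their three-class
  one-vs-rest generalization, plus the weighted cross-entropy and the
  combined objective `L(W) = L_class + L_seg`.
- **augment** — mask-consistent random affine transforms (translation
  ≤ 10 px, rotation within 30°, scale 0.9–1.1), single-type copies that
  quadruple a dataset (322 → 1288), with exact provenance replay.
- **trainer** — a DeepLab-v3+-style network (residual-bottleneck
  encoder with the 3/4/6/3 stage layout or a tiny 1/1/1/1 preset, ASPP,
  decoder, per-pixel softmax) implemented in pure NumPy, trained with
  SGDM: `v_{t+1} = μ·v_t − η·∇L(W_t)`, `W_{t+1} = W_t + v_{t+1}`, and a
  70/20/10 train/validation/test split (1288 → 902/258/128).
- **evaluate** — per-class Dice `2|P∩G|/(|P|+|G|)` and Jaccard
  `|P∩G|/|P∪G|`, grand-total-normalized confusion matrices, CDF and
  threshold-exceedance summaries, and per-class area-error accounting.
- **phantom** — synthetic MLO-like mammograms (half-ellipse breast,
  corner muscle wedge, planted bright annotation islands, Gaussian
  intensity noise) with exact ground truth, so the whole pipeline is
  testable end-to-end without clinical data.

## Worked example

```python
import numpy as np
from pectseg import (PhantomSpec, generate_dataset, ModelConfig, TrainConfig,
                     build_model, train, predict, dice_per_class)

pairs = generate_dataset(96, PhantomSpec(image_size=(96, 96), n_annotations=0),
                         seed=1)
model = build_model(ModelConfig(input_size=(96, 96), backbone="tiny", seed=1))
cfg = TrainConfig(learning_rate=0.05, momentum=0.9, epochs=12, batch_size=4,
                  lam=1.0, seed=1)
result = train(model, pairs, cfg)
print("class weights:", np.round(result.class_weights.per_class, 3))

_, _, test_idx = result.split
preds = predict(result.model, [pairs[i][0] for i in test_idx])
for k, name in enumerate(("background", "breast", "muscle")):
    d = np.mean([dice_per_class(p, pairs[i][1], k)
                 for p, i in zip(preds, test_idx)])
    print(f"held-out dice {name}: {d:.4f}")
```

prints

```
class weights: [1.02  0.6   1.38]
held-out dice background: 0.9982
held-out dice breast: 0.9985
held-out dice muscle: 0.9961
```

The class-weight vector shows the imbalance correction: the rare muscle
class (≈8 % of pixels) gets the largest weight, the dominant breast
class the smallest. The held-out Dice values are per-class means over
the ten test phantoms never seen during training; values near 1 mean
the predicted regions almost exactly overlap the ground truth.

The same stages are available from the shell:

```sh
pectseg synth --n 20 --seed 7 --out data/
pectseg preprocess --input data/ --out clean/
pectseg weights --masks data/ --lam 1.0 --out weights.json
pectseg augment --data data/ --copies 3 --out augmented/
pectseg train --data data/ --config train.yaml --out run/
pectseg eval --pred predictions/ --truth data/ --out metrics.json
pectseg report --metrics metrics.json --out report/
```

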