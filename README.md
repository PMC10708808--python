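# ipseg

Position-attention, inverted-pyramid segmentation of low-resolution cardiac
images — a self-contained Python implementation with a synthetic phantom
generator, so the whole pipeline trains and evaluates on one CPU with no
external data.

## The problem

Echocardiographic frames are small (typically 112 × 112 pixels), noisy with
multiplicative speckle, and carry strong positional priors: the ventricle
sits in roughly the same part of every frame.  `ipseg` targets exactly this
regime with two mechanisms:

* **Inverted pyramid** — the input is *enlarged* by bicubic interpolation
  (cubic-convolution kernel, a = −0.5) to a ladder of factors such as
  [1×, 2×, 4×]; one network branch per rung; per-scale predictions are fused
  at base resolution by a 1×1 convolution:
  `y = conv(concat(y₁, y₂, y₃))`.
* **Position Attention Block (PABlock)** — features are average-pooled
  separately over width and height, fused and compressed (ratio r = 64),
  enriched with a sinusoidal positional encoding
  (`sin(p / base^{i/d})`, `cos(p / base^{(i−1)/d})`, d = 512, base = 1000),
  restored to full extent, replicated across the orthogonal axis, and used
  to gate the input residually: `Y = X + X ⊙ σ(conv(O_h + O_w))`.  Each
  scale branch runs backbone → ASPP → 3 × PABlock → segmentation head.

Predictions are scored with Dice, Jaccard, Precision, Recall and F-Measure
(a = 1, where F-Measure ≡ Dice) from exact pixel confusion counts.

The network and its training loop run on a small NumPy reverse-mode
autograd shipped with the package (`ipseg.nn`); every adjoint is verified
against finite differences in the test suite.

## Worked example

```python
import numpy as np
from ipseg import PANetSegmenter, generate_phantom
from ipseg.metrics import dice

samples = [generate_phantom(i) for i in range(160)]
X = np.stack([s.image.pixels[0] for s in samples]).astype(np.float32)
y = np.stack([s.mask for s in samples])

est = PANetSegmenter(factors=(1.0, 2.0), epochs=10, random_state=0)
est.fit(X[:128], y[:128], X[128:], y[128:])   # 128 train / 32 held-out
print(round(est.score(X[128:], y[128:]), 4))
print(round(float(np.mean([dice(np.zeros_like(g), g) for g in y[128:]])), 4))
```

prints

```
0.9687
0.0
```

i.e. the tiny two-scale model reaches a held-out mean Dice of about 0.96 on
the phantom task after ten epochs (roughly a minute on one CPU), while the
all-background baseline scores 0.  `est.predict(X)` returns binary masks,
`est.history_` the per-epoch loss and validation Dice.

The same pipeline is available from the shell:

```bash
ipseg synth --out data --n 160 --seed 0
ipseg train --manifest data/manifest.csv --out model.npz --epochs 10
ipseg eval  --manifest data/manifest.csv --checkpoint model.npz --split test
ipseg predict --manifest data/manifest.csv --checkpoint model.npz --out preds
ipseg ablate --manifest data/manifest.csv --out ablation.csv
```

`ipseg ablate` trains the 2 × 2 grid {pyramid on/off} × {PABlock on/off}
with a shared seed and reports the five metrics per variant.

## Layout

| Module | Contents |
| --- | --- |
| `ipseg.pyramid` | bicubic kernel/interpolation, inverted pyramid, PNG I/O |
| `ipseg.pablock` | directional pooling, positional encoding, PABlock, head |
| `ipseg.panet` | backbones, ASPP, per-scale branches, multi-scale fusion |
| `ipseg.metrics` | confusion counts and the five overlap metrics |
| `ipseg.synthetic_data` | phantom generator and dataset/manifest writer |
| `ipseg.engine` | training loop, checkpoints, evaluation, ablation grid |
| `ipseg.estimator` | `PANetSegmenter`, the scikit-learn-style front end |
| `ipseg.nn` | NumPy autograd, layers, SGD |

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
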