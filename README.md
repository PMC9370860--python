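# fruitseg

Semi-supervised, multi-stage transfer learning for fruit/background
**pixel segmentation** in orchard imagery — for researchers in
agricultural robotics and biological image analysis who want to train a
fruit detector **without manual pixel annotation**, and for anyone who
wants a fully self-contained, CPU-only test bed for pseudo-labeling
curricula.

Manually labeling field images pixel-by-pixel is the dominant cost of
deploying segmentation on a farm robot. The pipeline implemented here
replaces it with a cascade of automatically labeled training sets:

1. **Stage 1 — First CE net.** Fruits photographed on a neutral
   background under uniform light (SET1) are labeled by a color
   threshold in RGB space (`R ≥ 130`, `R−G ≥ 40`, `R−B ≥ 40`) followed
   by three morphological operators — small-component removal, stem
   discarding by ellipse eccentricity (`e = √(1−(b/a)²) > 0.92` after
   disk erosion, restored by dilation), and hole filling. A small
   encoder–ASPP–classifier network (2-class, pixel-wise cross-entropy)
   is trained on these auto-labels.
2. **Stage 2 — Final CE net.** The First CE net pseudo-labels the
   harsh-light images (SET2), where shadows defeat fixed color
   thresholds; the same morphology cleans its predictions; the network
   is retrained on SET1 + SET2.
3. **Stage 3 — TNA / FIA.** The CE corpus is extended either with
   **true negatives** (fruitless field frames whose masks are set to all
   zeros → the TNA net, which suppresses false positives at the price of
   recall) or with **field frames pseudo-labeled by the CE net with no
   morphological finishing** (→ the FIA net, which balances both error
   types and yields the best F1).

Every training set is expanded exactly **20×** by paired augmentation
(right-angle rotations, reflection, contrast, exposure). Evaluation is
pixel-wise: P, R, F1, global/mean accuracy, mean/weighted IoU
(per-image averaged), plus four-color error maps (TP white, TN black,
FN magenta, FP green).

Everything runs on seeded synthetic orchard scenes with exact ground
truth — including yellow dry-leaf "confusers" whose withered tips
overlap the fruit hue — so the whole cascade is testable on one CPU
with no downloads. The network is implemented directly in numpy
(im2col convolutions, explicit backprop, Adam); scikit-image provides
the morphology.

## Worked example

```bash
python examples/02_autolabel.py
```

```
scenes: 20
mean IoU of auto-labels vs ground truth: 0.982
worst scene IoU: 0.964
```

The auto-labeler recovers 98% of the fruit-pixel overlap with the exact
generator masks, with stems removed (stems are rendered in fruit-like
red, picked up by the threshold, and must be eliminated by the
eccentricity filter).

```bash
python examples/04_train_and_evaluate.py
```

```
final training loss: 0.0399
held-out: P=95.6%  R=95.0%  F1=95.3%  mean IoU=94.3%  weighted IoU=96.3%
error-map pixel counts: {'white/TP': 899, 'black/TN': 3096, 'magenta/FN': 51, 'green/FP': 50}
```

Ten epochs on 40 neutral-background scenes suffice for the tiny net to
segment held-out scenes at F1 ≈ 0.95.

```bash
python examples/05_cascade.py     # the full curriculum, a few minutes
```

prints each stage's training-set arithmetic (e.g. 28 originals → 560
after 20× augmentation) and the per-net field metrics; across seeds the
expected ordering is P(TNA) > P(CE), R(TNA) < R(CE) and
F1(FIA) > max(F1(CE), F1(TNA)) — the precision/recall trade the
curriculum is designed around.

A thin CLI mirrors the library (`fruitseg synth | autolabel | augment |
train-stage | run-cascade | evaluate`); see `--help` on each
subcommand. The library API (`import fruitseg`) is the primary
interface; `examples/` has one narrative script per capability.

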