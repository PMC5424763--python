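# seedvision

Machine-vision grading of seed quality from color images, modelled on the
automatic optical sorters used for small vegetable seeds (e.g. Chinese
cabbage).  A camera frame shows a grid of seeds on a dark field; each seed
must be graded **good** or **NG** ("not good": misshapen, discolored, or
surface-defective) fast enough to drive a pneumatic sorter.

The package implements the full software pipeline:

1. **Segmentation** (`seedvision.imaging`) — global threshold on the
   mean-channel gray image (Otsu or fixed), morphological opening, hole
   filling, 8-connected labelling; each seed becomes a `SeedRegion` with a
   tight mask, masked color crop and traced boundary contour.
2. **Features** — 27 per seed:
   * 15 shape descriptors (`seedvision.shape`): circularity `4πA/P²`,
     compactness `2√(πA)/P`, circumcircle defect ratio, Feret elongation
     `Dmin/Dmax`, moment-ellipse eccentricity `√(a²−b²)/a`, ellipticity
     index `πa²/A`, radial out-of-roundness, convex-hull angle extremes,
     deepest convexity defect, and three symmetry area ratios over the
     principal-axis quadrants.
   * 6 color features (`seedvision.color`): mean B, G, R, hue, saturation
     (geometric HSI model) and mean gray `(R+G+B)/3`.
   * 6 texture features (`seedvision.texture`): angular second moment,
     entropy, contrast and homogeneity of the gray-level co-occurrence
     matrix (distance 1; orientations 0°/45°/90°/135°, averaged), plus the
     local-similarity-pattern (LSP) gray average and a Tamura-style
     coarseness.
3. **Feature selection** (`seedvision.sffs`) — sequential floating forward
   selection against the validation accuracy of a network trained on the
   candidate subset.
4. **Classification** (`seedvision.bpnn`) — two from-scratch three-layer
   back-propagation networks (logistic sigmoid, online gradient descent,
   learning rate 0.01, MSE tolerance 0.01, hidden size
   `nh = ⌈0.5·(ni+no)⌉`): one on shape features, one on color+texture.
   A seed is good only if **both** networks say good (AND rule).
5. **Evaluation** (`seedvision.evaluation`) — 2×2 confusion matrix
   (rows = predicted, columns = actual) with per-class and pooled accuracy.

Because real sorter imagery is rarely available, `seedvision.synthetic`
renders seed-like frames with exact ground truth (controllable shape class,
surface color class and spot density), so every stage is testable end to end.

## Worked example

Train both networks on synthetic seeds, select features by SFFS, and grade a
400-seed test set:

```python
import numpy as np
import seedvision as sv
from seedvision.bpnn import TrainConfig, train_classifier
from seedvision.features import SHAPE_POOL, COLORTEX_POOL
from seedvision.sffs import make_subset_criterion

train_df = sv.make_feature_dataset(150, 150, rng_seed=11)
val = np.random.default_rng(11).random(len(train_df)) < 0.5

def build_net(pool, ok_col, basic):
    df = train_df.copy()
    df["label"] = ["good" if ok else "ng" for ok in df[ok_col]]
    crit = make_subset_criterion(df[~val], df[val],
                                 TrainConfig(rng_seed=3, max_epochs=400),
                                 pool_columns=pool)
    trace = sv.sffs(set(pool), basic, crit, max_steps=30)
    cols = [pool[i] for i in sorted(trace.best_subset)]
    return train_classifier(df[cols].to_numpy(float), list(df["label"]),
                            TrainConfig(rng_seed=5, max_epochs=3000),
                            feature_columns=cols)

shape_net = build_net(SHAPE_POOL, "shape_ok", basic=9)
colortex_net = build_net(COLORTEX_POOL, "colortex_ok", basic=6)

rng = np.random.default_rng(77)
labels = [["good" if rng.random() < 0.5 else "ng" for _ in range(20)]
          for _ in range(20)]
frames, truths = sv.synthetic.make_labeled_frames(labels, rng_seed=77, grid=(4, 5))
_, report = sv.run_pipeline(frames, shape_net, colortex_net, truth=truths)
print(report["acc_good"], report["acc_ng"], report["acc_overall"])
```

Output:

```
100.0 99.49 99.75
```

i.e. on this 400-seed synthetic test set every true-good seed is accepted,
99.49 % of NG seeds are rejected, and 99.75 % of all seeds are graded
correctly by the dual-network AND rule.

Confusion-matrix arithmetic works on any tally.  For example, a field test
tally of 8922 good and 7128 NG seeds:

```python
import numpy as np, seedvision as sv
cm = sv.ConfusionMatrix2(np.array([[8166, 788], [756, 6340]]))
print(sv.accuracies(cm))   # (91.53, 88.95, 90.38)
```

giving 91.53 % good-class accuracy, 88.95 % NG-class accuracy and a pooled
overall accuracy of 90.38 %.

## Command line

```bash
seedvision --seed 3 synth --frames 2 --out frames/
seedvision segment frames/frame_000.png --out segments/
seedvision extract frames/*.png --out features.csv
seedvision select --features features.csv --pool shape --basic 9 --out trace.csv
seedvision train --features features.csv --net shape --out shape.json
seedvision classify --frames frames/ --shape-model shape.json \
    --colortex-model colortex.json --out report/
seedvision evaluate --pred report/predictions.csv --truth truth.csv
```

All stage parameters live in one YAML config (`--config run.yaml`); see
`docs/methods.md` for the tunables and their defaults.

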