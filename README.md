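# lfe — small-object localization from sparse point annotations

`lfe` localizes dense small objects — cell nuclei in histopathology, cells in
microfluidic droplets, insects, heads in crowds — from images in which only a
handful of objects per training image carry a point annotation.  It implements
the learn-from-educator (LFE) approach: a location-map predictor is trained by
positive-unlabeled (PU) learning over *redundant count maps*, then refined by
beta-mixture pseudo-labeling, and objects are read out as prominent local
maxima of the predicted map.

## The method

A ground-truth **location map** `P_gt` carries a unit impulse at every
annotated center.  Its **redundant count map** is the r×r box sum

    C_gt(i, j) = Σ_{(m,n) ∈ S_r(i,j)} P_gt(m, n),

so each object contributes to r² entries; with `r` slightly smaller than the
object diameter this multiplies the positive-pixel rate by r² while keeping at
most one object per window.  Crucially, minimizing the L2 distance between
predicted and ground-truth count maps over non-negative location maps recovers
the impulse map itself, so a trained predictor develops sharp local maxima at
object centers.

With only a few labels, non-zero count-map entries are known positives and the
zero entries are *unlabeled* (background or hidden objects).  Stage 1 minimizes
the non-negative PU risk

    R̂_pu = π_p · R̂_p⁺ + max(0, R̂_u⁻ − π_p · R̂_p⁻),

where `R̂_p⁺` is the mean squared count error on known-positive entries, the
negative terms use a saturating `tanh` of the predicted counts over all N
entries (de-biased by the masked entries), and `π_p` is the positive class
prior — estimated as `μ r² / (ω h)` or fixed at 0.1.

Stage 2 turns unlabeled entries into pseudo-labels: the losses
`l = C_pre²` on the unlabeled region (after removing clear negatives,
`l < 0.01`) are fitted with a two-component **beta mixture** by EM; the
posterior of the high-mean component scores every local maximum of the
predicted map, and confident peaks become predicted positives while the rest
becomes predicted negatives.  An ordinary positive–negative stage then
minimizes an L2-tanh loss at a 100× smaller learning rate.

Evaluation matches predictions to centers greedily (nearest pair first,
one-to-one) within a dataset-dependent pixel radius, reporting precision,
recall, F1, and the mean localization error.

## Worked example

```python
from lfe import LFELocalizer, TrainConfig, CountMapConfig
from lfe.synthetic import SceneConfig, generate_dataset

scene = SceneConfig()                      # 96×96 px, ~15 soft disks r=4, 1 label/image
train = generate_dataset(scene, 48, seed=7)
val   = generate_dataset(scene, 8,  seed=8)

cfg = TrainConfig(kernel=CountMapConfig(7), class_prior=0.1,
                  stage1_epochs=50, stage2_epochs=15, eval_threshold=4.0)
results = LFELocalizer(train, val, cfg).fit(stages=2)
print(results.summary())

test = generate_dataset(scene, 16, seed=9)
print(results.evaluate(test))
print(results.peak_statistics(test))
```

prints (about six minutes on one CPU):

```
Learn-from-educator small-object localizer
============================================
kernel size r:            7
class prior pi_p:         0.1
training images:          48
validation images:        8
annotations per image:    1.0
network parameters:       5361
--------------------------------------------
stage 1 (PU risk):        best val F1 1.000 @ epoch 21
stage 2 (pseudo-label):   best val F1 1.000 @ epoch 0

{'precision': 1.0, 'recall': 1.0, 'f1': 1.0, 'tp': 240, 'fp': 0, 'fn': 0}
{'n': 240, 'mean_value': 0.207, 'sd_value': 0.041,
 'mean_proportion': 0.179, 'sd_proportion': 0.031, 'gaussian_center': 0.117}
```

Only one of ~15 objects per image (≈7% of all annotations) was labeled, yet
all 240 test objects are found with no false positives at the 4-px matching
radius.  `results.detect(image)` returns the per-image detections as a
DataFrame of `(row, col, score, proportion)`.  The peak statistics show the
count-map signature: the mean response at a detected center (0.207) clearly
exceeds the central density a matched Gaussian kernel would put there
(`1/(2π(r/6)²) = 0.117`), with each peak carrying ~18% of its 7×7 window sum.

A command-line interface mirrors the library: `lfe simulate`, `lfe train`,
`lfe detect`, `lfe evaluate`, `lfe benchmark`.

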