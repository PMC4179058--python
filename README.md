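# thermotrack

Automated detection and recognition of warm animals in top-view thermal
imagery, aimed at wildlife-friendly agriculture: finding rabbits, leverets,
chickens or fawns in a field from a camera looking straight down, before
mowing machinery reaches them. The package implements the full processing
chain for calibrated thermal recordings (2-D temperature rasters in °C) and
ships a synthetic thermal-scene generator with ground truth, so every stage
is testable without field data.

## Method

1. **Detection.** Each frame is thresholded at `th = t̃ + c`, where `t̃` is
   the median frame temperature and `c` (default 5 °C) keeps only objects
   significantly warmer than the background. The median adapts the
   threshold to each frame, so sun-heated scenes and cool evenings use the
   same `c`. Above-threshold pixels are grouped into blobs by connected
   components.
2. **Thermal signature.** For each blob the mask is dilated once with a
   4-connected cross to sample a ring just outside the object (iteration
   `i = −1`), then the 4-connected perimeter contour is repeatedly recorded
   and peeled until the blob is exhausted (`i = 0 … M`). The sequence of
   contour mean temperatures `cm(i)` is the thermal signature: insulated
   animals show a steep rise over the first interior contours, while lamps
   are flat and warm soil mounds rise gently. The signature is invariant to
   translation, right-angle rotation and — after subtracting the outer-ring
   mean — to absolute scene temperature.
3. **DCT features.** Signature length depends on object size, so the
   normalized signature is parameterized by its first 7 coefficients of a
   length-compensated orthonormal type-II DCT (coefficient 0 equals the
   sequence mean for any length). Seven coefficients retain ≥ 95 % of the
   signature energy for ≥ 95 % of synthetic animal signatures.
4. **kNN classification.** A k-nearest-neighbor vote (`k = 11`, Euclidean
   distance) labels each feature vector animal/non-animal and returns the
   animal-vote fraction `g_A = k_A / k` as a likelihood.
5. **Tracking and belief.** Detections are linked across frames by a gating
   tracker (velocity-extrapolated guess region, 190 px radius, tracks
   survive 3 missed frames). Each accepted detection updates the track's
   animal belief by Bayes' rule,
   `Bel(n) = Bel(n−1)·g / (Bel(n−1)·g + (1−Bel(n−1))·(1−g))`,
   with `g` clamped to [0.05, 0.95]. A track whose final belief exceeds 0.5
   is an animal, and all of its detections inherit that label — temporal
   aggregation that corrects ambiguous single-frame decisions at high
   altitude.

Evaluation uses the balanced classification accuracy
`(sensitivity + specificity) / 2`, robust to the class imbalance caused by
altitude-dependent detection loss; object pixel footprints shrink with the
altitude squared (a 305-pixel animal at 5 m covers 19 pixels at 20 m).

## Worked example

```python
import numpy as np
import thermotrack as tt

vals = np.full((7, 7), 20.0)     # 20 °C background
vals[2:5, 2:5] = 30.0            # 3x3 hot object
frame = tt.ThermalFrame(values=vals)

blob = tt.detect(frame)[0]                      # threshold = 20 + 5 = 25 °C
sig = tt.extract_signature(frame, blob)
print(sig.samples)        # [20. 30. 30.]  outer ring, perimeter, core
print(sig.contour_sizes)  # [12  8  1]
fv = tt.dct_parameterize(tt.normalize_signature(sig))
print(np.round(fv.coefficients, 3))
# [ 6.667 -4.082 -2.357  0.     0.     0.     0.   ]

print(tt.update_belief(0.8, 0.95))   # 0.987012987...
print(tt.pixel_footprint(305, 5, 20))  # 19
rep = tt.confusion_metrics(tt.ConfusionMatrix(TP=2056, FP=332, FN=330, TN=1663))
print(rep.to_dict())
# {'accuracy': 0.8489, 'balanced_accuracy': 0.8476,
#  'sensitivity': 0.8617, 'specificity': 0.8336}
```

The signature `[20, 30, 30]` reads: the ring just outside the object
averages 20 °C, the object's perimeter and core both 30 °C; normalization
subtracts the ring mean, and the DCT coefficients encode the resulting
step. The belief update shows one strong animal observation (g = 0.95)
lifting a 0.8 prior to 0.987.

A command-line interface mirrors the stages:

```sh
thermotrack simulate --output run/           # synthetic recording + truth
thermotrack detect --input run/frames.tif --output run/blobs.json
thermotrack features --input run/frames.tif --blobs run/blobs.json \
    --output run/features.csv
thermotrack train --output run/training.csv  # synthetic labeled vectors
thermotrack classify --features run/features.csv --training run/training.csv \
    --output run/predictions.csv
thermotrack track --predictions run/predictions.csv --output run/tracks.json
thermotrack evaluate --confusion 2056,332,330,1663
```

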