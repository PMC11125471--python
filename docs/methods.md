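# Methods

## Problem

Exudates and aneurysms (treated as a single class, EX-AN) appear in
retinal OCT B-scans as small hyperreflective blobs strictly between the
internal limiting membrane (ILM) and the retinal pigment epithelium
(RPE). They are hard to separate from other bright tissue: the RPE band
and a bright ILM surface share their intensity range, speckle noise
mimics small blobs, and cysts produce dark regions that confuse
shadow-based cues. The pipeline therefore combines four stages, each of
which is a testable library module:

1. **Pre-processing** — intensity normalization to [0, 1] by dividing by
   the image maximum, then contrast enhancement with the top-hat /
   bottom-hat identity `clip(img + tophat − bothat, 0, 1)` using a disk
   structuring element (default radius 5 px, on the scale of the target
   blobs). Top-hat lifts small bright structures off the layered
   background; bottom-hat deepens small dark ones (shadows, cysts).
2. **ROI segmentation** — a nested U-Net (U-Net++) predicts the band
   between ILM and RPE. Node `X[i,j]` receives the 2×-upsampled deeper
   node `X[i+1,j−1]` concatenated with all same-level predecessors;
   every convolution block is two 3×3 convolutions with batch norm and
   ReLU; the head is a 1×1 convolution + sigmoid. Training minimizes
   `L = L_BCE + L_Dice` with `L_BCE` averaged over pixels and
   `L_Dice = 1 − 2Σyp/(Σy+Σp)` per patch, probabilities clamped at
   1e−7 inside the logs. The optimizer is RMSprop (decay 0.9).
3. **Candidate generation** — inside the predicted ROI, pixels with
   enhanced intensity ≥ τ = 0.7 become candidates; 8-connected
   components of at least 2 px are candidate blobs.
4. **Feature extraction + classification** — nine features per blob
   (mean/min/max intensity, area, |x_b − x_f| to the fovea, vertical
   distances to the ILM and RPE curves, and two shadow-marker
   contrasts), classified by a bagged decision-tree ensemble evaluated
   with stratified five-fold cross-validation. A candidate is labeled
   positive for training when it overlaps the ground truth by strictly
   more than 30% of its own area.

## Neural-network backend

The segmenter runs on a small NumPy convolutional-network core written
for this package (`octexan.nn`): stride-1 same-padded convolution via
`tensordot` over `sliding_window_view` patches (the backward pass of
such a convolution is itself a convolution with the spatially flipped
kernel), batch normalization with running statistics, 2×2 max pooling,
2× nearest-neighbor upsampling, and RMSprop. Everything is float32 and
bit-deterministic given the seed, which makes the pipeline's
determinism guarantees testable without configuring a backend. Decoder
upsampling is nearest-neighbor + convolution rather than transposed
convolution; deep supervision is not used — the single output sits on
the last top-level node.

Defaults mirror the full-scale recipe (depth 4, base_filters 32,
224-px patches, 300 patches/image, 50 epochs, batch 4, learning rate
1e−4). The **scaled-down recipe** used by the tests and the acceptance
script — `roi.scaled_down_config()` — is base_filters 8, 64-px patches,
6 patches/image, 10 epochs, learning rate 1e−3 on 40 synthetic scenes
of 192×256 px. These sizes were chosen so the whole system trains on a
single CPU in a few minutes while still reaching ≥ 0.9 pixel F1 on
held-out scenes.

Full-image inference tiles the scan with half-patch stride, averages
overlapping probability maps, thresholds at 0.5 (configurable), and
keeps the largest connected component, since the retina is a single
band. Boundary curves are read per column as the first/last mask row;
columns with no ROI are NaN.

## Fovea detection on discrete curves

The fovea search fits a least-squares line `L` to the ILM curve, finds
the curve/line intersections, keeps the two nearest the middle of the
curve, and returns the in-between curve point with maximum |distance|
to `L` — the absolute value handles both the normal downward pit and
the upward "mountain" apex of displaced foveae. Two numerical choices
matter on pixel curves:

- An absolute-distance-below-ε criterion for "intersection" almost
  never fires on integer-valued curves; intersections are instead the
  sign changes of the residual, interpolated to sub-pixel positions —
  the ε → 0 limit of the same criterion.
- Boundary curves quantized to whole rows flatten the foveal extremum
  into a plateau (half-width ≈ σ√(2·δ/D) for a Gaussian dip of depth D
  and width σ at quantization step δ=1, i.e. ~4–5 px at realistic
  geometry). A centered 15-px moving average — wider than the plateau,
  much narrower than the ~2σ ≈ 30-px foveal region — restores a
  sub-pixel extremum. `smooth_window=1` disables it for exact tests.

If fewer than two crossings exist (straight ILM), the detector falls
back to the global maximum-|residual| column and flags the result.

## Shadow-marker geometry

For a blob with bounding-box width `w_b` and height `h_b`, the test
rectangle is `w_b × 3h_b`, placed `ceil(h_b/2)` px below the box's
bottom row; the flanking rectangles have identical size and are offset
horizontally by the rectangle width plus a 5-px gap. Features f8/f9 are
the absolute differences between the mean intensity of the middle
rectangle and each flank; rectangles are clipped to the image and means
taken over surviving pixels (both features are 0 if the middle
rectangle leaves the image entirely). Anchoring at the bbox bottom
rather than the centroid keeps the rectangle fully below the blob
footprint.

## Classifier

Trees are grown unpruned with Gini impurity (scikit-learn's
`DecisionTreeClassifier` as the base learner); the bagging loop is
implemented here so the vote semantics are exact: each of 30 trees fits
a bootstrap resample (fraction 1.0, with replacement), prediction is a
majority vote, and exact ties break toward the negative class, which is
precision-conservative. Stratified folds shuffle each class and deal
round-robin, so per-fold class counts deviate from balance by at most
one sample. The labeling and evaluation overlap rules are strictly
greater-than 30%: a blob at exactly 30% overlap is negative.

## Synthetic scenes

The generator emulates exactly the features the pipeline keys on: a
wing-shaped ILM (baseline minus parabolic flanks) with a Gaussian
foveal dip of configurable sign (−1 gives the pathological upward
apex), four stacked gray inner layers (0.2–0.5), a bright RPE band
(0.9) whose inner surface bounds the ROI, EX-AN disks (intensity
0.75–0.95, radius 1.5–3.5 px) placed mid-band with x drawn around the
fovea, each casting a shadow column (multiplicative attenuation 0.3
below the blob), distractor disks of the same brightness sitting on the
ILM/RPE bands or above cysts without shadows, dark elliptical cysts,
and multiplicative Gaussian speckle (σ = 0.03, clipped to [0, 1]).
Intensity bands are chosen so the τ = 0.7 threshold is meaningful:
blobs clear it, layers and the ILM edge do not.

What it does **not** model: physically realistic speckle statistics,
A-scan acquisition artifacts, curved/broken RPE pathology, intensity
inhomogeneity across the scan, or annotation noise in hand-drawn ground
truth. Passing tests therefore demonstrate that the implementation is
faithful and self-consistent and that the method's logic separates the
constructed confusers — not that the reported numbers transfer to
clinical OCT collections.

## Degenerate inputs and conventions

All modules share 0-based (row=y, col=x) coordinates with y growing
downward. All-zero images are rejected at normalization. An empty ROI
or an empty candidate set produces an empty-but-valid report, not an
error. Metric conventions: precision (or recall) is 0 when its
denominator is 0 and the other set is nonempty; all metrics are 1 when
prediction and ground truth are both empty. In blob-level evaluation
each predicted blob is scored independently against the ground-truth
mask, and a ground-truth component counts as found when at least one
true-positive prediction touches it.

## Known limitations

- The NumPy backend is CPU-bound; the full-scale recipe (224-px
  patches, 300 patches/image, 50 epochs) is supported but slow, and is
  not exercised by the tests.
- The candidate threshold is applied to the globally normalized,
  contrast-enhanced image; per-ROI renormalization is not implemented.
- The fovea detector assumes a single dominant extremum between the
  central crossings; multi-dip pathologies would need the flagged
  fallback path or an external fovea prior.
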