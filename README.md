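# octexan

Automatic segmentation of exudates and aneurysms (EX-AN) in retinal OCT
B-scans, for researchers building diabetic-retinopathy prescreening
tools and for anyone who needs a fully testable reference implementation
of a hyperreflective-foci pipeline.

Exudates and microaneurysms surface in OCT cross-sections as small
hyperreflective blobs confined to the band between the internal limiting
membrane (ILM) and the retinal pigment epithelium (RPE). The pipeline:

1. **Pre-process** — normalize intensities to [0, 1] and enhance
   contrast with disk top-hat/bottom-hat filtering:
   `clip(I + (I − I∘s) − (I•s − I), 0, 1)`.
2. **Scope the ROI** — a nested U-Net (U-Net++) segments the ILM–RPE
   band, trained on patches with geometric augmentation under the loss
   `L = L_BCE + L_Dice`, `L_Dice = 1 − 2Σyŷ/(Σy + Σŷ)`.
3. **Generate candidates** — adaptive thresholding keeps ROI pixels
   with enhanced intensity ≥ τ = 0.7; 8-connected components become
   candidate blobs.
4. **Extract nine features per blob** — mean/min/max intensity, area,
   distance to the fovea `|x_b − x_f|` (the fovea is the ILM point of
   maximum |distance| to the ILM's fitted line between the two central
   line crossings), vertical distances to the ILM and RPE curves, and
   two shadow-marker contrasts `|Ī_m − Ī_l|`, `|Ī_m − Ī_r|` measured in
   thin rectangles beneath the blob.
5. **Classify** — a bagged decision-tree ensemble (30 trees, majority
   vote) separates EX-AN from other hyperreflective tissue; candidates
   overlapping ground truth by strictly more than 30% of their area are
   the positive class during training.

Real clinical collections with hand-drawn EX-AN ground truth are not
redistributable, so the package ships a parametric B-scan simulator
(`octexan.synthetic`) that generates scenes with exact ground truth —
wing-shaped ILM with a foveal dip (or pathological upward apex), bright
RPE band, shadow-casting EX-AN blobs, shadow-free distractors on the
layer bands, cysts, and speckle — and every stage is tested against it.

## Worked example

```python
import numpy as np
from octexan import roi
from octexan.classify import EnsembleConfig
from octexan.metrics import blob_metrics
from octexan.pipeline import PipelineConfig, fit_system, predicted_exan_blobs, run_scene
from octexan.synthetic import default_config_sampler, generate_scene

rng = np.random.default_rng(0)
train = [generate_scene(default_config_sampler(i, rng)) for i in range(40)]
cfg = PipelineConfig(roi=roi.scaled_down_config(rng_seed=0),
                     ensemble=EnsembleConfig(rng_seed=1))
model, clf, history = fit_system(train, cfg)          # ~4 min on one CPU

test_scene = generate_scene(default_config_sampler(0, np.random.default_rng(99)))
report = run_scene(model, clf, test_scene.image, cfg)
match, metrics = blob_metrics(predicted_exan_blobs(report),
                              test_scene.exan_mask(), overlap_threshold=0.30)
print(f"candidates={report['n_candidates']} predicted={report['n_predicted']} "
      f"TP={match.tp} FP={match.fp} FN={match.fn} F1={metrics['f1']:.3f}")
```

```
candidates=16 predicted=6 TP=6 FP=0 FN=0 F1=1.000
```

Adaptive thresholding found sixteen bright candidates in the scene —
the true EX-AN blobs plus band reflections and shadow-free distractors.
The ensemble kept six, all of which match a true blob under the strict
30%-overlap rule, and missed none, so blob-level precision, recall, and
F1 are all 1.0 on this scene. (Across twenty held-out scenes the
acceptance script typically reports blob-level F1 in the mid-90s.)

The same flow is available from the shell:

```bash
octexan simulate --n-scenes 40 --out-dir data --seed 0
octexan train-roi --data-dir data --out roi.npz --scaled
octexan segment-roi --model roi.npz --in data/scene_0000.png --out mask.png
octexan candidates --image data/scene_0000.png --roi mask.png --out cands.json
octexan features --image data/scene_0000.png --roi mask.png \
    --candidates cands.json --gt-annotations data/scene_0000.json --out feats.csv
octexan train-clf --features feats.csv --out clf.pkl     # pool CSVs from many scenes
octexan pipeline --roi-model roi.npz --clf clf.pkl --in data/scene_0001.png --out-dir work
```

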