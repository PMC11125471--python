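"""End-to-end orchestration: raw B-scan -> predicted EX-AN blobs.

Stage order: normalize -> contrast enhancement -> U-Net++ ROI ->
boundary curves -> adaptive-threshold candidates -> fovea detection ->
nine-feature extraction -> bagged-tree classification -> report. The
enhanced image is used both for candidate thresholding and for the
intensity features, matching what the segmenter was trained on.
"""

from __future__ import annotations

import dataclasses
import json
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from octexan import annotations as ann
from octexan import roi as roi_mod
from octexan.blobs import Blob, ThresholdConfig, extract_candidates
from octexan.classify import BaggedTrees, EnsembleConfig, assign_labels, features_to_matrix, train_bagged_trees
from octexan.features import detect_fovea, extract_features
from octexan.preprocess import BScan, enhance_contrast, normalize
from octexan.roi import NoRoiError, UnetPPConfig, boundaries_from_mask, predict_roi
from octexan.synthetic import SyntheticScene


@dataclass(frozen=True)
class PipelineConfig:
    roi: UnetPPConfig = field(default_factory=roi_mod.scaled_down_config)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    se_radius: int = 5
    rng_seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one master seed deterministically to every stage."""
        return dataclasses.replace(
            self,
            rng_seed=seed,
            roi=dataclasses.replace(self.roi, rng_seed=seed),
            ensemble=dataclasses.replace(self.ensemble, rng_seed=seed + 1),
        )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file with per-stage
    sections (``roi``, ``threshold``, ``ensemble``, plus top-level
    ``se_radius``/``rng_seed``); omitted fields keep their defaults."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    roi_kwargs = dict(doc.get("roi", {}))
    if "augmentation" in roi_kwargs:
        roi_kwargs["augmentation"] = roi_mod.AugmentConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in roi_kwargs["augmentation"].items()
        })
    cfg = PipelineConfig(
        roi=UnetPPConfig(**roi_kwargs) if roi_kwargs else roi_mod.scaled_down_config(),
        threshold=ThresholdConfig(**doc.get("threshold", {})),
        ensemble=EnsembleConfig(**doc.get("ensemble", {})),
        se_radius=int(doc.get("se_radius", 5)),
        rng_seed=int(doc.get("rng_seed", 0)),
    )
    return cfg.with_seed(cfg.rng_seed) if "rng_seed" in doc else cfg


def preprocess_image(image: np.ndarray, se_radius: int = 5):
    """normalize + enhance; returns (normalized, enhanced)."""
    norm = normalize(np.asarray(image, dtype=float))
    enh = enhance_contrast(norm, se_radius=se_radius)
    return norm, enh


def run_scene(roi_model, clf: BaggedTrees | None, image: np.ndarray,
              cfg: PipelineConfig) -> dict:
    """Run the full pipeline on one image array; returns a report dict.

    An empty ROI or an empty candidate set yields an empty-but-valid
    report rather than an error.
    """
    t0 = time.perf_counter()
    report: dict = {"stages": {}}
    _norm, enh = preprocess_image(image, cfg.se_radius)
    prob, mask = predict_roi(roi_model, enh, cfg.roi)
    report["stages"]["roi_pixels"] = int(mask.sum())
    if not mask.any():
        report.update(blobs=[], labels=[], n_candidates=0, n_predicted=0,
                      status="no ROI detected", elapsed_s=time.perf_counter() - t0)
        return report
    layers = boundaries_from_mask(mask)
    cands = extract_candidates(enh, mask, cfg.threshold)
    report["stages"]["n_candidates"] = len(cands)
    fovea = detect_fovea(layers.ilm)
    report["fovea_xy"] = list(fovea.fovea_xy)
    report["fovea_fallback"] = fovea.fallback
    if not cands:
        report.update(blobs=[], labels=[], n_candidates=0, n_predicted=0,
                      status="no candidates", elapsed_s=time.perf_counter() - t0)
        return report
    feats = extract_features(cands, enh, fovea, layers)
    labels = clf.predict(features_to_matrix(feats)) if clf is not None else np.ones(len(cands), int)
    report.update(
        blobs=cands, features=feats, labels=labels, roi_mask=mask, prob_map=prob,
        layers=layers, n_candidates=len(cands), n_predicted=int(labels.sum()),
        status="ok", elapsed_s=time.perf_counter() - t0,
    )
    return report


def predicted_exan_blobs(report: dict) -> list[Blob]:
    return [b for b, lab in zip(report.get("blobs", []), report.get("labels", [])) if lab == 1]


def classifier_training_table(scenes: list[SyntheticScene], roi_model, cfg: PipelineConfig,
                              use_true_roi: bool = False):
    """Pooled labeled feature matrix from a list of synthetic scenes.

    Candidates come from the predicted ROI (or the ground-truth ROI when
    ``use_true_roi``); labels follow the strict 30%-overlap rule against
    each scene's EX-AN mask.
    """
    X_parts, y_parts = [], []
    for scene in scenes:
        _norm, enh = preprocess_image(scene.image, cfg.se_radius)
        if use_true_roi:
            mask = scene.roi_mask
        else:
            _prob, mask = predict_roi(roi_model, enh, cfg.roi)
            if not mask.any():
                continue
        layers = boundaries_from_mask(mask)
        cands = extract_candidates(enh, mask, cfg.threshold)
        if not cands:
            continue
        fovea = detect_fovea(layers.ilm)
        feats = extract_features(cands, enh, fovea, layers)
        labels = assign_labels(cands, scene.exan_mask(), cfg.ensemble.overlap_label_threshold)
        X_parts.append(features_to_matrix(feats))
        y_parts.append(labels)
    if not X_parts:
        raise NoRoiError("no usable candidates in any scene")
    return np.concatenate(X_parts), np.concatenate(y_parts)


def fit_system(train_scenes: list[SyntheticScene], cfg: PipelineConfig):
    """Train the ROI segmenter then the blob classifier on synthetic scenes."""
    dataset = []
    for scene in train_scenes:
        _norm, enh = preprocess_image(scene.image, cfg.se_radius)
        dataset.append((enh.pixels, scene.roi_mask.astype(float)))
    model = roi_mod.build_model(cfg.roi)
    model, history = roi_mod.train(model, dataset, cfg.roi)
    X, y = classifier_training_table(train_scenes, model, cfg)
    clf = train_bagged_trees(X, y, cfg.ensemble)
    return model, clf, history


def save_classifier(clf: BaggedTrees, path: str | Path) -> None:
    Path(path).write_bytes(pickle.dumps({"config": clf.cfg, "trees": clf.trees}))


def load_classifier(path: str | Path) -> BaggedTrees:
    blob = pickle.loads(Path(path).read_bytes())
    clf = BaggedTrees(blob["config"])
    clf.trees = blob["trees"]
    return clf


def run_pipeline(cfg: PipelineConfig, image_path: str | Path, roi_model_path: str | Path,
                 classifier_path: str | Path, work_dir: str | Path) -> dict:
    """File-level pipeline: reads an image, writes every intermediate.

    Outputs in ``work_dir``: enhanced image, probability map, ROI mask,
    candidate annotations, feature CSV, prediction annotations, and a
    JSON report with per-stage counts and timings.
    """
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    scan = BScan.from_file(image_path)
    roi_model, roi_cfg = roi_mod.load_model(roi_model_path)
    cfg = dataclasses.replace(cfg, roi=roi_cfg)
    clf = load_classifier(classifier_path)
    report = run_scene(roi_model, clf, scan.pixels, cfg)

    stem = scan.source_id
    _norm, enh = preprocess_image(scan.pixels, cfg.se_radius)
    ann.write_image(enh.pixels, work_dir / f"{stem}_enhanced.png")
    if "roi_mask" in report:
        ann.write_mask(report["roi_mask"], work_dir / f"{stem}_roi.png")
        ann.write_image(report["prob_map"], work_dir / f"{stem}_prob.png")
    blobs = report.get("blobs", [])
    labels = list(map(int, report.get("labels", [])))
    doc = {
        "scene_id": stem,
        "image_shape": list(scan.pixels.shape),
        "fovea_xy": report.get("fovea_xy"),
        "blobs": [
            {"label": "EXAN" if lab == 1 else "CANDIDATE",
             "rle": ann.rle_encode(b.pixel_set, scan.pixels.shape)}
            for b, lab in zip(blobs, labels)
        ],
    }
    ann.write_annotations(doc, work_dir / f"{stem}_predictions.json")
    if "features" in report:
        report["features"].to_csv(work_dir / f"{stem}_features.csv", index=False)
    summary = {
        "scene_id": stem, "status": report["status"],
        "n_candidates": report["n_candidates"], "n_predicted": report["n_predicted"],
        "fovea_xy": report.get("fovea_xy"), "elapsed_s": report["elapsed_s"],
        "stages": report["stages"],
    }
    (work_dir / f"{stem}_report.json").write_text(json.dumps(summary, indent=1) + "\n")
    return report
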