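"""End-to-end synthetic experiment: generate pseudo-slides, train the
patch CNN, assemble heatmaps, train the slide booster, train the U-Net,
and evaluate everything on held-out slides.

Slide-level evaluation is honest by construction: held-out slides
contribute patches to no training stage. Within the training slides the
booster's features default to 2-fold cross-fitting (each half's heatmaps
are predicted by the CNN trained on the other half), so the booster never
learns from over-confident self-predicted heatmaps; ``cross_fit=False``
reproduces the simpler shared-training-set scheme instead.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import evaluation, features, heatmap, patch_model, segmentation, slide_model, synthetic, tiling


@dataclass
class PipelineConfig:
    n_slides: int = 24
    slide_size: int = 4096
    patch_size: int = 1024
    n_tumor_regions: int = 2
    backbone: str = "small_cnn"
    epochs: int = 5
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    cross_fit: bool = True
    seg_epochs: int = 8
    seg_tiles_per_patch: int = 8
    seg_train_patches_per_slide: int = 2
    seg_eval_patches: int = 4
    out_dir: str | None = None


@dataclass
class SlideData:
    """Everything the pipeline keeps per slide once the full-resolution
    image has been dropped."""

    slide_id: str
    label: str
    records: list  # PatchRecords with images downscaled for the CNN
    background_flags: dict
    seg_patches: list  # (image_1024, mask_1024) pairs
    shape: tuple[int, int]


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _downscale_record(record, factor: int):
    img = record.image
    h = img.shape[0] // factor
    small = np.rint(img.reshape(h, factor, h, factor, 3)
                       .mean(axis=(1, 3))).astype(np.uint8)
    from dataclasses import replace
    return replace(record, image=small)


def _prepare_slide(seed: int, label: str, cfg: PipelineConfig,
                   index: int, keep_seg: int) -> SlideData:
    slide = synthetic.generate_slide(
        cfg.slide_size, cfg.slide_size,
        cfg.n_tumor_regions if label == synthetic.CANCEROUS else 0,
        seed=seed, slide_id=f"slide_{index:03d}")
    records = tiling.tile_slide(slide, cfg.patch_size, cfg.patch_size)
    flags = {(r.x, r.y): r.background_flag for r in records}
    seg_patches = []
    if label == synthetic.CANCEROUS and keep_seg:
        # prefer patches with a genuine tumor/normal boundary
        candidates = sorted(
            (r for r in records if r.tumor_fraction and 0.15 <= r.tumor_fraction <= 0.95),
            key=lambda r: abs(0.5 - r.tumor_fraction))
        for r in candidates[:keep_seg]:
            mask = synthetic.rasterize_mask(slide, (r.x, r.y, r.size, r.size))
            seg_patches.append((r.image.copy(), mask))
    factor = cfg.patch_size // 256 if cfg.patch_size % 256 == 0 else 1
    if factor > 1:
        records = [_downscale_record(r, factor) for r in records]
    return SlideData(slide_id=slide.slide_id, label=label, records=records,
                     background_flags=flags, seg_patches=seg_patches,
                     shape=slide.shape)


def _train_fold(slides: list[SlideData], cfg: PipelineConfig, seed: int):
    patches = [r for s in slides for r in s.records]
    by_class = {tiling.NORMAL: 0, tiling.CARCINOMA: 0}
    for p in patches:
        if p.label in by_class and not p.background_flag:
            by_class[p.label] += 1
    fractions = (0.7, 0.3, 0.0)
    targets = {}
    for split, frac_idx in (("training", 0), ("validation", 1)):
        cell = min(tiling.split_sizes(n, fractions)[frac_idx]
                   for n in by_class.values())
        if cell == 0:
            raise ValueError(f"no parents available for split {split}")
        targets[split] = cell * 6
    manifest = tiling.build_balanced_manifest(patches, targets, seed=seed,
                                              split_fractions=fractions)
    config = patch_model.TrainingConfig(backbone=cfg.backbone,
                                        learning_rate=cfg.learning_rate,
                                        epochs=cfg.epochs,
                                        batch_size=cfg.batch_size,
                                        seed=seed)
    clf = patch_model.build_classifier(config)
    patch_model.train_patch_classifier(clf, manifest, config)
    return clf


def _slide_heatmap(slide: SlideData, models: list, cfg: PipelineConfig):
    """Average the models' patch probabilities and assemble the grid."""
    probs = None
    for m in models:
        preds = patch_model.predict_patches(m, slide.records)
        arr = np.array([[p.p_normal, p.p_tumor] for p in preds])
        probs = arr if probs is None else probs + arr
    probs /= len(models)
    merged = [patch_model.PatchPrediction(slide_id=slide.slide_id,
                                          x=r.x, y=r.y,
                                          p_normal=float(p[0]),
                                          p_tumor=float(p[1]))
              for r, p in zip(slide.records, probs)]
    hm = heatmap.assemble_heatmap(
        merged, slide.shape, cfg.patch_size, cfg.patch_size,
        background_flags=slide.background_flags, slide_id=slide.slide_id)
    return hm


def _segmentation_stage(train_slides, heldout_slides, cfg: PipelineConfig,
                        seed: int):
    rng = np.random.default_rng(seed)
    tiles, masks = [], []
    for s in train_slides:
        for img, msk in s.seg_patches:
            t_img, coords = tiling.subsample_half_overlap(img)
            t_msk, _ = tiling.subsample_half_overlap(msk)
            # favour tiles straddling the lesion boundary: pure-background or
            # pure-tumor tiles teach the net almost nothing here
            means = np.array([m.mean() for m in t_msk])
            mixed = np.flatnonzero((means > 0.05) & (means < 0.95))
            other = np.flatnonzero((means <= 0.05) | (means >= 0.95))
            take = min(cfg.seg_tiles_per_patch, len(t_img))
            idx = list(rng.permutation(mixed)[:take])
            if len(idx) < take:
                idx += list(rng.permutation(other)[:take - len(idx)])
            tiles += [t_img[i] for i in idx]
            masks += [t_msk[i] for i in idx]
    seg_cfg = segmentation.SegmentationConfig.test_preset(
        epochs=cfg.seg_epochs, seed=seed)
    segmenter = segmentation.train_unet(np.array(tiles), np.array(masks), seg_cfg)

    # pooled dice over stitched held-out patches
    inter = p_sum = t_sum = 0.0
    n_eval = 0
    for s in heldout_slides:
        for img, msk in s.seg_patches:
            if n_eval >= cfg.seg_eval_patches:
                break
            t_img, coords = tiling.subsample_half_overlap(img)
            maps = segmenter.predict(np.array(t_img))
            stitched = segmentation.stitch(list(maps), coords, img.shape[:2])
            binary = (stitched >= 0.5).astype(float)
            inter += float((binary * msk).sum())
            p_sum += float(binary.sum())
            t_sum += float(msk.sum())
            n_eval += 1
    dice = 2.0 * inter / (p_sum + t_sum) if (p_sum + t_sum) else 1.0
    return segmenter, dice, n_eval


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic study; returns a flat dict of results."""
    if cfg.n_slides % 4:
        raise ValueError("n_slides must be divisible by 4 (stratified halves)")
    seeds = _derive_seeds(cfg.seed, cfg.n_slides + 8)
    slide_seeds, aux = seeds[:cfg.n_slides], seeds[cfg.n_slides:]

    labels = [synthetic.CANCEROUS if i % 2 else synthetic.NORMAL
              for i in range(cfg.n_slides)]
    n_train = cfg.n_slides // 2
    slides: list[SlideData] = []
    for i, (seed_i, label) in enumerate(zip(slide_seeds, labels)):
        training = i < n_train
        keep = cfg.seg_train_patches_per_slide if training else 1
        slides.append(_prepare_slide(seed_i, label, cfg, i, keep))
    train_slides, heldout_slides = slides[:n_train], slides[n_train:]

    # -- patch-level CNN(s) -------------------------------------------------
    if cfg.cross_fit:
        half = len(train_slides) // 2
        fold_a, fold_b = train_slides[:half], train_slides[half:]
        model_a = _train_fold(fold_a, cfg, aux[0])
        model_b = _train_fold(fold_b, cfg, aux[1])
        patch_val_accuracy = float(np.mean([model_a.best_val_accuracy,
                                            model_b.best_val_accuracy]))
        feature_models = {id(s): [model_b] for s in fold_a}
        feature_models.update({id(s): [model_a] for s in fold_b})
        heldout_models = [model_a, model_b]
    else:
        model = _train_fold(train_slides, cfg, aux[0])
        patch_val_accuracy = float(model.best_val_accuracy)
        feature_models = {id(s): [model] for s in train_slides}
        heldout_models = [model]

    # -- heatmaps and features ----------------------------------------------
    train_features, train_labels = [], []
    for s in train_slides:
        hm = _slide_heatmap(s, feature_models[id(s)], cfg)
        train_features.append(features.extract_features(hm))
        train_labels.append(s.label)
    heldout_features, heldout_labels, heldout_hms = [], [], []
    patch_true, patch_score = [], []
    for s in heldout_slides:
        hm = _slide_heatmap(s, heldout_models, cfg)
        heldout_hms.append(hm)
        heldout_features.append(features.extract_features(hm))
        heldout_labels.append(s.label)
        for r, p in zip(s.records, hm.grid.reshape(-1, 2)):
            if r.label in (tiling.NORMAL, tiling.CARCINOMA):
                patch_true.append(1 if r.label == tiling.CARCINOMA else 0)
                patch_score.append(p[1])

    # -- slide-level booster -------------------------------------------------
    booster = slide_model.train_slide_classifier(train_features, train_labels,
                                                 seed=aux[2])
    predictions = slide_model.predict_slide(booster, heldout_features)
    y_true = np.array([1 if lab == synthetic.CANCEROUS else 0
                       for lab in heldout_labels])
    y_pred = np.array([1 if p.predicted_label == "cancerous" else 0
                       for p in predictions])
    cm = evaluation.confusion(y_true, y_pred)
    slide_report = evaluation.metrics_from_confusion(cm)
    _, slide_auc = evaluation.roc_auc([p.p_cancerous for p in predictions], y_true)

    patch_true = np.array(patch_true)
    patch_score = np.array(patch_score)
    patch_heldout_accuracy = float(((patch_score >= 0.5).astype(int) == patch_true).mean())
    _, patch_auc = evaluation.roc_auc(np.clip(patch_score, 0, 1), patch_true)

    # -- segmentation --------------------------------------------------------
    segmenter, seg_dice, n_seg_eval = _segmentation_stage(
        train_slides, heldout_slides, cfg, aux[3])

    results = {
        "config": asdict(cfg),
        "patch_val_accuracy": patch_val_accuracy,
        "patch_heldout_accuracy": patch_heldout_accuracy,
        "patch_heldout_auc": float(patch_auc),
        "n_heldout_patches": int(len(patch_true)),
        "slide_accuracy": slide_report.accuracy,
        "slide_auc": float(slide_auc),
        "slide_confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "n_heldout_slides": len(heldout_slides),
        "segmentation_dice": float(seg_dice),
        "n_segmentation_eval_patches": n_seg_eval,
    }
    if cfg.out_dir:
        _write_outputs(Path(cfg.out_dir), results, train_features,
                       heldout_features, predictions, heldout_hms,
                       heldout_slides, booster)
    # keep handles for callers that want to inspect the trained models
    results["_models"] = {"patch": heldout_models, "booster": booster,
                          "segmenter": segmenter}
    return results


def _write_outputs(out, results, train_features, heldout_features,
                   predictions, heldout_hms, heldout_slides, booster):
    import json

    out.mkdir(parents=True, exist_ok=True)
    features.features_to_frame(train_features + heldout_features).to_csv(
        out / "heatmap_features.csv", index=False)
    slide_model.predictions_to_csv(
        predictions, out / "slide_predictions.csv",
        true_labels={s.slide_id: s.label for s in heldout_slides})
    slide_model.save_model(booster, out / "slide_model")
    for hm in heldout_hms[:2]:
        heatmap.save_heatmap(hm, out / f"heatmap_{hm.slide_id}")
        heatmap.save_overlay_png(heatmap.colorize(hm, block=32),
                                 out / f"heatmap_{hm.slide_id}.png")
    json.dump({k: v for k, v in results.items() if not k.startswith("_")},
              (out / "results.json").open("w"), indent=2)
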