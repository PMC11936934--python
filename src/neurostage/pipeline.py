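"""End-to-end orchestration: enhance -> backbone + attention -> ELM -> report.

The training flow follows the framework's block diagram: build (or scan) the
dataset, apply the class-balance plan (cap + augmentation targets), split
stratified, optionally HRLG-enhance the images, fine-tune the attention
fusion scalars and softmax head on the training split, fit the ELM on pooled
training features, and evaluate on the held-out split.  Every run writes a
resolved-config snapshot sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import elm
from .backbone import assemble_model, build_feature_extractor, finetune_head
from .config import RunConfig, save_config
from .data import (
    DatasetManifest,
    derive_seed,
    augment_to_target,
    generate_phantom_dataset,
    load_image,
    save_image,
    scan_dataset,
    select_utilized,
    stratified_split,
)
from .enhancement import enhance_image
from .evaluation import EvalReport, evaluate_predictions, write_report
from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = ["run_enhance", "run_train_eval", "render_attention_overlays"]


def run_enhance(input_dir, output_dir, dehaze, contrast) -> dict:
    """Mirror ``input_dir``'s tree into ``output_dir`` with every readable
    image HRLG-enhanced.  Returns ``{"enhanced": n, "skipped": m}``."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    if not input_dir.is_dir():
        raise DataError(f"input directory {input_dir} does not exist")
    paths = sorted(
        p for p in input_dir.rglob("*")
        if p.is_file() and p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise DataError(f"no images found under {input_dir}")
    enhanced = skipped = 0
    for path in paths:
        rel = path.relative_to(input_dir)
        target = output_dir / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        try:
            image = load_image(path)
        except Exception:  # unreadable/corrupt file: account for it and move on
            logger.warning("skipping unreadable image %s", path)
            skipped += 1
            continue
        save_image(enhance_image(image, dehaze, contrast), target)
        logger.info("enhanced %s", rel)
        enhanced += 1
    logger.info("enhancement done: %d enhanced, %d skipped", enhanced, skipped)
    return {"enhanced": enhanced, "skipped": skipped}


def _materialise_dataset(config: RunConfig, work_dir: Path) -> DatasetManifest:
    if config.data_root is not None:
        return scan_dataset(config.data_root)
    phantom = replace(config.phantom, seed=derive_seed(config.seed, "phantom"))
    return generate_phantom_dataset(phantom, work_dir / "phantoms")


def _apply_balance(config: RunConfig, manifest: DatasetManifest, work_dir: Path) -> DatasetManifest:
    plan = replace(config.balance, seed=derive_seed(config.seed, "balance"))
    manifest = select_utilized(manifest, plan)
    if not plan.augment_targets:
        return manifest
    files = dict(manifest.files)
    aug_cfg = replace(config.augment, seed=derive_seed(config.seed, "augment"))
    for label, target in plan.augment_targets.items():
        if label not in files:
            raise DataError(f"augment target for unknown class {label!r}")
        if target > len(files[label]):
            files[label] = augment_to_target(
                files[label], target, aug_cfg, work_dir / "augmented" / str(label)
            )
    return DatasetManifest(classes=list(manifest.classes), files=files)


def _enhance_manifest(config: RunConfig, manifest: DatasetManifest, work_dir: Path) -> DatasetManifest:
    out: dict = {}
    for label in manifest.classes:
        class_dir = work_dir / "enhanced" / str(label)
        class_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for p in manifest.files[label]:
            target = class_dir / Path(p).name
            save_image(enhance_image(load_image(p), config.dehaze, config.contrast), target)
            paths.append(target)
        out[label] = paths
    return DatasetManifest(classes=list(manifest.classes), files=out)


def run_train_eval(config: RunConfig) -> tuple[EvalReport, Path]:
    """Execute the full training/evaluation flow; returns the test-set report
    and the artifact directory (checkpoint, report JSON, config snapshot)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(config, out_dir / "resolved_config.yaml")

    manifest = _materialise_dataset(config, out_dir)
    manifest = _apply_balance(config, manifest, out_dir)
    train_manifest, test_manifest = stratified_split(
        manifest, config.split_fractions, derive_seed(config.seed, "split")
    )
    if config.enhance:
        train_manifest = _enhance_manifest(config, train_manifest, out_dir / "train")
        test_manifest = _enhance_manifest(config, test_manifest, out_dir / "test")
    train_manifest.to_csv(out_dir / "train_manifest.csv")
    test_manifest.to_csv(out_dir / "test_manifest.csv")

    extractor = build_feature_extractor(
        config.backbone, seed=derive_seed(config.seed, "backbone")
    )
    model = assemble_model(
        extractor,
        config.heads,
        n_classes=len(manifest.classes),
        seed=derive_seed(config.seed, "gsa"),
        use_gsa=config.use_gsa,
    )
    train_cfg = replace(config.train, seed=derive_seed(config.seed, "finetune"))
    history = finetune_head(model, train_manifest, train_cfg)

    def _features_and_labels(m: DatasetManifest):
        images, labels = [], []
        for label in m.classes:
            for p in m.files[label]:
                images.append(load_image(p))
                labels.append(label)
        return model.features(images), np.asarray(labels)

    X_train, y_train = _features_and_labels(train_manifest)
    X_test, y_test = _features_and_labels(test_manifest)

    n_hidden = min(config.n_hidden, len(y_train) - 1)
    classifier = elm.fit_elm(
        X_train, y_train, n_hidden=n_hidden,
        seed=derive_seed(config.seed, "elm"), activation=config.elm_activation,
    )
    y_pred = elm.predict_elm(classifier, X_test)
    scores = elm.decision_matrix(classifier, X_test)
    report = evaluate_predictions(
        y_test, y_pred, scores=scores, labels=classifier.class_labels
    )

    classifier.save(out_dir / "elm_model.json")
    write_report(report, out_dir / "report.json")
    (out_dir / "train_history.json").write_text(json.dumps(history))
    logger.info(
        "run complete: accuracy %.4f, macro-F1 %.4f",
        report.accuracy, report.macro_avg["f1"],
    )
    return report, out_dir


def render_attention_overlays(model, image_path, out_dir) -> list:
    """Export per-head spatial-attention overlays: the softmax weights are
    reshaped to the feature-map grid, upsampled to the image size and blended
    into the red channel over the grayscale slice."""
    from skimage import transform as sktransform

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image = load_image(image_path)
    gray = image if image.ndim == 2 else image.mean(axis=2)
    fmap = model.feature_map(image)
    fh, fw = fmap.shape[:2]
    diags = model.attention_diagnostics(image)
    written = []
    for i, weights in enumerate(diags.spatial_weights):
        heat = np.asarray(weights).reshape(fh, fw)
        heat = heat / heat.max() if heat.max() > 0 else heat
        heat = sktransform.resize(heat, gray.shape, order=1, mode="reflect")
        overlay = np.stack([
            np.clip(0.6 * gray + 0.4 * heat, 0, 1),
            0.6 * gray,
            0.6 * gray,
        ], axis=2)
        path = out_dir / f"{Path(image_path).stem}_head{i}.png"
        save_image(overlay, path)
        gates_path = out_dir / f"{Path(image_path).stem}_head{i}_gates.json"
        gates_path.write_text(json.dumps({
            "spatial_weights": np.asarray(weights).reshape(fh, fw).tolist(),
            "channel_gates": np.asarray(diags.channel_gates[i]).tolist(),
        }))
        written.append(path)
    return written
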