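"""End-to-end experiment orchestration at desk scale.

Each scenario reproduces one of the study designs on synthetic scenes:

* ``run_decoupled`` — MSER localization + tile CNN, scored with the
  localization/classification FN split;
* ``run_detector_train_eval`` — auto-annotated boxes feeding the anchor
  detector, scored with box matching;
* ``run_size_feature_study`` — is cell size the dominant classifier cue?
  (test-time enlargement of the small class, then size-equalized retraining
  at 36×36 and at 15×15);
* ``run_robustness_study`` — detector metrics on photometrically transformed
  test sets plus a re-generated "new experiment" analogue;
* ``run_negative_retrain_study`` — contrast-polarity collapse and recovery
  after retraining on originals + negatives.

Default sizes are chosen so every scenario completes in minutes on one CPU;
everything is configurable and seeded, and train/test splits are disjoint by
image with a split seed separate from scene generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import transforms
from .annotate import AnnotationConfig, BoundingBox, annotate_image
from .classifier import (
    ClassifierConfig,
    classify_tiles,
    label_tiles,
    resize_tiles,
    train_classifier,
)
from .detector import DetectorConfig, detect, train_detector
from .evaluation import EvalReport, match_detections, decoupled_confusion
from .mser import Tile, crop_tiles, derive_mser_params, localize_cells
from .scenes import MCF7, WBC, SceneSpec, generate_scene

__all__ = [
    "ExperimentConfig",
    "default_decoupled_spec",
    "default_detector_spec",
    "run_decoupled",
    "run_detector_train_eval",
    "run_size_feature_study",
    "run_robustness_study",
    "run_negative_retrain_study",
]

TILE = 36


def default_decoupled_spec() -> SceneSpec:
    """Scenes for the decoupled study: every cell tile-croppable (interior)."""
    return SceneSpec(n_mcf7=6, n_wbc=18, n_debris=4, interior_margin_px=TILE / 2)


def default_detector_spec() -> SceneSpec:
    """Smaller frames for the detector studies (dense anchor scoring is the
    cost driver)."""
    return SceneSpec(
        image_size_px=(256, 256),
        n_mcf7=4,
        n_wbc=7,
        n_debris=2,
        interior_margin_px=TILE / 2,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    scenario: str = "decoupled_train_eval"
    scene: SceneSpec = field(default_factory=default_decoupled_spec)
    n_images: int = 20
    train_fraction: float = 0.6
    classifier: ClassifierConfig = field(default_factory=lambda: ClassifierConfig(epochs=20))
    detector: DetectorConfig = field(default_factory=lambda: DetectorConfig())
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def _scene_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def make_scenes(spec: SceneSpec, n: int, seed: int):
    return [generate_scene(spec.with_(seed=int(s))) for s in _scene_seeds(seed, n)]


def split_indices(n: int, train_fraction: float, seed: int):
    order = np.random.default_rng(seed + 1_000_003).permutation(n)
    n_train = int(round(n * train_fraction))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def mser_params_for(spec: SceneSpec, margin: float = 0.05):
    """Size band spanning both cell classes (±3 sd), in pixels."""
    lo_um = spec.wbc_diameter_um[0] - 3 * spec.wbc_diameter_um[1]
    hi_um = spec.mcf7_diameter_um[0] + 3 * spec.mcf7_diameter_um[1]
    return derive_mser_params([lo_um, hi_um], margin=margin, pixel_scale=spec.pixel_scale)


def annotation_config_for(spec: SceneSpec) -> AnnotationConfig:
    d_lo = (spec.mcf7_diameter_um[0] - 3 * spec.mcf7_diameter_um[1]) / spec.pixel_scale
    d_hi = (spec.mcf7_diameter_um[0] + 3 * spec.mcf7_diameter_um[1]) / spec.pixel_scale
    return AnnotationConfig(radius_range_px=(0.4 * d_lo, 0.6 * d_hi), box_size=TILE)


def truth_boxes(truth, image_id: str = "", box_size: int = TILE, image_shape=None):
    """Fixed-size boxes centered on interior target-class truth records."""
    half = box_size // 2
    boxes = []
    for t in truth:
        if t.cell_class != MCF7 or t.touches_boundary:
            continue
        x0 = int(round(t.center[0])) - half
        y0 = int(round(t.center[1])) - half
        if image_shape is not None:
            h, w = image_shape[:2]
            if x0 < 0 or y0 < 0 or x0 + box_size > w or y0 + box_size > h:
                continue
        boxes.append(BoundingBox(x0, y0, box_size, box_size, image_id))
    return boxes


# ---------------------------------------------------------------------------
# decoupled approach
# ---------------------------------------------------------------------------


def _localize_and_crop(bf, params, tile_size=TILE):
    """Centroids plus aligned tiles (None where the tile crossed the border)."""
    centroids = localize_cells(bf, params)
    tiles: list[Tile | None] = []
    for c in centroids:
        got, _ = crop_tiles(bf, [c], tile_size)
        tiles.append(got[0] if got else None)
    return centroids, tiles


def run_decoupled(config: ExperimentConfig = ExperimentConfig()):
    """Train and evaluate the two-module pipeline; returns (EvalReport, extras)."""
    scenes = make_scenes(config.scene, config.n_images, config.seed)
    train_idx, test_idx = split_indices(config.n_images, config.train_fraction, config.seed)
    params = mser_params_for(config.scene)

    train_tiles = []
    for i in train_idx:
        bf, fitc, dapi, _ = scenes[i]
        _, tiles = _localize_and_crop(bf, params)
        train_tiles.extend(label_tiles([t for t in tiles if t is not None], fitc, dapi))
    model, train_report = train_classifier(train_tiles, config.classifier)

    total = EvalReport(fn_localization=0, fn_classification=0)
    per_image = []
    for i in test_idx:
        bf, fitc, dapi, truth = scenes[i]
        centroids, tiles = _localize_and_crop(bf, params)
        preds: list[str | None] = [None] * len(centroids)
        live = [(j, t) for j, t in enumerate(tiles) if t is not None]
        if live:
            results = classify_tiles(model, [t for _, t in live])
            for (j, _), (lbl, _) in zip(live, results):
                preds[j] = lbl
        rep = decoupled_confusion(centroids, preds, truth, match_radius_px=TILE / 2)
        per_image.append(rep)
        total = total + rep
    total.refresh()
    extras = {
        "model": model,
        "train_report": train_report,
        "per_image": per_image,
        "n_train_tiles": len(train_tiles),
    }
    return total, extras


# ---------------------------------------------------------------------------
# detector
# ---------------------------------------------------------------------------


def run_detector_train_eval(config: ExperimentConfig | None = None):
    """Auto-annotate, train the anchor detector, evaluate on held-out scenes.

    Returns (EvalReport, extras) where extras carries the model, the train
    report, and the held-out scenes for reuse by the robustness studies.
    """
    if config is None:
        config = ExperimentConfig(scenario="detector_train_eval", scene=default_detector_spec())
    scenes = make_scenes(config.scene, config.n_images, config.seed)
    train_idx, test_idx = split_indices(config.n_images, config.train_fraction, config.seed)
    ann_cfg = annotation_config_for(config.scene)

    train_imgs, train_anns = [], []
    for i in train_idx:
        bf, fitc, dapi, _ = scenes[i]
        train_imgs.append(bf)
        train_anns.append(annotate_image(bf, fitc, dapi, ann_cfg, image_id=f"img_{i}"))
    model, train_report = train_detector(train_imgs, train_anns, config.detector)

    test_imgs = [scenes[i][0] for i in test_idx]
    test_truth = [
        truth_boxes(scenes[i][3], image_shape=scenes[i][0].shape) for i in test_idx
    ]
    report = evaluate_detector(model, test_imgs, test_truth, config.detector)
    extras = {
        "model": model,
        "train_report": train_report,
        "test_images": test_imgs,
        "test_truth": test_truth,
        "train_images": train_imgs,
        "train_annotations": train_anns,
    }
    return report, extras


def evaluate_detector(model, images, truths, det_cfg: DetectorConfig) -> EvalReport:
    total = EvalReport(fp_redundant=0, fp_nonmcf7=0)
    for img, truth in zip(images, truths):
        dets = detect(model, img, det_cfg)
        total = total + match_detections(dets, truth)
    return total.refresh()


# ---------------------------------------------------------------------------
# size-feature study
# ---------------------------------------------------------------------------


def tiles_from_truth(scenes, tile_size=TILE, classes=(MCF7, WBC)):
    """Crop one labeled tile per interior truth cell (classifier study input)."""
    out = {c: [] for c in classes}
    for si, (bf, _, _, truth) in enumerate(scenes):
        for t in truth:
            if t.cell_class not in classes:
                continue
            got, _ = crop_tiles(
                bf, [t.center], tile_size, source_image=f"img_{si}"
            )
            if got:
                out[t.cell_class].append(replace(got[0], label=t.cell_class))
    return out


def _acc(model, tiles, positive_class=MCF7):
    preds = classify_tiles(model, tiles)
    correct = sum(
        1
        for t, (lbl, _) in zip(tiles, preds)
        if (lbl == "MCF7") == (t.label == positive_class)
    )
    return correct / len(tiles)


def _as_two_class(tiles):
    return [replace(t, label="MCF7" if t.label == MCF7 else "NON_MCF7") for t in tiles]


def run_size_feature_study(config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Probe whether the classifier leans on the 2× size difference.

    Rows: baseline accuracy; test-time 2× enlargement of the small class
    (accuracy drop); size-equalized retraining at 36×36 (recovery);
    shrink-the-large-class retraining at 15×15 (recovery, slightly below the
    36×36 retrain).  Accuracies are on held-out tiles.
    """
    if config is None:
        config = ExperimentConfig(
            scenario="size_feature_study",
            scene=SceneSpec(n_mcf7=8, n_wbc=12, n_debris=0, interior_margin_px=TILE / 2),
            n_images=20,
        )
    scenes = make_scenes(config.scene, config.n_images, config.seed)
    train_idx, test_idx = split_indices(config.n_images, config.train_fraction, config.seed)
    tr = tiles_from_truth([scenes[i] for i in train_idx])
    te = tiles_from_truth([scenes[i] for i in test_idx])
    tr_m, tr_w = _as_two_class(tr[MCF7]), _as_two_class(tr[WBC])
    te_m, te_w = _as_two_class(te[MCF7]), _as_two_class(te[WBC])

    base_cfg = config.classifier
    model, _ = train_classifier(tr_m + tr_w, base_cfg)
    rows = []
    rows.append(("baseline_36", _acc(model, te_m + te_w)))

    te_w_big = resize_tiles(te_w, 2.0, TILE)
    rows.append(("wbc_enlarged_test_time", _acc(model, te_m + te_w_big)))

    tr_w_big = resize_tiles(tr_w, 2.0, TILE)
    model_eq, _ = train_classifier(tr_m + tr_w_big, base_cfg)
    rows.append(("retrain_wbc_enlarged_36", _acc(model_eq, te_m + te_w_big)))

    cfg15 = replace(base_cfg, input_side=15, n_conv_layers=2, channels=(16, 32))
    tr15 = resize_tiles(tr_m, 0.5, 15) + resize_tiles(tr_w, 1.0, 15)
    te15 = resize_tiles(te_m, 0.5, 15) + resize_tiles(te_w, 1.0, 15)
    model15, _ = train_classifier(tr15, cfg15)
    rows.append(("retrain_mcf7_halved_15", _acc(model15, te15)))

    return pd.DataFrame(rows, columns=["row", "accuracy"])


# ---------------------------------------------------------------------------
# robustness studies
# ---------------------------------------------------------------------------


def _transform_set(images, op, seed):
    rng = np.random.default_rng(seed)
    out = []
    for img in images:
        if op == "shift":
            out.append(transforms.shift_intensity(img, rng)[0])
        elif op == "stretch":
            out.append(transforms.stretch_contrast(img, rng)[0])
        elif op == "negate":
            out.append(transforms.negate(img))
        else:
            raise ValueError(op)
    return out


def new_experiment_spec(spec: SceneSpec) -> SceneSpec:
    """Analogue of re-acquiring images with altered focus/exposure."""
    return spec.with_(
        background_level=spec.background_level - 20,
        cell_contrast=spec.cell_contrast * 0.85,
        wbc_contrast=spec.wbc_contrast * 0.85,
        blur_sigma=spec.blur_sigma + 0.5,
        noise_sd=spec.noise_sd + 1.0,
    )


def run_robustness_study(config: ExperimentConfig | None = None, base=None):
    """Detector metrics across photometric variants of the test set.

    Returns (table, extras); one row per dataset variant with sensitivity,
    precision and F1 (percent).  ``base`` may carry a precomputed
    ``(report, extras)`` pair from ``run_detector_train_eval``.
    """
    if config is None:
        config = ExperimentConfig(scenario="robustness_study", scene=default_detector_spec())
    base_report, extras = base if base is not None else run_detector_train_eval(config)
    model = extras["model"]
    imgs, truths = extras["test_images"], extras["test_truth"]
    n_test = len(imgs)
    new_scenes = make_scenes(
        new_experiment_spec(config.scene), n_test, config.seed + 77
    )
    variants = [
        ("original", imgs, truths),
        ("intensity_shift", _transform_set(imgs, "shift", config.seed + 11), truths),
        ("contrast_stretch", _transform_set(imgs, "stretch", config.seed + 12), truths),
        ("negative", _transform_set(imgs, "negate", 0), truths),
        (
            "new_experiment",
            [s[0] for s in new_scenes],
            [truth_boxes(s[3], image_shape=s[0].shape) for s in new_scenes],
        ),
    ]
    rows = []
    for name, images, tr in variants:
        rep = evaluate_detector(model, images, tr, config.detector)
        rows.append(
            {
                "dataset": name,
                "tp": rep.tp,
                "fn": rep.fn,
                "fp": rep.fp,
                "sensitivity": rep.sensitivity,
                "precision": rep.precision,
                "f1": rep.f1,
            }
        )
    return pd.DataFrame(rows), extras


def run_negative_retrain_study(config: ExperimentConfig | None = None, base=None):
    """Contrast-polarity collapse and recovery.

    Rows: original-test F1; negated-test F1 under the original model; and
    negated-test F1 after retraining on originals + their negatives.  A
    previously computed ``(report, extras)`` pair from
    ``run_detector_train_eval`` with the same config can be passed as
    ``base`` to reuse the trained model and scenes.
    """
    if config is None:
        config = ExperimentConfig(
            scenario="negative_retrain_study", scene=default_detector_spec()
        )
    base_report, extras = base if base is not None else run_detector_train_eval(config)
    model = extras["model"]
    imgs, truths = extras["test_images"], extras["test_truth"]
    neg_imgs = _transform_set(imgs, "negate", 0)
    neg_report = evaluate_detector(model, neg_imgs, truths, config.detector)

    aug_imgs = extras["train_images"] + [
        transforms.negate(i) for i in extras["train_images"]
    ]
    aug_anns = extras["train_annotations"] * 2
    model2, _ = train_detector(aug_imgs, aug_anns, config.detector, diagnostics=False)
    rec_report = evaluate_detector(model2, neg_imgs, truths, config.detector)
    table = pd.DataFrame(
        [
            {"row": "original_test", "f1": base_report.f1},
            {"row": "negative_test", "f1": neg_report.f1},
            {"row": "negative_test_after_retrain", "f1": rec_report.f1},
        ]
    )
    return table, {"model": model, "retrained_model": model2, **extras}
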