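"""Three-stage pseudo-labeling training curriculum.

Stage 1 trains the *First CE* net on auto-labeled neutral-background
images (SET1).  Stage 2 uses that net to pseudo-label the harsh-light
SET2 images (with morphological cleanup), then retrains on SET1 + SET2 to
obtain the *Final CE* net.  Stage 3 extends the CE training set in one of
two directions: adding true-negative frames carrying all-zero masks (the
*TNA* net, which suppresses false positives at the cost of recall) or
adding field frames pseudo-labeled by the CE net without any
morphological finishing (the *FIA* net, which balances both error types).
A *manual* arm trains on externally supplied field labels for comparison.

Every assembled training set is expanded 20x by the augmentation module
before training, and each later stage fine-tunes from the previous CE
line's weights.  Field imagery never enters stages 1-2, and training and
test sample ids are checked for disjointness.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .augment import augment_dataset
from .autolabel import AutolabelConfig, autolabel, discard_stems, fill_holes, \
    remove_small_components
from .metrics import MetricsReport, evaluate_test_set
from .samples import LabeledSample, stable_seed
from .segnet import (
    NetworkConfig,
    TrainHyperparams,
    TrainedModel,
    build_model,
    manifest_hash,
    predict_mask,
    train,
)
from .synthgen import generate_dataset, scene_specs

STAGES = ("stage1_first_ce", "stage2_ce", "stage3_tna", "stage3_fia", "manual")

_STAGE_TAG = {
    "stage1_first_ce": "first_ce",
    "stage2_ce": "ce",
    "stage3_tna": "tna",
    "stage3_fia": "fia",
    "manual": "manual",
}


@dataclass
class StageConfig:
    """Recipe for a single training stage.

    ``sources`` maps role names to data: ``set1_labeled`` /
    ``set2_labeled`` / ``manual_labeled`` hold :class:`LabeledSample`
    lists; ``pseudo_images`` holds raw RGB images to be labeled by
    ``pseudo_label_model``; ``negative_images`` holds raw images that
    receive all-zero masks when ``negatives_as_zero_masks`` is set.
    """

    stage: str
    sources: dict = dc_field(default_factory=dict)
    pseudo_label_model: TrainedModel | None = None
    cleanup_pseudo_labels: bool = False
    negatives_as_zero_masks: bool = False
    augmentation_seed: int = 0
    autolabel_config: AutolabelConfig = dc_field(default_factory=AutolabelConfig)

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        needs_pseudo = self.stage in ("stage2_ce", "stage3_fia")
        if needs_pseudo and self.pseudo_label_model is None:
            raise ValueError(f"{self.stage} requires a pseudo_label_model")
        if self.stage == "stage2_ce" and not self.cleanup_pseudo_labels:
            raise ValueError("stage2_ce pseudo-labels must be cleaned up")
        if self.stage == "stage3_fia" and self.cleanup_pseudo_labels:
            raise ValueError(
                "stage3_fia uses raw pseudo-labels (no morphological finishing)"
            )
        if self.stage == "stage1_first_ce":
            extra = set(self.sources) - {"set1_labeled"}
            if extra or self.pseudo_label_model is not None:
                raise ValueError("stage1 trains on set1 auto-labels only")


def cleanup_mask(mask: np.ndarray, config: AutolabelConfig) -> np.ndarray:
    """The morphological finishing chain applied to pseudo-labels."""
    mask = remove_small_components(
        mask, config.scaled_min_area(mask.shape), config.connectivity
    )
    mask = discard_stems(mask, config)
    return fill_holes(mask, config.connectivity)


def pseudo_label(
    model: TrainedModel,
    images: Sequence[np.ndarray],
    cleanup: bool,
    config: AutolabelConfig | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[LabeledSample]:
    """Label images with a trained net, optionally with cleanup."""
    if len(images) == 0:
        raise ValueError("image list must be non-empty")
    config = config or AutolabelConfig()
    out = []
    for i, img in enumerate(images):
        mask = predict_mask(model, img)
        if cleanup:
            mask = cleanup_mask(mask, config)
        sid = sample_ids[i] if sample_ids else f"pseudo-{i:05d}"
        out.append(
            LabeledSample(image=img, mask=mask, provenance="pseudo", sample_id=sid)
        )
    return out


def make_negative_samples(
    images: Sequence[np.ndarray], sample_ids: Sequence[str] | None = None
) -> list[LabeledSample]:
    """True-negative samples: the mask is obtained by zeroing every pixel."""
    out = []
    for i, img in enumerate(images):
        sid = sample_ids[i] if sample_ids else f"negative-{i:05d}"
        out.append(
            LabeledSample(
                image=img,
                mask=np.zeros(img.shape[:2], dtype=np.uint8),
                provenance="negative",
                sample_id=sid,
            )
        )
    return out


def run_stage(
    cfg: StageConfig,
    hp: TrainHyperparams,
    network: NetworkConfig | None = None,
    init_model: TrainedModel | None = None,
) -> tuple[TrainedModel, dict]:
    """Assemble the stage's training set, augment 20x, train, tag.

    Returns the trained model and a log entry with the pre- and
    post-augmentation counts.
    """
    cfg.validate()
    training: list[LabeledSample] = []
    for key in ("set1_labeled", "set2_labeled", "manual_labeled"):
        training.extend(cfg.sources.get(key, []))
    pseudo_images = cfg.sources.get("pseudo_images", [])
    if pseudo_images:
        if cfg.pseudo_label_model is None:
            raise ValueError("pseudo_images supplied without a pseudo_label_model")
        training.extend(
            pseudo_label(
                cfg.pseudo_label_model,
                pseudo_images,
                cleanup=cfg.cleanup_pseudo_labels,
                config=cfg.autolabel_config,
                sample_ids=cfg.sources.get("pseudo_ids"),
            )
        )
    if cfg.negatives_as_zero_masks:
        negatives = cfg.sources.get("negative_images", [])
        training.extend(
            make_negative_samples(negatives, cfg.sources.get("negative_ids"))
        )
    if not training:
        raise ValueError(f"{cfg.stage}: assembled training set is empty")

    pre_n = len(training)
    augmented = augment_dataset(training, seed=cfg.augmentation_seed)
    if init_model is not None:
        model = init_model.copy()
    else:
        if network is None:
            raise ValueError("need either init_model or a network config")
        model = build_model(network)
    tag = _STAGE_TAG[cfg.stage]
    train(model, augmented, hp, stage_tag=tag)
    log = {
        "stage": cfg.stage,
        "tag": tag,
        "pre_augmentation_count": pre_n,
        "post_augmentation_count": len(augmented),
        "final_loss": model.history[-1]["loss"] if model.history else None,
    }
    return model, log


@dataclass
class CascadeConfig:
    """Desk-scale end-to-end run over synthetic scenes.

    Counts are originals per set; every stage's training set is expanded
    20x by augmentation before training.
    """

    n_set1: int = 16
    n_set2: int = 12
    n_negative: int = 12
    n_field_train: int = 20
    n_field_test: int = 40
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0
    backbone: str = "tiny"
    aspp_rates: tuple[int, ...] = (1, 2, 4)
    hyperparams: TrainHyperparams | None = None
    autolabel_config: AutolabelConfig = dc_field(default_factory=AutolabelConfig)
    include_manual: bool = False


@dataclass
class CascadeResult:
    models: dict
    reports: dict
    logs: list
    test_set: list


def run_cascade(config: CascadeConfig) -> CascadeResult:
    """Execute all stages in dependency order and score every model on a
    shared held-out field-style test set."""
    hp = config.hyperparams or TrainHyperparams(
        epochs=6, batch_size=8, learning_rate=1e-3, seed=config.seed
    )
    net_cfg = NetworkConfig(
        backbone=config.backbone,
        aspp_rates=config.aspp_rates,
        input_size=config.image_size,
        seed=stable_seed(config.seed, "init"),
    )
    al_cfg = config.autolabel_config

    # -- data -------------------------------------------------------------
    set1 = generate_dataset(
        scene_specs("set1", config.n_set1, stable_seed(config.seed, "set1"),
                    config.image_size)
    )
    set2 = generate_dataset(
        scene_specs("set2", config.n_set2, stable_seed(config.seed, "set2"),
                    config.image_size)
    )
    negatives = generate_dataset(
        scene_specs("negative", config.n_negative,
                    stable_seed(config.seed, "negative"), config.image_size)
    )
    # FIA trains on the first frames of field acquisition: close range,
    # better lit, few dry leaves, so the CE pseudo-labels are reliable
    field_train = generate_dataset(
        scene_specs("field-close", config.n_field_train,
                    stable_seed(config.seed, "field-train"), config.image_size)
    )
    test_set = generate_dataset(
        scene_specs("field", config.n_field_test,
                    stable_seed(config.seed, "field-test"), config.image_size)
    )
    # test/train hygiene: ids must be disjoint
    train_ids = {s.sample_id for s in set1 + set2 + negatives + field_train}
    overlap = train_ids & {s.sample_id for s in test_set}
    if overlap:
        raise RuntimeError(f"test set overlaps training data: {sorted(overlap)[:3]}")

    # stage 1 labels come from the color-threshold auto-labeler
    set1_labeled = [
        LabeledSample(
            image=s.image,
            mask=autolabel(s.image, al_cfg),
            provenance="set1",
            sample_id=s.sample_id,
        )
        for s in set1
    ]

    logs: list[dict] = []
    models: dict[str, TrainedModel] = {}

    first_ce, log1 = run_stage(
        StageConfig(
            stage="stage1_first_ce",
            sources={"set1_labeled": set1_labeled},
            augmentation_seed=stable_seed(config.seed, "aug1"),
            autolabel_config=al_cfg,
        ),
        hp,
        network=net_cfg,
    )
    models["first_ce"] = first_ce
    logs.append(log1)

    ce, log2 = run_stage(
        StageConfig(
            stage="stage2_ce",
            sources={
                "set1_labeled": set1_labeled,
                "pseudo_images": [s.image for s in set2],
                "pseudo_ids": [s.sample_id for s in set2],
            },
            pseudo_label_model=first_ce,
            cleanup_pseudo_labels=True,
            augmentation_seed=stable_seed(config.seed, "aug2"),
            autolabel_config=al_cfg,
        ),
        hp,
        init_model=first_ce,
    )
    models["ce"] = ce
    logs.append(log2)

    # stage 3 reuses the CE net's cleaned SET2 pseudo-labels
    set2_labeled = pseudo_label(
        ce,
        [s.image for s in set2],
        cleanup=True,
        config=al_cfg,
        sample_ids=[s.sample_id for s in set2],
    )

    tna, log3 = run_stage(
        StageConfig(
            stage="stage3_tna",
            sources={
                "set1_labeled": set1_labeled,
                "set2_labeled": set2_labeled,
                "negative_images": [s.image for s in negatives],
                "negative_ids": [s.sample_id for s in negatives],
            },
            negatives_as_zero_masks=True,
            augmentation_seed=stable_seed(config.seed, "aug3"),
            autolabel_config=al_cfg,
        ),
        hp,
        init_model=ce,
    )
    models["tna"] = tna
    logs.append(log3)

    fia, log4 = run_stage(
        StageConfig(
            stage="stage3_fia",
            sources={
                "set1_labeled": set1_labeled,
                "set2_labeled": set2_labeled,
                "pseudo_images": [s.image for s in field_train],
                "pseudo_ids": [s.sample_id for s in field_train],
            },
            pseudo_label_model=ce,
            cleanup_pseudo_labels=False,
            augmentation_seed=stable_seed(config.seed, "aug4"),
            autolabel_config=al_cfg,
        ),
        hp,
        init_model=ce,
    )
    models["fia"] = fia
    logs.append(log4)

    if config.include_manual:
        # comparison arm: generator ground truth plays the manual-label role
        manual_labeled = [
            LabeledSample(
                image=s.image, mask=s.mask, provenance="field",
                sample_id=s.sample_id,
            )
            for s in field_train
        ]
        manual, log5 = run_stage(
            StageConfig(
                stage="manual",
                sources={
                    "set1_labeled": set1_labeled,
                    "set2_labeled": set2_labeled,
                    "manual_labeled": manual_labeled,
                },
                augmentation_seed=stable_seed(config.seed, "aug5"),
                autolabel_config=al_cfg,
            ),
            hp,
            init_model=ce,
        )
        models["manual"] = manual
        logs.append(log5)

    reports = {
        tag: evaluate_test_set(model, test_set) for tag, model in models.items()
    }
    return CascadeResult(models=models, reports=reports, logs=logs, test_set=test_set)
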