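"""Deterministic paired image/mask augmentation: 20 variants per original.

Each original yields exactly 20 derived samples by combining rotation,
reflection, contrast and exposure changes.  The realization is the eight
interpolation-free geometric variants (right-angle rotations x optional
horizontal flip) cycled against three photometric modes (none, contrast
gain, exposure gain) until 20 distinct specs are reached.  Geometric
transforms are pixel permutations applied identically to image and mask;
photometric transforms touch the image only, with intensities clipped to
[0, 255], so masks stay binary and spatially aligned throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .samples import LabeledSample, stable_seed

N_AUGMENTATIONS = 20

CONTRAST_GAIN_RANGE = (0.7, 1.3)
EXPOSURE_GAIN_RANGE = (0.75, 1.35)


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation: geometry (rotation k*90 deg, optional horizontal
    flip) composed with an optional photometric change."""

    rotation_quarters: int = 0          # number of 90-degree CCW rotations
    horizontal_flip: bool = False
    photometric: str = "none"           # none | contrast | exposure
    contrast_gain: float = 1.0
    exposure_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.rotation_quarters not in (0, 1, 2, 3):
            raise ValueError("rotation must be a multiple of 90 degrees")
        if self.photometric not in ("none", "contrast", "exposure"):
            raise ValueError("photometric must be none|contrast|exposure")


@dataclass(frozen=True)
class AugmentationPlan:
    transforms: tuple[TransformSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.transforms) != N_AUGMENTATIONS:
            raise ValueError(
                f"a plan holds exactly {N_AUGMENTATIONS} transforms, "
                f"got {len(self.transforms)}"
            )


def default_plan(seed: int) -> AugmentationPlan:
    """The standard 20-transform plan, deterministic in ``seed``.

    The 8 geometric variants {0, 90, 180, 270 deg} x {identity, hflip}
    are cycled against photometric modes: items 0-7 are purely geometric,
    items 8-15 add a sampled contrast gain, items 16-19 add a sampled
    exposure offset.
    """
    rng = np.random.default_rng(seed)
    geoms = [(k, f) for f in (False, True) for k in (0, 1, 2, 3)]
    modes = ["none", "contrast", "exposure"]
    transforms = []
    for i in range(N_AUGMENTATIONS):
        k, flip = geoms[i % 8]
        mode = modes[i // 8]
        c_gain, e_gain = 1.0, 1.0
        if mode == "contrast":
            c_gain = float(rng.uniform(*CONTRAST_GAIN_RANGE))
        elif mode == "exposure":
            e_gain = float(rng.uniform(*EXPOSURE_GAIN_RANGE))
        transforms.append(
            TransformSpec(
                rotation_quarters=k,
                horizontal_flip=flip,
                photometric=mode,
                contrast_gain=c_gain,
                exposure_gain=e_gain,
            )
        )
    return AugmentationPlan(transforms=tuple(transforms), seed=seed)


def apply_transform(
    image: np.ndarray, mask: np.ndarray, t: TransformSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one transform to an image/mask pair."""
    img = image
    m = mask
    if t.horizontal_flip:
        img = img[:, ::-1]
        m = m[:, ::-1]
    if t.rotation_quarters:
        img = np.rot90(img, k=t.rotation_quarters)
        m = np.rot90(m, k=t.rotation_quarters)
    img = img.astype(np.float64)
    if t.photometric == "contrast":
        # gain applied around mid-gray so "contrast" stretches rather than
        # uniformly brightens
        img = (img - 127.5) * t.contrast_gain + 127.5
    elif t.photometric == "exposure":
        # exposure acts as a scene-luminance scaling, the same mechanism
        # by which shadows attenuate pixel values
        img = img * t.exposure_gain
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(img), np.ascontiguousarray(m)


def apply_plan(sample: LabeledSample, plan: AugmentationPlan) -> list[LabeledSample]:
    """Produce the 20 derived samples for one original."""
    out = []
    for j, t in enumerate(plan.transforms):
        img, m = apply_transform(sample.image, sample.mask, t)
        out.append(
            LabeledSample(
                image=img,
                mask=m,
                provenance=sample.provenance,
                sample_id=f"{sample.sample_id}-aug{j:02d}",
                meta={
                    "source_sample_id": sample.sample_id,
                    "transform": {
                        "rotation_quarters": t.rotation_quarters,
                        "horizontal_flip": t.horizontal_flip,
                        "photometric": t.photometric,
                        "contrast_gain": t.contrast_gain,
                        "exposure_gain": t.exposure_gain,
                    },
                },
            )
        )
    return out


def augment_dataset(
    samples: Sequence[LabeledSample], seed: int
) -> list[LabeledSample]:
    """Expand a dataset 20x; per-sample plans derive from (seed, sample_id)."""
    if len(samples) == 0:
        raise ValueError("dataset must be non-empty")
    out: list[LabeledSample] = []
    for s in samples:
        plan = default_plan(stable_seed(seed, s.sample_id))
        out.extend(apply_plan(s, plan))
    return out
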