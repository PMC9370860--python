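"""Core sample containers shared by every pipeline stage.

An ``RgbImage`` is an ``(H, W, 3)`` uint8 array and a ``BinaryMask`` an
``(H, W)`` array over ``{0, 1}`` (1 = fruit pixel), aligned 1:1 with its
image. ``LabeledSample`` carries the pair plus a provenance tag recording
which arm of the pipeline produced the label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

PROVENANCES = ("set1", "set2", "negative", "field", "synthetic-gt", "pseudo")


def as_rgb_image(arr: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit RGB image array."""
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected uint8 intensities, got dtype {arr.dtype}")
    return arr


def as_binary_mask(arr: np.ndarray) -> np.ndarray:
    """Validate a mask and return it as uint8 over {0, 1}."""
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected an (H, W) mask, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask values must be exactly 0 or 1, found {vals}")
    return arr.astype(np.uint8)


@dataclass
class LabeledSample:
    """An image/mask pair with provenance.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3), uint8
    mask : ndarray, shape (H, W), values in {0, 1}; 1 marks fruit pixels.
    provenance : str
        One of ``set1 | set2 | negative | field | synthetic-gt | pseudo``.
    sample_id : str
        Unique identifier; downstream augmentation seeds derive from it.
    """

    image: np.ndarray
    mask: np.ndarray
    provenance: str
    sample_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = as_rgb_image(self.image)
        self.mask = as_binary_mask(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "must have identical height and width"
            )
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance {self.provenance!r} not in {PROVENANCES}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def write_image_png(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(as_rgb_image(image), mode="RGB").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Masks are stored single-channel with values {0, 255} (255 = fruit)."""
    Image.fromarray(as_binary_mask(mask) * 255, mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_manifest(
    out_dir: str | Path, samples: Iterable[LabeledSample], extra: dict | None = None
) -> Path:
    """Write samples as PNG pairs plus a JSON manifest listing them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in samples:
        img_path = out_dir / f"{s.sample_id}.png"
        mask_path = out_dir / f"{s.sample_id}_mask.png"
        write_image_png(img_path, s.image)
        write_mask_png(mask_path, s.mask)
        entries.append(
            {
                "sample_id": s.sample_id,
                "image": img_path.name,
                "mask": mask_path.name,
                "provenance": s.provenance,
                "meta": s.meta,
            }
        )
    manifest = {"samples": entries}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_manifest(path: str | Path) -> list[LabeledSample]:
    path = Path(path)
    doc = json.loads(path.read_text())
    samples = []
    for e in doc["samples"]:
        samples.append(
            LabeledSample(
                image=read_image_png(path.parent / e["image"]),
                mask=read_mask_png(path.parent / e["mask"]),
                provenance=e["provenance"],
                sample_id=e["sample_id"],
                meta=e.get("meta", {}),
            )
        )
    return samples


def stable_seed(*parts: int | str) -> int:
    """Deterministic 31-bit seed derived from mixed ints/strings.

    Python's builtin ``hash`` is salted per process, so a CRC-based mix is
    used to keep augmentation plans reproducible across runs.
    """
    import zlib

    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode("utf8"), h)
    return h & 0x7FFFFFFF
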