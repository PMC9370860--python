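"""Automatic ground-truth mask generation for controlled-environment images.

The labeling rule is a per-pixel red-dominance test in RGB space followed
by three connected-component cleanup operators applied in order:

1. noise removal — drop components whose area falls below a threshold;
2. stem discarding — erode to detach thin protruding stems, drop the
   detached components whose moment-equivalent ellipse is highly eccentric
   (stem-like), then restore the survivors by dilation;
3. hole filling — set to foreground every background region not connected
   to the image border, so labels stay uniform across shaded fruit areas.

Structuring elements are disks; component shape comes from second-order
central moments (the moment-equivalent ellipse), for which eccentricity
has the closed form ``sqrt(1 - (b/a)^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .samples import as_binary_mask, as_rgb_image

_CONNECTIVITY = {"4-connected": 1, "8-connected": 2}


@dataclass(frozen=True)
class AutolabelConfig:
    """Thresholds and cleanup parameters.

    Defaults are calibrated to the synthetic deep-red fruit palette on a
    neutral gray background: ``red_min=130`` with 40-intensity dominance
    margins accepts fruit bodies and reddish stems while rejecting the
    background; ``min_area`` scales quadratically with resolution from
    64 px at 256x256; ``eccentricity_max=0.92`` passes near-round fruit
    bodies and rejects thin stem fragments.
    """

    red_min: int = 130
    red_green_margin: int = 40
    red_blue_margin: int = 40
    min_area: int = 64
    erosion_radius: int = 3
    dilation_radius: int = 3
    eccentricity_max: float = 0.92
    connectivity: str = "8-connected"

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.erosion_radius < 1:
            raise ValueError("erosion_radius must be >= 1")
        if not 0.0 <= self.eccentricity_max < 1.0:
            raise ValueError("eccentricity_max must lie in [0, 1)")
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError(f"connectivity must be one of {list(_CONNECTIVITY)}")

    def scaled_min_area(self, shape: tuple[int, int]) -> int:
        """min_area rescaled quadratically from the 256x256 reference."""
        h, w = shape
        return max(1, int(round(self.min_area * (h * w) / (256 * 256))))


@dataclass(frozen=True)
class ComponentShape:
    """Moment-equivalent ellipse summary of one connected component."""

    area: int
    centroid: tuple[float, float]
    ellipse_semi_major: float
    ellipse_semi_minor: float
    eccentricity: float


def threshold_fruit_pixels(image: np.ndarray, config: AutolabelConfig) -> np.ndarray:
    """Purely per-pixel red-dominance threshold.

    A pixel is fruit iff ``R >= red_min`` and ``R - G >= red_green_margin``
    and ``R - B >= red_blue_margin``; no spatial context is used.
    """
    image = as_rgb_image(image)
    r = image[:, :, 0].astype(np.int16)
    g = image[:, :, 1].astype(np.int16)
    b = image[:, :, 2].astype(np.int16)
    mask = (
        (r >= config.red_min)
        & (r - g >= config.red_green_margin)
        & (r - b >= config.red_blue_margin)
    )
    return mask.astype(np.uint8)


def remove_small_components(
    mask: np.ndarray, min_area: int, connectivity: str = "8-connected"
) -> np.ndarray:
    """Zero every connected component with area strictly below ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = as_binary_mask(mask)
    # strict "< min_area" removal: drop components of size <= min_area - 1
    if min_area == 1:
        return mask
    keep = morphology.remove_small_objects(
        mask.astype(bool),
        max_size=min_area - 1,
        connectivity=_CONNECTIVITY[connectivity],
    )
    return keep.astype(np.uint8)


def measure_components(
    mask: np.ndarray, connectivity: str = "8-connected"
) -> list[ComponentShape]:
    """One :class:`ComponentShape` per connected component (empty mask -> [])."""
    mask = as_binary_mask(mask)
    labels = measure.label(mask, connectivity=_CONNECTIVITY[connectivity])
    shapes = []
    for rp in measure.regionprops(labels):
        shapes.append(
            ComponentShape(
                area=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                ellipse_semi_major=float(rp.axis_major_length) / 2.0,
                ellipse_semi_minor=float(rp.axis_minor_length) / 2.0,
                eccentricity=float(rp.eccentricity),
            )
        )
    return shapes


def discard_stems(mask: np.ndarray, config: AutolabelConfig) -> np.ndarray:
    """Erode, drop stem-like (high-eccentricity) components, dilate back.

    Erosion by a disk detaches stems thinner than its diameter from the
    fruit body (thin stems may disappear outright); any surviving detached
    fragment with eccentricity above ``eccentricity_max`` is dropped; the
    remaining bodies are restored by dilation.
    """
    mask = as_binary_mask(mask)
    if not mask.any():
        return mask
    selem_e = morphology.disk(config.erosion_radius)
    eroded = morphology.erosion(mask, selem_e).astype(bool)
    labels = measure.label(eroded, connectivity=_CONNECTIVITY[config.connectivity])
    survivors = np.zeros_like(eroded)
    for rp in measure.regionprops(labels):
        if rp.eccentricity <= config.eccentricity_max:
            survivors[labels == rp.label] = True
    selem_d = morphology.disk(config.dilation_radius)
    restored = morphology.dilation(survivors.astype(np.uint8), selem_d)
    return restored.astype(np.uint8)


def fill_holes(mask: np.ndarray, connectivity: str = "8-connected") -> np.ndarray:
    """Set to 1 every background region not connected to the image border."""
    mask = as_binary_mask(mask)
    # hole background connectivity is the complement of the foreground's
    struct = ndimage.generate_binary_structure(
        2, 2 if _CONNECTIVITY[connectivity] == 1 else 1
    )
    filled = ndimage.binary_fill_holes(mask.astype(bool), structure=struct)
    return filled.astype(np.uint8)


def autolabel(image: np.ndarray, config: AutolabelConfig | None = None) -> np.ndarray:
    """Threshold -> noise removal -> stem discarding -> hole filling."""
    if config is None:
        config = AutolabelConfig()
    mask = threshold_fruit_pixels(image, config)
    mask = remove_small_components(
        mask, config.scaled_min_area(mask.shape), config.connectivity
    )
    mask = discard_stems(mask, config)
    mask = fill_holes(mask, config.connectivity)
    return mask
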