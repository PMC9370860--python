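"""Seeded synthetic orchard-style scenes with exact ground-truth masks.

Four scene kinds mirror the data-set taxonomy the training cascade
consumes:

``set1``
    harvested fruits on a neutral background under uniform light;
``set2``
    the same arrangement under harsh, non-uniform light with cast shadows;
``negative``
    true-negative frames: foliage, branches and dry-leaf confusers but no
    fruit (ground truth is all zeros);
``field``
    tree-row frames combining foliage, branches, shadows, fruits and
    yellow-brown dry-leaf confusers whose color overlaps the fruit hue.

Every fruit is a filled, analytically defined ellipse; the ground-truth
mask is computed from the same ellipse equations used for rendering, so a
mask pixel is 1 iff it lies inside a fruit body.  Stems are rendered in a
reddish palette (they are meant to be caught by color thresholding and
removed by morphology) but are excluded from ground truth.  A single
pseudo-random stream keyed by the spec seed drives all sampling, so equal
specs reproduce bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .samples import LabeledSample

SCENE_KINDS = ("set1", "set2", "negative", "field")

#: Deep red/crimson fruit palette: strongly red-dominant so that an RGB
#: red-dominance threshold separates fruit from neutral background.
DEFAULT_FRUIT_COLOR_RANGE = ((150, 220), (20, 80), (20, 80))
DEFAULT_BACKGROUND_COLOR = (120, 120, 120)
#: Yellow-brown "dry leaf" palette; red-dominant enough to confuse a net
#: trained only on neutral backgrounds.
CONFUSER_COLOR_RANGE = ((180, 220), (140, 180), (40, 90))


@dataclass(frozen=True)
class SceneSpec:
    """Full recipe for one synthetic scene.

    Identical specs (including ``seed``) always render bit-identical
    image/mask pairs.
    """

    scene_kind: str
    image_size: tuple[int, int] = (64, 64)
    n_fruits: int = 3
    fruit_color_range: tuple = DEFAULT_FRUIT_COLOR_RANGE
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND_COLOR
    stem_probability: float = 0.6
    shadow_strength: float = 0.0
    confuser_count: int = 0
    fruit_shade_min: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.scene_kind not in SCENE_KINDS:
            raise ValueError(f"scene_kind must be one of {SCENE_KINDS}")
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError(f"image_size must be at least 32x32, got {h}x{w}")
        if self.n_fruits < 0 or self.confuser_count < 0:
            raise ValueError("n_fruits and confuser_count must be non-negative")
        if self.scene_kind == "negative" and self.n_fruits != 0:
            raise ValueError("negative scenes must have n_fruits = 0")
        if self.scene_kind == "set1" and self.shadow_strength != 0:
            raise ValueError("set1 scenes must have shadow_strength = 0")
        if self.scene_kind in ("set1", "set2") and self.confuser_count != 0:
            raise ValueError("confusers only occur in field/negative scenes")
        if not 0.0 <= self.stem_probability <= 1.0:
            raise ValueError("stem_probability must lie in [0, 1]")
        if not 0.0 <= self.shadow_strength <= 1.0:
            raise ValueError("shadow_strength must lie in [0, 1]")
        if not 0.0 < self.fruit_shade_min <= 1.0:
            raise ValueError("fruit_shade_min must lie in (0, 1]")


def _ellipse_interior(
    h: int, w: int, cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Boolean mask of the interior of a rotated ellipse.

    ``a``/``b`` are semi-major/semi-minor axes in pixels, ``theta`` the
    major-axis angle; coordinates are 0-based row-major, origin top-left.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_color(rng: np.random.Generator, color_range) -> np.ndarray:
    (r0, r1), (g0, g1), (b0, b1) = color_range
    return np.array(
        [rng.uniform(r0, r1), rng.uniform(g0, g1), rng.uniform(b0, b1)]
    )


def _foliage_background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Textured green canopy: low-frequency blotches plus pixel noise."""
    coarse = rng.uniform(0.7, 1.3, size=(max(h // 8, 2), max(w // 8, 2), 1))
    reps = (int(np.ceil(h / coarse.shape[0])), int(np.ceil(w / coarse.shape[1])))
    blotch = np.kron(coarse, np.ones((reps[0], reps[1], 1)))[:h, :w, :]
    base = np.array([55.0, 105.0, 45.0])
    img = base[None, None, :] * blotch
    img += rng.normal(0.0, 8.0, size=(h, w, 3))
    return img


def _draw_canopy_leaves(img, rng, h, w, n_leaves, scale):
    """Yellow-green living leaves: bright but never red-dominant.

    They populate the color band between foliage green and dry-leaf
    yellow, giving field-supervised nets background anchors near the
    confuser spectrum.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_leaves):
        a = rng.uniform(0.06, 0.11) * scale
        b = a * rng.uniform(0.4, 0.7)
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(a, h - a)
        cx = rng.uniform(a, w - a)
        inside = _ellipse_interior(h, w, cy, cx, a, b, theta)
        r = rng.uniform(140, 185)
        g = r + rng.uniform(0, 25)
        color = np.array([r, g, rng.uniform(40, 80)])
        img[inside] = color[None, :]
    return img


def _draw_branches(img, rng, h, w, n_branches):
    """Brown strokes drawn as thick line segments."""
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_branches):
        y0, x0 = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.5, 1.2) * max(h, w)
        y1, x1 = y0 + length * np.sin(ang), x0 + length * np.cos(ang)
        thick = rng.uniform(1.5, 3.5)
        dy, dx = y1 - y0, x1 - x0
        denom = dy * dy + dx * dx
        t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / denom, 0, 1)
        dist = np.hypot(yy - (y0 + t * dy), xx - (x0 + t * dx))
        stroke = dist <= thick
        color = np.array(
            [rng.uniform(90, 120), rng.uniform(55, 80), rng.uniform(25, 45)]
        )
        img[stroke] = color[None, :]
    return img


def generate_scene(spec: SceneSpec) -> LabeledSample:
    """Render one scene and its exact ground-truth mask.

    The returned sample's ``meta`` records the analytic shape parameters
    (fruit ellipses, stem rectangles, confuser ellipses), which downstream
    tests use as the geometric oracle.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    field_like = spec.scene_kind in ("negative", "field")

    if field_like:
        img = _foliage_background(rng, h, w)
        img = _draw_branches(img, rng, h, w, n_branches=int(rng.integers(2, 5)))
        img = _draw_canopy_leaves(
            img, rng, h, w, n_leaves=int(rng.integers(3, 7)), scale=min(h, w)
        )
    else:
        # the neutral backdrop varies in level and carries mild blotchy
        # texture from scene to scene, as real boards and sheets do; this
        # variation forces the nets toward the fruit-color rule instead of
        # memorizing one particular gray
        level = rng.uniform(0.75, 1.25)
        img = np.asarray(spec.background_color, dtype=float)[None, None, :] * np.ones(
            (h, w, 1)
        ) * level
        coarse = rng.uniform(0.9, 1.1, size=(max(h // 8, 2), max(w // 8, 2), 1))
        reps = (int(np.ceil(h / coarse.shape[0])), int(np.ceil(w / coarse.shape[1])))
        img *= np.kron(coarse, np.ones((reps[0], reps[1], 1)))[:h, :w, :]
        img += rng.normal(0.0, 3.0, size=(h, w, 3))

    scale = min(h, w)
    placed_centers: list[tuple[float, float, float]] = []

    def _place(radius: float) -> tuple[float, float, float]:
        # blobs are kept strictly disjoint (fruits laid out on a surface do
        # not interpenetrate, and disjointness makes the ground-truth mask
        # an exact union of the analytic ellipses); if a radius cannot be
        # placed it shrinks and retries
        r = radius
        while True:
            for _ in range(60):
                cy = rng.uniform(r, h - r)
                cx = rng.uniform(r, w - r)
                if all(
                    np.hypot(cy - py, cx - px) > r + pr + 3.0
                    for py, px, pr in placed_centers
                ):
                    placed_centers.append((cy, cx, r))
                    return cy, cx, r
            if r <= 0.06 * scale:
                # last resort: accept a cramped position
                placed_centers.append((cy, cx, r))
                return cy, cx, r
            r *= 0.8

    confusers = []
    for _ in range(spec.confuser_count):
        a = rng.uniform(0.08, 0.13) * scale
        theta = rng.uniform(0, np.pi)
        cy, cx, a = _place(a)
        b = a * rng.uniform(0.45, 0.75)  # leaf-like, elongated
        inside = _ellipse_interior(h, w, cy, cx, a, b, theta)
        color = _sample_color(rng, CONFUSER_COLOR_RANGE)
        img[inside] = color[None, :]
        # dry leaves carry a withered tip whose color sits on the continuum
        # between the leaf's yellow-brown and ripe-fruit red. The per-leaf
        # withering factor varies, so tips range from mildly reddish to
        # nearly fruit-colored: red-dominant enough that a net knowing only
        # neutral backgrounds extrapolates them to "fruit", while nets with
        # in-field supervision have nearby background anchors (leaf bodies,
        # branches) to pull the continuum back
        pa = a * rng.uniform(0.45, 0.65)
        pb = b * rng.uniform(0.55, 0.85)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        off = sign * (a - pa)
        pcy = cy + off * np.sin(theta)
        pcx = cx + off * np.cos(theta)
        patch = _ellipse_interior(h, w, pcy, pcx, pa, pb, theta) & inside
        withering = rng.uniform(0.35, 0.95)
        patch_color = (
            (1.0 - withering) * color
            + withering * _sample_color(rng, spec.fruit_color_range)
        )
        img[patch] = patch_color[None, :]
        confusers.append(
            {"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta}
        )

    fruits = []
    stems = []
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_fruits):
        # fruit bodies span a sizeable fraction of the frame (table-top and
        # close-range canopy views); the minor axis stays comfortably above
        # the default morphological erosion diameter at any size >= 32 px
        a = rng.uniform(0.11, 0.16) * scale
        theta = rng.uniform(0, np.pi)
        cy, cx, a = _place(a)
        b = a * rng.uniform(0.7, 1.0)  # near-round fruit bodies
        inside = _ellipse_interior(h, w, cy, cx, a, b, theta)
        color = _sample_color(rng, spec.fruit_color_range)
        if spec.scene_kind == "field" and spec.fruit_shade_min < 1.0:
            # canopy self-shading: field fruits are often much darker than
            # the table-top acquisitions, which is what makes field recall
            # a contested quantity
            color = color * rng.uniform(spec.fruit_shade_min, 1.0)
        img[inside] = color[None, :]
        mask |= inside
        fruits.append({"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta})

        if rng.uniform() < spec.stem_probability:
            # thin reddish rectangle protruding outward along a random
            # direction; caught by color thresholding, absent from GT
            phi = rng.uniform(0, 2 * np.pi)
            width = rng.uniform(2.0, 4.0)
            length = rng.uniform(0.10, 0.25) * (2 * a)
            ux, uy = np.cos(phi), np.sin(phi)
            # radial extent of the ellipse along phi
            ca, sa = np.cos(theta), np.sin(theta)
            uu = ux * ca + uy * sa
            vv = -ux * sa + uy * ca
            r_edge = 1.0 / np.sqrt((uu / a) ** 2 + (vv / b) ** 2)
            stem_color = np.array(
                [rng.uniform(140, 180), rng.uniform(25, 60), rng.uniform(25, 60)]
            )
            stems.append(
                {
                    "cy": cy,
                    "cx": cx,
                    "phi": phi,
                    "width": width,
                    "length": length,
                    "r_edge": float(r_edge),
                    "color": stem_color,
                }
            )

    # stems are painted after every fruit so they never overwrite (or get
    # counted inside) any fruit body; ground truth stays fruit-only
    for st in stems:
        ux, uy = np.cos(st["phi"]), np.sin(st["phi"])
        proj = (xx - st["cx"]) * ux + (yy - st["cy"]) * uy
        perp = -(xx - st["cx"]) * uy + (yy - st["cy"]) * ux
        stem_px = (
            (proj >= st["r_edge"] - 1.0)
            & (proj <= st["r_edge"] + st["length"])
            & (np.abs(perp) <= st["width"] / 2.0)
            & ~mask
        )
        img[stem_px] = st["color"][None, :]
        st.pop("color")

    if spec.scene_kind in ("set2", "field", "negative") and spec.shadow_strength > 0:
        # multiplicative illumination ramp across a random direction
        ang = rng.uniform(0, 2 * np.pi)
        ramp = (yy * np.sin(ang) + xx * np.cos(ang)).astype(float)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
        lo = 1.0 - 0.35 * spec.shadow_strength
        img *= (lo + (1.0 - lo) * ramp)[:, :, None]
        # hard-edged elliptical cast shadows
        for _ in range(int(rng.integers(1, 4))):
            sa_ = rng.uniform(0.15, 0.35) * scale
            sb_ = sa_ * rng.uniform(0.5, 1.0)
            sh = _ellipse_interior(
                h, w, rng.uniform(0, h), rng.uniform(0, w), sa_, sb_,
                rng.uniform(0, np.pi),
            )
            img[sh] *= 1.0 - 0.55 * spec.shadow_strength

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    sample_id = f"{spec.scene_kind}-s{spec.seed}"
    return LabeledSample(
        image=image,
        mask=mask.astype(np.uint8),
        provenance=spec.scene_kind,
        sample_id=sample_id,
        meta={
            "spec": asdict(spec),
            "fruits": fruits,
            "stems": stems,
            "confusers": confusers,
        },
    )


def generate_dataset(specs: Sequence[SceneSpec]) -> list[LabeledSample]:
    """Render one sample per spec, in order, with unique sample ids."""
    if len(specs) == 0:
        raise ValueError("spec list must be non-empty")
    samples = []
    for i, spec in enumerate(specs):
        s = generate_scene(spec)
        s.sample_id = f"{s.sample_id}-{i:05d}"
        samples.append(s)
    return samples


def scene_specs(
    scene_kind: str,
    count: int,
    base_seed: int,
    image_size: tuple[int, int] = (64, 64),
    **overrides,
) -> list[SceneSpec]:
    """Convenience batch of per-kind specs with realistic defaults.

    Per-scene seeds and fruit/confuser counts derive deterministically
    from ``base_seed`` so a batch is fully reproducible.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(base_seed)
    # "field" emulates frames from the full robot traverse (confuser-rich,
    # strongly shaded fruit); "field-close" emulates the first seconds of
    # acquisition: close-range, better lit, few dry leaves in view -- the
    # frames the cascade pseudo-labels for its final training stage
    defaults = {
        "set1": dict(shadow_strength=0.0, confuser_count=0, stem_probability=0.6),
        "set2": dict(shadow_strength=0.6, confuser_count=0, stem_probability=0.6),
        "negative": dict(shadow_strength=0.4, stem_probability=0.0),
        "field": dict(shadow_strength=0.5, stem_probability=0.3,
                      fruit_shade_min=0.4),
        "field-close": dict(shadow_strength=0.4, stem_probability=0.3,
                            fruit_shade_min=0.6),
    }[scene_kind]
    preset, scene_kind = scene_kind, (
        "field" if scene_kind == "field-close" else scene_kind
    )
    specs = []
    for _ in range(count):
        kw = dict(defaults)
        if scene_kind == "negative":
            kw["n_fruits"] = 0
            kw["confuser_count"] = int(rng.integers(2, 5))
        elif preset == "field-close":
            # close-range canopy views: fruit clusters fill the frame and
            # ground-level dry leaves are out of view
            kw["n_fruits"] = int(rng.integers(2, 5))
            kw["confuser_count"] = 0
        elif scene_kind == "field":
            kw["n_fruits"] = int(rng.integers(1, 5))
            kw["confuser_count"] = int(rng.integers(2, 5))
        else:
            kw["n_fruits"] = int(rng.integers(2, 6))
        kw["seed"] = int(rng.integers(0, 2**31 - 1))
        kw["image_size"] = image_size
        kw.update(overrides)
        specs.append(SceneSpec(scene_kind=scene_kind, **kw))
    return specs
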