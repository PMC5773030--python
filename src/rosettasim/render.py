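"""Software rasterization of a rosette scene into a labeled top-down image.

The camera is exactly nadir orthographic.  The plant is centered, scaled so
that the ratio of plant diameter to image side is drawn uniformly from a
configurable range (default 0.5..1.0, i.e. 1:2 to 1:1), and composited in
painter's order with higher organs drawn last.  Rasterization is polygon
scan-conversion of the projected primitives at a supersampled resolution,
box-downsampled to the final image; the foreground mask is computed at the
final resolution with a majority rule, and pixels outside the mask keep the
flat background color exactly.

Backgrounds are a flat soil color, a uniform random RGB color, black, or a
mixture (random with probability ``mixed_p``, soil otherwise) — the policy
used to vary foreground/background contrast in synthetic training sets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
from PIL import Image
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .turtle import Blade, Cylinder, Scene

__all__ = [
    "RenderConfig",
    "LabeledSample",
    "RenderError",
    "InvisibleBladeError",
    "compute_diameter",
    "render",
    "apply_mask_black",
]

BACKGROUND_MODES = ("soil", "random_rgb", "mixed", "black")


class RenderError(RuntimeError):
    pass


class InvisibleBladeError(RenderError):
    """A blade contributed no visible pixel; the sample should be regenerated."""


@dataclass(frozen=True)
class RenderConfig:
    image_size: int = 256
    scale_ratio_range: tuple[float, float] = (0.5, 1.0)
    background_mode: str = "soil"
    mixed_p: float = 0.5
    soil_color: tuple[int, int, int] = (110, 80, 55)
    leaf_color_base: tuple[int, int, int] = (46, 112, 48)
    petiole_color: tuple[int, int, int] = (88, 138, 74)
    internode_color: tuple[int, int, int] = (96, 122, 60)
    leaf_jitter: float = 0.10  # per-leaf brightness jitter amplitude
    supersample: int = 2
    blade_outline_segments: int = 24

    def __post_init__(self):
        lo, hi = self.scale_ratio_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("scale_ratio_range must lie within (0, 1]")
        if not (0 <= self.mixed_p <= 1):
            raise ValueError("mixed_p must be in [0, 1]")
        if self.background_mode not in BACKGROUND_MODES:
            raise ValueError(f"background_mode must be one of {BACKGROUND_MODES}")


@dataclass
class LabeledSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, {0, 255}
    leaf_count: int
    params_ref: Optional[object] = None
    render_seed: Optional[int] = None
    background_kind: str = "soil"  # realized draw: soil | random | black
    scale_ratio: float = 0.0

    def png_bytes(self) -> bytes:
        buf = io.BytesIO()
        Image.fromarray(self.image).save(buf, format="PNG")
        return buf.getvalue()

    def save(self, image_path, mask_path) -> None:
        Image.fromarray(self.image).save(image_path, format="PNG")
        Image.fromarray(self.mask).save(mask_path, format="PNG")


def compute_diameter(scene: Scene) -> float:
    """Side of the minimal axis-aligned bounding square of the top-down projection."""
    pts = scene.projected_points()
    if len(pts) == 0:
        raise RenderError("cannot compute the diameter of an empty scene")
    ext = pts[:, :2].max(axis=0) - pts[:, :2].min(axis=0)
    return float(ext.max())


_ORGAN_RANK = {"internode": 0, "segment": 0, "petiole": 1, "blade": 2}


def _projected_primitives(scene: Scene, cfg: RenderConfig):
    """Projected primitives in painter's order (higher organs last).

    Organs tagged with a node index sort by node: node order equals the
    attachment height on the stem, so leaves emitted later — higher and
    more central — are drawn on top, as seen from a nadir camera.
    Untagged primitives fall back to their base height.
    """
    prims = []
    for p in scene.primitives:
        if isinstance(p, Blade):
            poly = p.outline(cfg.blade_outline_segments)[:, :2]
            prims.append((poly, (p.node, _ORGAN_RANK["blade"], float(p.origin[2])), "blade", p.node, None))
        elif isinstance(p, Cylinder):
            a, b = p.p0[:2], p.p1[:2]
            zbase = float(min(p.p0[2], p.p1[2]))
            key = (p.node, _ORGAN_RANK.get(p.organ, 0), zbase)
            d = b - a
            norm = np.hypot(*d)
            if norm < 1e-12:
                # degenerate in projection (vertical segment): a disk
                prims.append((None, key, p.organ, p.node, (a, max(p.r0, p.r1))))
            else:
                perp = np.array([-d[1], d[0]]) / norm
                poly = np.array([a + perp * p.r0, b + perp * p.r1, b - perp * p.r1, a - perp * p.r0])
                prims.append((poly, key, p.organ, p.node, None))
    prims.sort(key=lambda t: t[1])
    return prims


def _jitter_color(base: tuple, factor: float) -> np.ndarray:
    return np.clip(np.asarray(base, dtype=float) * factor, 0, 255)


def render(scene: Scene, cfg: RenderConfig, rng: np.random.Generator) -> LabeledSample:
    """Rasterize ``scene`` into a LabeledSample.

    Deterministic given (scene, cfg, rng state).  Raises
    :class:`InvisibleBladeError` if any blade ends up with no visible pixel
    (fully occluded or sub-pixel): callers should regenerate the sample.
    """
    diameter = compute_diameter(scene)
    if diameter <= 0:
        raise RenderError("scene has zero projected extent")

    # -- stochastic draws, in a fixed order for reproducibility
    lo, hi = cfg.scale_ratio_range
    scale_ratio = float(rng.uniform(lo, hi))
    if cfg.background_mode == "mixed":
        use_random = bool(rng.random() < cfg.mixed_p)
    else:
        use_random = cfg.background_mode == "random_rgb"
    # random background color is always drawn in mixed mode to keep the
    # stream layout independent of the bernoulli outcome
    random_bg = rng.integers(0, 256, size=3)
    if use_random:
        background = np.asarray(random_bg, dtype=float)
        background_kind = "random"
    elif cfg.background_mode == "black":
        background = np.zeros(3)
        background_kind = "black"
    else:
        background = np.asarray(cfg.soil_color, dtype=float)
        background_kind = "soil"
    blade_nodes = sorted({b.node for b in scene.blades})
    jitter = {
        n: float(f)
        for n, f in zip(blade_nodes, rng.uniform(1 - cfg.leaf_jitter, 1 + cfg.leaf_jitter, len(blade_nodes)))
    }

    # -- projection to supersampled pixel coordinates
    S = cfg.image_size
    ss = cfg.supersample
    R = S * ss
    pts = scene.projected_points()[:, :2]
    center = 0.5 * (pts.max(axis=0) + pts.min(axis=0))
    ppu = scale_ratio * R / diameter  # supersampled pixels per model unit

    def to_px(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = (xy[:, 0] - center[0]) * ppu + R / 2
        rows = R / 2 - (xy[:, 1] - center[1]) * ppu
        return rows, cols

    canvas = np.empty((R, R, 3), dtype=float)
    canvas[:] = background
    fg = np.zeros((R, R), dtype=bool)
    idbuf = np.full((R, R), -10, dtype=np.int32)

    for poly, _z, organ, node, disk in _projected_primitives(scene, cfg):
        if organ == "blade":
            color = _jitter_color(cfg.leaf_color_base, jitter.get(node, 1.0))
            pid = node
        elif organ == "petiole":
            color = _jitter_color(cfg.petiole_color, jitter.get(node, 1.0))
            pid = -1
        else:
            color = np.asarray(cfg.internode_color, dtype=float)
            pid = -1
        if disk is not None:
            (cxy, r) = disk
            rows, cols = to_px(cxy[None, :])
            rr, cc = draw_disk((rows[0], cols[0]), max(r * ppu, 1.0), shape=(R, R))
        else:
            rows, cols = to_px(poly)
            rr, cc = draw_polygon(rows, cols, shape=(R, R))
        canvas[rr, cc] = color
        fg[rr, cc] = True
        idbuf[rr, cc] = pid

    visible = set(np.unique(idbuf))
    missing = [n for n in blade_nodes if n not in visible]
    if missing:
        raise InvisibleBladeError(f"blades with no visible pixel: {missing}")

    # -- downsample: box filter for color, majority rule for the mask
    img = canvas.reshape(S, ss, S, ss, 3).mean(axis=(1, 3))
    coverage = fg.reshape(S, ss, S, ss).mean(axis=(1, 3))
    mask = coverage >= 0.5
    img = np.where(mask[:, :, None], img, background[None, None, :])
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return LabeledSample(
        image=image,
        mask=(mask.astype(np.uint8) * 255),
        leaf_count=len(scene.blades),
        background_kind=background_kind,
        scale_ratio=scale_ratio,
    )


def apply_mask_black(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Set background (mask == 0) pixels to black; foreground unchanged."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape[:2]} dimensions differ")
    out = image.copy()
    out[mask == 0] = 0
    return out
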